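import numpy as np
import pytest

from dcmflearn import collection_from_arrays, synth
from dcmflearn.dcmf import (
    ConfigurationError,
    DCMFConfig,
    LatentFactor,
    SupervisedTask,
    fit,
    init_network,
    reconstruct_view,
)

FAST = dict(learning_rate=0.01, weight_decay=0.0, epochs=60)


@pytest.fixture(scope="module")
def small_collection():
    spec = synth.SynthSpec(
        entities={"patients": 30, "diseases": 12, "meds": 9},
        rank=2,
        noise_sd=0.2,
        views=(
            ("v1", "patients", "diseases", "real"),
            ("v2", "patients", "meds", "real"),
        ),
        seed=5,
    )
    coll, factors = synth.simulate_collection(spec)
    return coll, factors


class TestReconstructView:
    def test_identity_times_diagonal(self):
        u_r = LatentFactor("a", np.eye(2))
        u_c = LatentFactor("b", np.diag([2.0, 3.0]))
        np.testing.assert_array_equal(
            reconstruct_view(u_r, u_c), [[2.0, 0.0], [0.0, 3.0]]
        )

    def test_rank_one_outer_product(self):
        u_r = LatentFactor("a", np.array([[1.0], [2.0]]))
        u_c = LatentFactor("b", np.array([[3.0], [4.0]]))
        np.testing.assert_array_equal(
            reconstruct_view(u_r, u_c), [[3.0, 4.0], [6.0, 8.0]]
        )

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        ur, uc = rng.standard_normal((7, 3)), rng.standard_normal((5, 3))
        got = reconstruct_view(LatentFactor("a", ur), LatentFactor("b", uc))
        expected = np.zeros((7, 5))
        for i in range(7):
            for j in range(5):
                for f in range(3):
                    expected[i, j] += ur[i, f] * uc[j, f]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_latent_dim_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruct_view(
                LatentFactor("a", np.zeros((2, 2))), LatentFactor("b", np.zeros((3, 4)))
            )


class TestNetwork:
    def test_one_autoencoder_per_entity(self, small_collection):
        coll, _ = small_collection
        model = init_network(coll, DCMFConfig(latent_dim=3, **FAST))
        assert set(model.encoders) == set(coll.entities)
        assert model.head is None
        sup = init_network(
            coll,
            DCMFConfig(latent_dim=3, **FAST),
            SupervisedTask("patients", np.zeros(30, dtype=int)),
        )
        assert sup.head is not None

    def test_identical_seed_identical_init(self, small_collection):
        coll, _ = small_collection
        cfg = DCMFConfig(latent_dim=3, seed=11, **FAST)
        m1, m2 = init_network(coll, cfg), init_network(coll, cfg)
        for e in m1.encoders:
            for l1, l2 in zip(m1.encoders[e].layers, m2.encoders[e].layers):
                np.testing.assert_array_equal(l1.W, l2.W)

    def test_latent_dim_exceeding_width_rejected(self):
        coll = collection_from_arrays(
            {"X": ("a", "b", np.random.default_rng(0).standard_normal((6, 3)))}
        )
        with pytest.raises(ConfigurationError, match="width"):
            init_network(coll, DCMFConfig(latent_dim=3, **FAST))

    def test_encode_width_mismatch(self, small_collection):
        coll, _ = small_collection
        model = init_network(coll, DCMFConfig(latent_dim=3, **FAST))
        with pytest.raises(ValueError, match="width"):
            model.encode_entity("patients", np.zeros((4, 5)))

    def test_encode_deterministic(self, small_collection):
        coll, _ = small_collection
        model = init_network(coll, DCMFConfig(latent_dim=3, **FAST))
        a = model.encode_entity("patients", model.inputs["patients"]).values
        b = model.encode_entity("patients", model.inputs["patients"]).values
        np.testing.assert_array_equal(a, b)


class TestObjective:
    def test_total_matches_independent_recomputation(self, small_collection):
        """The reported total equals hand-summed MSE terms computed from
        the factors and decoders directly."""
        coll, _ = small_collection
        labels = (np.arange(30) % 2).astype(int)
        task = SupervisedTask("patients", labels)
        cfg = DCMFConfig(latent_dim=3, loss_weights=(0.7, 1.3, 2.1), seed=3, **FAST)
        model = init_network(coll, cfg, task)
        breakdown = model.objective()

        total = 0.0
        for e in coll.entities:
            c = model.inputs[e]
            u = model.encoders[e].forward(c)
            c_hat = model.decoders[e].forward(u)
            total += 0.7 * np.mean((c_hat - c) ** 2)
        u = {e: model.encoders[e].forward(model.inputs[e]) for e in coll.entities}
        for v in coll.views:
            x_hat = u[v.row_entity] @ u[v.col_entity].T
            total += 1.3 * np.mean((x_hat - v.dense()) ** 2)
        logits = u["patients"] @ model.head.W + model.head.b
        p = 1 / (1 + np.exp(-logits.ravel()))
        bce = -np.mean(labels * np.log(p + 1e-12) + (1 - labels) * np.log(1 - p + 1e-12))
        total += 2.1 * bce
        assert breakdown.total == pytest.approx(total, abs=1e-9)

    def test_weighted_sum_identity(self, small_collection):
        coll, _ = small_collection
        cfg = DCMFConfig(latent_dim=3, loss_weights=(2.0, 0.5, 1.0), **FAST)
        model = fit(coll, cfg)
        for h in model.history:
            expected = 2.0 * sum(h.entity_losses.values()) + 0.5 * sum(
                h.view_losses.values()
            )
            assert h.total == pytest.approx(expected, rel=1e-12)

    def test_zero_task_weight_equals_unsupervised(self, small_collection):
        coll, _ = small_collection
        labels = (np.arange(30) % 2).astype(int)
        cfg = DCMFConfig(latent_dim=3, loss_weights=(1, 1, 0), seed=2, **FAST)
        sup = fit(coll, cfg, SupervisedTask("patients", labels))
        uns = fit(coll, cfg)
        for e in coll.entities:
            np.testing.assert_array_equal(
                sup.factors[e].values, uns.factors[e].values
            )
        assert [h.total for h in sup.history] == [h.total for h in uns.history]


class TestFit:
    def test_epochs_zero_history_empty(self, small_collection):
        coll, _ = small_collection
        cfg = DCMFConfig(latent_dim=3, learning_rate=0.01, epochs=0, seed=1)
        model = fit(coll, cfg)
        assert model.history == []
        fresh = init_network(coll, cfg)
        np.testing.assert_array_equal(
            model.factors["patients"].values,
            fresh.encode_entity("patients", fresh.inputs["patients"]).values,
        )

    def test_seeded_runs_reproducible(self, small_collection):
        coll, _ = small_collection
        cfg = DCMFConfig(latent_dim=3, seed=9, **FAST)
        m1, m2 = fit(coll, cfg), fit(coll, cfg)
        assert [h.total for h in m1.history] == [h.total for h in m2.history]
        np.testing.assert_array_equal(
            m1.factors["diseases"].values, m2.factors["diseases"].values
        )

    def test_noiseless_low_rank_recovery(self):
        """Linear-activation training drives the mean relative Frobenius
        view error below 5% on noiseless rank-2 data."""
        spec = synth.SynthSpec(
            entities={"e1": 40, "e2": 30, "e3": 20},
            rank=2,
            noise_sd=0.0,
            views=(("v1", "e1", "e2", "real"), ("v2", "e1", "e3", "real")),
            seed=0,
        )
        coll, _ = synth.simulate_collection(spec)
        cfg = DCMFConfig(latent_dim=2, activation="linear", learning_rate=0.02,
                         weight_decay=0.0, epochs=2500, seed=0)
        model = fit(coll, cfg)
        errs = [
            np.linalg.norm(
                reconstruct_view(
                    model.factors[v.row_entity], model.factors[v.col_entity]
                )
                - v.dense()
            )
            / np.linalg.norm(v.dense())
            for v in coll.views
        ]
        assert np.mean(errs) <= 0.05

    def test_loss_mostly_non_increasing(self, small_collection):
        coll, _ = small_collection
        cfg = DCMFConfig(latent_dim=3, learning_rate=0.005, epochs=200, seed=4)
        model = fit(coll, cfg)
        totals = np.array([h.total for h in model.history])
        frac = np.mean(np.diff(totals) <= 1e-12)
        assert frac >= 0.9

    def test_single_matrix_special_case(self):
        """One matrix, two entities: the collective model degenerates to a
        pair of coupled autoencoders factorizing X ~ U V^T."""
        rng = np.random.default_rng(6)
        u, v = rng.standard_normal((25, 2)), rng.standard_normal((10, 2))
        coll = collection_from_arrays({"X": ("rows", "cols", u @ v.T)})
        cfg = DCMFConfig(latent_dim=2, activation="linear", learning_rate=0.02,
                         weight_decay=0.0, epochs=2500, seed=0)
        model = fit(coll, cfg)
        x_hat = reconstruct_view(model.factors["rows"], model.factors["cols"])
        rel = np.linalg.norm(x_hat - u @ v.T) / np.linalg.norm(u @ v.T)
        assert rel <= 0.05


@pytest.fixture(scope="module")
def trained(small_collection):
    coll, factors = small_collection
    labels = (factors["patients"][:, 0] > 0).astype(int)
    cfg = DCMFConfig(latent_dim=3, learning_rate=0.01, weight_decay=1e-6,
                     epochs=400, seed=0, loss_weights=(1, 1, 1))
    model = fit(coll, cfg, SupervisedTask("patients", labels))
    return model, labels


class TestSupervised:

    def test_training_rows_reproduce_head_outputs(self, trained):
        model, _ = trained
        scores, _ = model.predict(model.inputs["patients"])
        fwd = model._forward()
        np.testing.assert_allclose(scores, fwd["probs"].ravel(), atol=1e-12)

    def test_softmax_rows_sum_to_one(self, small_collection):
        coll, _ = small_collection
        labels = np.arange(30) % 3
        cfg = DCMFConfig(latent_dim=3, epochs=30, learning_rate=0.01, seed=0)
        model = fit(
            coll, cfg, SupervisedTask("patients", labels,
                                      "multiclass_classification")
        )
        scores, y_hat = model.predict(model.inputs["patients"])
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)
        assert scores.shape == (30, 3)
        np.testing.assert_array_equal(y_hat, scores.argmax(axis=1))

    def test_beats_majority_on_factor_sign_labels(self):
        """Held-out accuracy on labels = sign of the first planted factor
        exceeds the 50% majority baseline."""
        spec = synth.SynthSpec(
            entities={"patients": 120, "diseases": 15},
            rank=2,
            noise_sd=0.3,
            views=(("v1", "patients", "diseases", "real"),),
            seed=8,
        )
        coll, factors = synth.simulate_collection(spec)
        labels = (factors["patients"][:, 0] > 0).astype(int)
        cfg = DCMFConfig(latent_dim=2, learning_rate=0.01, epochs=600, seed=0)
        train = np.arange(100)
        mask = np.zeros(120, dtype=bool)
        mask[train] = True
        model = fit(
            coll, cfg,
            SupervisedTask("patients", labels, labeled_mask=mask),
        )
        _, y_hat = model.predict(model.inputs["patients"][100:])
        assert np.mean(y_hat == labels[100:]) > 0.5

    def test_checkpoint_predictor_matches_model(self, trained, tmp_path):
        from dcmflearn.dcmf import load_predictor

        model, _ = trained
        model.save(str(tmp_path / "m.npz"))
        predictor = load_predictor(str(tmp_path / "m.npz"))
        rows = model.inputs["patients"][:5]
        s_model, y_model = model.predict(rows)
        s_ckpt, y_ckpt = predictor.predict(rows)
        np.testing.assert_array_equal(s_model, s_ckpt)
        np.testing.assert_array_equal(y_model, y_ckpt)

    def test_predict_without_head_rejected(self, small_collection):
        coll, _ = small_collection
        model = fit(coll, DCMFConfig(latent_dim=3, epochs=1, **{
            "learning_rate": 0.01, "weight_decay": 0.0}))
        with pytest.raises(ConfigurationError, match="head"):
            model.predict(np.zeros((2, model.inputs["patients"].shape[1])))


class TestRepresentations:
    def test_factor_shapes_and_reencoding(self, small_collection):
        coll, _ = small_collection
        model = fit(coll, DCMFConfig(latent_dim=3, **FAST))
        reps = model.extract_representations()
        assert set(reps) == set(coll.entities)
        for e, ent in coll.entities.items():
            assert reps[e].values.shape == (ent.dim, 3)
            again = model.encode_entity(e, model.inputs[e]).values
            np.testing.assert_array_equal(reps[e].values, again)

    def test_csv_round_trip(self, small_collection, tmp_path):
        coll, _ = small_collection
        model = fit(coll, DCMFConfig(latent_dim=3, **FAST))
        vals = model.factors["patients"].values
        path = tmp_path / "patients.csv"
        np.savetxt(path, vals, delimiter=",",
                   header=",".join(f"k{i}" for i in range(3)), comments="")
        back = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(back, vals, rtol=1e-12)

    def test_factors_feed_downstream_classifier(self, small_collection):
        from sklearn.linear_model import LogisticRegression

        coll, factors = small_collection
        labels = (factors["patients"][:, 0] > 0).astype(int)
        model = fit(coll, DCMFConfig(latent_dim=3, learning_rate=0.01,
                                     weight_decay=0.0, epochs=400, seed=0))
        u = model.factors["patients"].values
        clf = LogisticRegression(max_iter=1000).fit(u[:24], labels[:24])
        assert clf.score(u[24:], labels[24:]) >= 0.5
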