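"""Deep collective matrix factorization (DCMF).

Given a collection of M matrices relating E entity types, one autoencoder
per entity encodes that entity's concatenated matrix ``C^(e)`` into a
latent factor ``U_e`` (the bottleneck) and decodes it back to ``C^(e)'``.
All autoencoders are trained collectively on a joint objective

    L = w_E * sum_e l_E(C^(e), C^(e)') + w_R * sum_m l_R(X_m, U_r U_c^T)
        [+ w_T * l_T(y_T, y')]

where ``l_E`` and ``l_R`` are element-mean squared errors and the optional
task term attaches a single prediction layer to the bottleneck of one
designated entity (patients, typically), turning the model into an
end-to-end supervised predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._nn import MLP, OPTIMIZERS, Affine, softmax, _sigmoid
from .schema import ConcatenatedMatrix, MatrixCollection, concatenate_for_entity

TASK_KINDS = ("binary_classification", "multiclass_classification", "regression")


class ConfigurationError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class DCMFConfig:
    """Training configuration.

    ``latent_dim`` is the bottleneck width k shared by all entities.
    ``hidden_sizes`` lists intermediate encoder layers; the default empty
    tuple gives each autoencoder a single hidden layer — the bottleneck
    itself — with ``activation`` applied (tanh by default), mirrored by a
    linear decoder.  ``loss_weights`` are (w_E, w_R, w_T).
    """

    latent_dim: int = 8
    hidden_sizes: tuple = ()
    activation: str = "tanh"
    learning_rate: float = 1e-5
    weight_decay: float = 1e-6
    epochs: int = 100
    loss_weights: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 0:
            raise ConfigurationError("latent_dim must be >= 1 and epochs >= 0")
        if any(w < 0 for w in self.loss_weights):
            raise ConfigurationError("loss_weights must be non-negative")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class SupervisedTask:
    """Labels for one designated entity, attached via a task head.

    ``labels`` is aligned to the entity's instances (length d_e).  When
    ``labeled_mask`` is given, only masked rows contribute to the task loss
    (the usual train/test protocol: unlabeled rows still participate in the
    reconstruction terms).
    """

    target_entity: str
    labels: np.ndarray
    task_kind: str = "binary_classification"
    head_activation: str | None = None
    task_loss: str | None = None
    labeled_mask: Optional[np.ndarray] = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ConfigurationError(f"unknown task_kind {self.task_kind!r}")
        self.labels = np.asarray(self.labels)
        defaults = {
            "binary_classification": ("sigmoid", "cross_entropy"),
            "multiclass_classification": ("softmax", "cross_entropy"),
            "regression": ("linear", "mean_squared_error"),
        }
        act, loss = defaults[self.task_kind]
        self.head_activation = self.head_activation or act
        self.task_loss = self.task_loss or loss
        if (self.head_activation, self.task_loss) != (act, loss):
            raise ConfigurationError(
                f"head_activation/task_loss inconsistent with {self.task_kind}"
            )
        if self.task_kind == "multiclass_classification":
            if self.n_classes is None:
                self.n_classes = int(self.labels.max()) + 1
        elif self.task_kind == "binary_classification":
            self.n_classes = 2
        if self.labeled_mask is not None:
            self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)

    @property
    def head_width(self) -> int:
        if self.task_kind == "multiclass_classification":
            return self.n_classes
        if self.task_kind == "regression" and self.labels.ndim == 2:
            return self.labels.shape[1]
        return 1


@dataclass
class LatentFactor:
    """Entity representation U_e, one k-vector per instance."""

    entity: str
    values: np.ndarray


@dataclass
class LossBreakdown:
    entity_losses: dict
    view_losses: dict
    task_loss: Optional[float]
    weights: tuple
    total: float = field(init=False)

    def __post_init__(self) -> None:
        w_e, w_r, w_t = self.weights
        self.total = (
            w_e * sum(self.entity_losses.values())
            + w_r * sum(self.view_losses.values())
            + w_t * (self.task_loss or 0.0)
        )

    def worst_term(self) -> tuple[str, float]:
        terms = {f"l_E[{e}]": v for e, v in self.entity_losses.items()}
        terms.update({f"l_R[{m}]": v for m, v in self.view_losses.items()})
        if self.task_loss is not None:
            terms["l_T"] = self.task_loss
        name = max(terms, key=lambda t: abs(terms[t]) if np.isfinite(terms[t]) else np.inf)
        return name, terms[name]


def reconstruct_view(factor_row: LatentFactor, factor_col: LatentFactor) -> np.ndarray:
    """Low-rank view reconstruction U_r U_c^T (rank <= k)."""
    ur, uc = factor_row.values, factor_col.values
    if ur.shape[1] != uc.shape[1]:
        raise ValueError(
            f"latent dim mismatch: {ur.shape[1]} (rows) vs {uc.shape[1]} (cols)"
        )
    return ur @ uc.T


class DCMFModel:
    """One autoencoder per entity plus an optional task head.

    Built by :func:`init_network`; trained by :func:`fit`.  After training,
    ``factors`` holds U_e for every entity and ``history`` one
    :class:`LossBreakdown` per epoch.
    """

    def __init__(self, collection: MatrixCollection, config: DCMFConfig,
                 task: SupervisedTask | None = None):
        self.collection = collection
        self.config = config
        self.task = task
        self.history: list[LossBreakdown] = []
        self.factors: dict[str, LatentFactor] = {}

        if task is not None:
            if task.target_entity not in collection.entities:
                raise ConfigurationError(
                    f"task entity {task.target_entity!r} not in collection"
                )
            d = collection.entities[task.target_entity].dim
            if len(task.labels) != d:
                raise ConfigurationError(
                    f"label count {len(task.labels)} != entity dim {d}"
                )

        self.concats: dict[str, ConcatenatedMatrix] = {}
        self.inputs: dict[str, np.ndarray] = {}
        k = config.latent_dim
        rng = np.random.default_rng(config.seed)
        self.encoders: dict[str, MLP] = {}
        self.decoders: dict[str, MLP] = {}
        for e in collection.entities:
            cm = concatenate_for_entity(collection, e)
            self.concats[e] = cm
            self.inputs[e] = cm.dense()
            w = self.inputs[e].shape[1]
            if k >= w:
                raise ConfigurationError(
                    f"latent_dim {k} >= input width {w} for entity {e!r}"
                )
            hid = list(config.hidden_sizes)
            enc_sizes = [w, *hid, k]
            self.encoders[e] = MLP(
                enc_sizes, [config.activation] * (len(hid) + 1), rng
            )
            dec_sizes = [k, *reversed(hid), w]
            self.decoders[e] = MLP(
                dec_sizes, [config.activation] * len(hid) + ["linear"], rng
            )
        # head init from an independent stream so supervised and unsupervised
        # models share encoder initialization for the same seed
        self.head: Affine | None = None
        if task is not None:
            head_rng = np.random.default_rng([config.seed, 0x7A5])
            self.head = Affine(k, task.head_width, "linear", head_rng)

    # -- forward / losses ---------------------------------------------------

    def _head_outputs(self, u_ep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits = self.head.forward(u_ep)
        if self.task.head_activation == "softmax":
            return logits, softmax(logits)
        if self.task.head_activation == "sigmoid":
            return logits, _sigmoid(logits)
        return logits, logits

    def _forward(self) -> dict:
        u = {e: self.encoders[e].forward(self.inputs[e]) for e in self.encoders}
        c_hat = {e: self.decoders[e].forward(u[e]) for e in self.decoders}
        x_hat = {
            v.id: u[v.row_entity] @ u[v.col_entity].T for v in self.collection.views
        }
        out = {"u": u, "c_hat": c_hat, "x_hat": x_hat}
        if self.task is not None:
            logits, probs = self._head_outputs(u[self.task.target_entity])
            out["logits"], out["probs"] = logits, probs
        return out

    def _task_loss_and_grad(self, fwd: dict) -> tuple[float, np.ndarray]:
        task = self.task
        probs = fwd["probs"]
        mask = (
            task.labeled_mask
            if task.labeled_mask is not None
            else np.ones(len(task.labels), dtype=bool)
        )
        n = int(mask.sum())
        dlogits = np.zeros_like(fwd["logits"])
        eps = 1e-12
        if task.task_kind == "multiclass_classification":
            y = np.zeros((len(task.labels), task.n_classes))
            y[np.arange(len(task.labels)), task.labels.astype(int)] = 1.0
            loss = -np.sum(y[mask] * np.log(probs[mask] + eps)) / n
            dlogits[mask] = (probs[mask] - y[mask]) / n
        elif task.task_kind == "binary_classification":
            y = np.asarray(task.labels, dtype=float).reshape(-1, 1)
            p = probs
            loss = -np.mean(
                y[mask] * np.log(p[mask] + eps)
                + (1 - y[mask]) * np.log(1 - p[mask] + eps)
            )
            dlogits[mask] = (p[mask] - y[mask]) / n
        else:  # regression, linear head, MSE
            y = np.asarray(task.labels, dtype=float).reshape(len(task.labels), -1)
            resid = fwd["logits"][mask] - y[mask]
            loss = float(np.mean(resid**2))
            dlogits[mask] = 2.0 * resid / resid.size
        return float(loss), dlogits

    def _losses(self, fwd: dict) -> LossBreakdown:
        entity_losses = {
            e: float(np.mean((fwd["c_hat"][e] - self.inputs[e]) ** 2))
            for e in self.encoders
        }
        view_losses = {
            v.id: float(np.mean((fwd["x_hat"][v.id] - v.dense()) ** 2))
            for v in self.collection.views
        }
        task_loss = None
        if self.task is not None:
            task_loss, _ = self._task_loss_and_grad(fwd)
        return LossBreakdown(
            entity_losses, view_losses, task_loss, tuple(self.config.loss_weights)
        )

    def _backward(self, fwd: dict) -> None:
        w_e, w_r, w_t = self.config.loss_weights
        for e in self.encoders:
            self.encoders[e].zero_grad()
            self.decoders[e].zero_grad()
        if self.head is not None:
            self.head.zero_grad()

        du = {e: np.zeros_like(fwd["u"][e]) for e in self.encoders}
        for e in self.encoders:
            c = self.inputs[e]
            d_chat = w_e * 2.0 * (fwd["c_hat"][e] - c) / c.size
            du[e] += self.decoders[e].backward(d_chat)
        for v in self.collection.views:
            x = v.dense()
            g = w_r * 2.0 * (fwd["x_hat"][v.id] - x) / x.size
            r, c = v.row_entity, v.col_entity
            if r == c:
                du[r] += g @ fwd["u"][r] + g.T @ fwd["u"][r]
            else:
                du[r] += g @ fwd["u"][c]
                du[c] += g.T @ fwd["u"][r]
        if self.task is not None:
            _, dlogits = self._task_loss_and_grad(fwd)
            du[self.task.target_entity] += self.head.backward(w_t * dlogits)
        for e in self.encoders:
            self.encoders[e].backward(du[e])

    # -- public API ---------------------------------------------------------

    @property
    def params_and_grads(self):
        pg = []
        for e in self.encoders:
            pg.extend(self.encoders[e].params_and_grads)
            pg.extend(self.decoders[e].params_and_grads)
        if self.head is not None:
            pg.extend(self.head.params_and_grads)
        return pg

    def encode_entity(self, entity: str, concat: ConcatenatedMatrix | np.ndarray
                      ) -> LatentFactor:
        """Encode a concatenated matrix (or raw rows in concatenated-input
        coordinates) into the entity's latent factor."""
        rows = concat.dense() if isinstance(concat, ConcatenatedMatrix) else np.asarray(
            concat, dtype=float
        )
        expected = self.inputs[entity].shape[1]
        if rows.shape[1] != expected:
            raise ValueError(
                f"entity {entity!r}: input width {rows.shape[1]} != "
                f"encoder width {expected}"
            )
        return LatentFactor(entity, self.encoders[entity].forward(rows))

    def objective(self) -> LossBreakdown:
        """Evaluate the joint objective at the current parameters."""
        return self._losses(self._forward())

    def refresh_factors(self) -> None:
        for e in self.encoders:
            self.factors[e] = self.encode_entity(e, self.inputs[e])

    def extract_representations(self) -> dict[str, LatentFactor]:
        """Return U_e for every entity, recomputed from the encoders."""
        self.refresh_factors()
        return dict(self.factors)

    def predict(self, new_rows: np.ndarray):
        """Encode new target-entity rows (concatenated-input coordinates)
        and apply the task head.

        Classification returns ``(scores, labels)``: softmax rows sum to 1,
        sigmoid scores lie in [0, 1] with labels thresholded at 0.5.
        Regression returns the linear outputs.
        """
        if self.head is None:
            raise ConfigurationError("model has no task head; fit with a task first")
        u = self.encode_entity(self.task.target_entity, np.asarray(new_rows, float))
        _, out = self._head_outputs(u.values)
        if self.task.task_kind == "multiclass_classification":
            return out, out.argmax(axis=1)
        if self.task.task_kind == "binary_classification":
            scores = out.ravel()
            return scores, (scores >= 0.5).astype(int)
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint: one .npz blob of weights plus a JSON config sidecar."""
        arrays = {}
        for e in self.encoders:
            for tag, mlp in (("enc", self.encoders[e]), ("dec", self.decoders[e])):
                for i, layer in enumerate(mlp.layers):
                    arrays[f"{tag}:{e}:{i}:W"] = layer.W
                    arrays[f"{tag}:{e}:{i}:b"] = layer.b
        if self.head is not None:
            arrays["head:W"] = self.head.W
            arrays["head:b"] = self.head.b
        for e, f in self.factors.items():
            arrays[f"factor:{e}"] = f.values
        np.savez(path, **arrays)
        meta = {
            "config": self.config.__dict__ | {
                "hidden_sizes": list(self.config.hidden_sizes),
                "loss_weights": list(self.config.loss_weights),
            },
            "entities": {e: self.inputs[e].shape[1] for e in self.inputs},
            "task": None
            if self.task is None
            else {
                "target_entity": self.task.target_entity,
                "task_kind": self.task.task_kind,
                "n_classes": self.task.n_classes,
            },
        }
        sidecar = str(path)
        sidecar = sidecar[: -len(".npz")] if sidecar.endswith(".npz") else sidecar
        with open(sidecar + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


class Predictor:
    """A saved model's target-entity encoder plus task head, sufficient
    for prediction on new rows in concatenated-input coordinates."""

    def __init__(self, encoder: MLP, head: Affine, task_kind: str, width: int):
        self.encoder = encoder
        self.head = head
        self.task_kind = task_kind
        self.width = width

    def predict(self, new_rows: np.ndarray):
        rows = np.asarray(new_rows, dtype=float)
        if rows.shape[1] != self.width:
            raise ValueError(
                f"input width {rows.shape[1]} != encoder width {self.width}"
            )
        logits = self.head.forward(self.encoder.forward(rows))
        if self.task_kind == "multiclass_classification":
            probs = softmax(logits)
            return probs, probs.argmax(axis=1)
        if self.task_kind == "binary_classification":
            scores = _sigmoid(logits).ravel()
            return scores, (scores >= 0.5).astype(int)
        return logits


def load_predictor(path: str) -> Predictor:
    """Rebuild the prediction path (target-entity encoder + head) from a
    checkpoint written by :meth:`DCMFModel.save`."""
    base = str(path)
    base = base[: -len(".npz")] if base.endswith(".npz") else base
    with open(base + ".json") as fh:
        meta = json.load(fh)
    if meta["task"] is None:
        raise ConfigurationError("checkpoint has no task head")
    cfg = meta["config"]
    entity = meta["task"]["target_entity"]
    width = meta["entities"][entity]
    hid = list(cfg["hidden_sizes"])
    rng = np.random.default_rng(0)
    encoder = MLP([width, *hid, cfg["latent_dim"]],
                  [cfg["activation"]] * (len(hid) + 1), rng)
    arrays = np.load(base + ".npz" if not str(path).endswith(".npz") else path)
    for i, layer in enumerate(encoder.layers):
        layer.W = arrays[f"enc:{entity}:{i}:W"]
        layer.b = arrays[f"enc:{entity}:{i}:b"]
    n_out = arrays["head:W"].shape[1]
    head = Affine(cfg["latent_dim"], n_out, "linear", rng)
    head.W = arrays["head:W"]
    head.b = arrays["head:b"]
    return Predictor(encoder, head, meta["task"]["task_kind"], width)


def init_network(collection: MatrixCollection, config: DCMFConfig,
                 task: SupervisedTask | None = None) -> DCMFModel:
    """Construct the E dependent autoencoders (plus optional task head)
    with seed-deterministic initial parameters."""
    import warnings

    model = DCMFModel(collection, config, task)
    min_dim = min(e.dim for e in collection.entities.values())
    if config.latent_dim >= min_dim:
        warnings.warn(
            f"latent_dim {config.latent_dim} >= smallest entity dim {min_dim}; "
            "factorizations of views touching that entity are not low-rank",
            stacklevel=2,
        )
    return model


def fit(collection: MatrixCollection, config: DCMFConfig,
        task: SupervisedTask | None = None) -> DCMFModel:
    """Collectively train all autoencoders (and the task head, if any).

    Full-batch training: every epoch performs one optimizer step on the
    gradient of the joint objective over all networks simultaneously.
    Raises :class:`DivergenceError` if the loss goes non-finite.
    """
    model = init_network(collection, config, task)
    opt_cls = OPTIMIZERS[config.optimizer]
    opt = opt_cls(
        model.params_and_grads,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    for epoch in range(config.epochs):
        fwd = model._forward()
        breakdown = model._losses(fwd)
        if not np.isfinite(breakdown.total):
            name, value = breakdown.worst_term()
            raise DivergenceError(
                f"non-finite loss at epoch {epoch}: worst term {name}={value}"
            )
        model._backward(fwd)
        opt.step()
        model.history.append(breakdown)
    model.refresh_factors()
    return model


def random_search(collection: MatrixCollection, base_config: DCMFConfig,
                  param_grid: dict, n_trials: int, seed: int,
                  task: SupervisedTask | None = None):
    """Seeded random search over config fields; returns (best_model, trials).

    ``param_grid`` maps DCMFConfig field names to candidate value lists.
    Ranks by final total loss.  A deliberately simple stand-in for automated
    hyperparameter selection at desk scale.
    """
    rng = np.random.default_rng(seed)
    trials = []
    best = None
    for _ in range(n_trials):
        choice = {k: v[rng.integers(len(v))] for k, v in param_grid.items()}
        cfg = replace(base_config, **choice)
        model = fit(collection, cfg, task)
        score = model.history[-1].total if model.history else model.objective().total
        trials.append((choice, score))
        if best is None or score < best[1]:
            best = (model, score)
    return best[0], trials
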