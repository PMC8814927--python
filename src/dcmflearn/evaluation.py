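"""Train/test protocol, metrics, baselines, and the experiment runner.

The protocol mirrors a standard representation-learning comparison:
repeated random 90/10 splits, unsupervised arms that learn representations
on all instances and then train a downstream classifier on the training
split (a deliberately transductive reading), and a supervised end-to-end
arm that sees labels only for the training split and predicts the test
rows through its task head.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from . import dcmf
from ._nn import MLP, RMSprop
from .schema import MatrixCollection, concatenate_for_entity

VIEW_LEVELS = (1, 2, 3)
MODELS = ("sdae", "cmf", "dcmf", "dcmf_supervised")
CLASSIFIERS = ("lr", "rf", "none")


class ProtocolError(ValueError):
    pass


# ---------------------------------------------------------------- splits --

@dataclass
class SplitPlan:
    n: int
    train_fraction: float
    n_repeats: int
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)


def make_splits(n: int, train_fraction: float = 0.9, n_repeats: int = 3,
                seed: int = 0) -> SplitPlan:
    """Seeded random train/test partitions; |test| = round((1-f) * n)."""
    n_test = int(round((1.0 - train_fraction) * n))
    if n < 10 or n_test < 1:
        raise ProtocolError(f"n={n} too small for a non-empty test split")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return SplitPlan(n, train_fraction, n_repeats, seed, splits)


# ---------------------------------------------------------------- metrics --

@dataclass
class MetricsReport:
    per_repeat: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        keys = [k for k in self.per_repeat[0] if self.per_repeat[0][k] is not None]
        return {
            k: float(np.mean([r[k] for r in self.per_repeat])) for k in keys
        }

    def __getitem__(self, metric: str) -> float:
        return self.mean[metric]


def compute_metrics(y_true, y_pred, scores=None,
                    task_kind: str = "binary_classification") -> dict:
    """Accuracy, macro/weighted F1 and (binary, with scores) AUC.

    Macro F1 averages per-class F1 over the classes present in ``y_true``;
    weighted F1 weights them by support.  AUC uses the rank statistic over
    score thresholds and requires both classes in ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ProtocolError("y_true and y_pred lengths differ")
    labels = np.unique(y_true)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(
            f1_score(y_true, y_pred, labels=labels, average="macro",
                     zero_division=0)
        ),
        "weighted_f1": float(
            f1_score(y_true, y_pred, labels=labels, average="weighted",
                     zero_division=0)
        ),
        "auc": None,
    }
    if task_kind == "binary_classification" and scores is not None:
        if len(labels) < 2:
            raise ProtocolError("AUC undefined: y_true has a single class")
        out["auc"] = float(roc_auc_score(y_true, np.asarray(scores)))
    return out


# ------------------------------------------------------------------ SDAE --

@dataclass
class SDAEConfig:
    """Denoising autoencoder baseline: one sigmoid-encoding hidden layer,
    linear decoding, RMSprop with mini-batches, multiplicative zero-mask
    input corruption."""

    embedding_dim: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 32
    dropout: float = 0.4
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ProtocolError("embedding_dim must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ProtocolError("dropout must lie in [0, 1)")


@dataclass
class SDAEResult:
    representations: np.ndarray
    loss_history: list[float]


def train_sdae_baseline(matrix: np.ndarray, config: SDAEConfig) -> SDAEResult:
    """Train the denoising autoencoder to reconstruct the clean input from
    corrupted input; returns the bottleneck encodings of the clean rows."""
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        raise ProtocolError("empty input matrix")
    n, width = x.shape
    if config.embedding_dim >= width:
        raise ProtocolError(
            f"embedding_dim {config.embedding_dim} >= input width {width}"
        )
    rng = np.random.default_rng(config.seed)
    net = MLP([width, config.embedding_dim, width], ["sigmoid", "linear"], rng)
    opt = RMSprop(net.params_and_grads, lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            clean = x[idx]
            mask = (rng.random(clean.shape) >= config.dropout).astype(float)
            out = net.forward(clean * mask)
            resid = out - clean
            epoch_loss += float(np.sum(resid**2))
            net.zero_grad()
            net.backward(2.0 * resid / resid.size)
            opt.step()
        history.append(epoch_loss / x.size)
    encodings = net.layers[0].forward(x)
    return SDAEResult(encodings, history)


# ------------------------------------------------------- nonneural CMF ----

def fit_cmf_als(collection: MatrixCollection, latent_dim: int,
                n_iters: int = 30, reg: float = 1e-2, seed: int = 0
                ) -> dict[str, np.ndarray]:
    """Minimal alternating-least-squares collective factorization.

    Squared loss with shared factors per entity and ridge regularization;
    each sweep solves every entity's factor given the others.  This is a
    self-contained reimplementation standing in for classical nonneural
    CMF, not a port of any particular package.
    """
    rng = np.random.default_rng(seed)
    factors = {
        e: 0.1 * rng.standard_normal((ent.dim, latent_dim))
        for e, ent in collection.entities.items()
    }
    for _ in range(n_iters):
        for e in collection.entities:
            gram = reg * np.eye(latent_dim)
            rhs = np.zeros((collection.entities[e].dim, latent_dim))
            for v in collection.views:
                if v.row_entity == e and v.col_entity == e:
                    other = factors[e]
                    gram = gram + other.T @ other
                    rhs = rhs + v.dense() @ other
                elif v.row_entity == e:
                    other = factors[v.col_entity]
                    gram = gram + other.T @ other
                    rhs = rhs + v.dense() @ other
                elif v.col_entity == e:
                    other = factors[v.row_entity]
                    gram = gram + other.T @ other
                    rhs = rhs + v.dense().T @ other
            factors[e] = np.linalg.solve(gram, rhs.T).T
    return factors


# ------------------------------------------------------------ experiment --

# latent budget deliberately close to the expected intrinsic dimensionality:
# with ample capacity the reconstruction objective alone retains everything
# and neither supervision nor auxiliary views can add information
_DEFAULT_DCMF = dcmf.DCMFConfig(
    latent_dim=4,
    learning_rate=0.005,
    weight_decay=1e-4,
    epochs=2000,
)


def _downstream(classifier: str, seed: int):
    if classifier == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if classifier == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ProtocolError(f"unknown classifier {classifier!r}")


def valid_combinations() -> list[tuple[int, str, str]]:
    """All admissible (view_level, model, classifier) rows: the denoising
    autoencoder takes one concatenated patient matrix and so cannot absorb
    the square knowledge-graph views of levels 2-3; the supervised model is
    end-to-end and takes no downstream classifier; every other model needs
    one."""
    out = []
    for level in VIEW_LEVELS:
        for model in MODELS:
            if model == "sdae" and level != 1:
                continue
            clfs = ("none",) if model == "dcmf_supervised" else ("lr", "rf")
            out.extend((level, model, clf) for clf in clfs)
    return out


def _validate_combo(view_level: int, model: str, classifier: str) -> None:
    if (view_level, model, classifier) not in valid_combinations():
        raise ProtocolError(
            f"invalid combination ({view_level}, {model!r}, {classifier!r}); "
            f"valid combinations: {valid_combinations()!r}"
        )


def _task_kind(labels: np.ndarray) -> str:
    return ("binary_classification" if len(np.unique(labels)) <= 2
            else "multiclass_classification")


def run_experiment(bundle, view_level: int, model: str, classifier: str = "lr",
                   plan: SplitPlan | None = None, seed: int = 0,
                   dcmf_config: dcmf.DCMFConfig | None = None,
                   sdae_config: SDAEConfig | None = None,
                   supervised_weight: float = 0.25) -> MetricsReport:
    """One row of the model x view comparison grid.

    Unsupervised arms learn patient representations from the chosen view
    level, then train the downstream classifier per split repeat.  The
    supervised arm refits end-to-end per repeat with the task loss masked
    to the training rows and predicts the test rows through the head.
    """
    _validate_combo(view_level, model, classifier)
    labels = np.asarray(bundle.labels)
    task_kind = _task_kind(labels)
    plan = plan or make_splits(len(labels), seed=seed)
    coll = bundle.collections[view_level]
    cfg = replace(dcmf_config or _DEFAULT_DCMF, seed=seed)

    report = MetricsReport()
    if model == "dcmf_supervised":
        sup_cfg = replace(
            cfg, loss_weights=(cfg.loss_weights[0], cfg.loss_weights[1],
                               supervised_weight)
        )
        patient_inputs = concatenate_for_entity(coll, "patients").dense()
        for train_idx, test_idx in plan.splits:
            mask = np.zeros(len(labels), dtype=bool)
            mask[train_idx] = True
            task = dcmf.SupervisedTask("patients", labels, task_kind,
                                       labeled_mask=mask)
            trained = dcmf.fit(coll, sup_cfg, task)
            pred = trained.predict(patient_inputs[test_idx])
            scores, y_hat = pred
            s = scores if task_kind == "binary_classification" else None
            report.per_repeat.append(
                compute_metrics(labels[test_idx], y_hat, s, task_kind)
            )
        return report

    # unsupervised arms: representations once, classifier per repeat
    if model == "sdae":
        scfg = sdae_config or SDAEConfig(
            embedding_dim=min(
                300, concatenate_for_entity(coll, "patients").dense().shape[1] - 1
            ),
            seed=seed,
        )
        reps = train_sdae_baseline(
            concatenate_for_entity(coll, "patients").dense(), scfg
        ).representations
    elif model == "cmf":
        reps = fit_cmf_als(coll, cfg.latent_dim, seed=seed)["patients"]
    else:  # dcmf unsupervised
        reps = dcmf.fit(coll, cfg).factors["patients"].values

    for train_idx, test_idx in plan.splits:
        clf = _downstream(classifier, seed)
        clf.fit(reps[train_idx], labels[train_idx])
        y_hat = clf.predict(reps[test_idx])
        s = None
        if task_kind == "binary_classification":
            s = clf.predict_proba(reps[test_idx])[:, 1]
        report.per_repeat.append(
            compute_metrics(labels[test_idx], y_hat, s, task_kind)
        )
    return report


def experiment_table(bundle, combos=None, seed: int = 0, **kwargs):
    """Long-format results for every (view, model, classifier) combination."""
    import pandas as pd

    rows = []
    for level, model, clf in (combos or valid_combinations()):
        report = run_experiment(bundle, level, model, clf, seed=seed, **kwargs)
        for repeat, metrics in enumerate(report.per_repeat):
            for metric, value in metrics.items():
                if value is None:
                    continue
                rows.append(
                    {"view": level, "model": model, "classifier": clf,
                     "repeat": repeat, "metric": metric, "value": value}
                )
    return pd.DataFrame(rows)
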