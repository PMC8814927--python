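"""Synthetic multi-view data with known latent structure.

Every generator plants ground truth and returns it: view collections are
built from low-rank entity factors plus Gaussian noise, knowledge-graph
edges are drawn with probability increasing in the cosine similarity of
the planted concept factors (so graph structure genuinely reflects the
latent geometry), and labels are driven by the patient factors through a
logistic model.  Component streams are seeded independently, so changing
e.g. the KG seed leaves the views untouched.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import features, kg
from .gra import Graph, GRAParams, SimilarityMatrix
from .schema import MatrixCollection, ViewMatrix, collection_from_arrays

# fixed per-component stream keys mixed with the user seed
_S_FACTORS, _S_VIEWS, _S_KG, _S_LABELS = 101, 211, 307, 401


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass(frozen=True)
class KGEdgeRule:
    """Edge model: P(edge u~v) = floor + (1-floor) * sigmoid(steepness *
    (cos(U*_u, U*_v) - threshold)); a fraction of emitted triplets carry
    NEG-prefixed or excluded predicates to exercise the filter."""

    threshold: float = 0.6
    steepness: float = 8.0
    floor: float = 0.01
    fraction_neg: float = 0.05
    fraction_excluded: float = 0.05


@dataclass(frozen=True)
class LabelModel:
    """Logistic labels on the patient factors.

    Binary: y ~ Bernoulli(sigmoid(U* beta + intercept)); multiclass:
    argmax of the class scores.  ``scale`` is the coefficient standard
    deviation."""

    kind: str = "logistic_on_factors"
    n_classes: int = 2
    scale: float = 1.0
    intercept: float = 0.0


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic data set."""

    entities: dict = field(
        default_factory=lambda: {"patients": 500, "diseases": 50,
                                 "medications": 40, "procedures": 40, "labs": 25}
    )
    rank: int = 3
    views: tuple = ()
    noise_sd: float = 2.0
    binary_quantile: float = 0.5
    count_scale: float = 0.5
    count_shift: float = 0.0
    kg_edge_rule: KGEdgeRule = KGEdgeRule()
    label_model: LabelModel = LabelModel()
    gra_params: GRAParams = GRAParams()
    seed: int = 0
    kg_seed: int | None = None
    label_seed: int | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def draw_factors(spec: SynthSpec) -> dict[str, np.ndarray]:
    """Planted factors U*_e ~ N(0, 1), one d_e x k* matrix per entity."""
    rng = np.random.default_rng([spec.seed, _S_FACTORS])
    return {e: rng.standard_normal((d, spec.rank)) for e, d in spec.entities.items()}


def _materialize_view(base: np.ndarray, kind: str, spec: SynthSpec,
                      rng: np.random.Generator) -> np.ndarray:
    noisy = base + spec.noise_sd * rng.standard_normal(base.shape)
    if kind == "real":
        return noisy
    if kind == "binary":
        return (noisy > np.quantile(noisy, spec.binary_quantile)).astype(float)
    if kind == "count":
        return np.maximum(
            np.round(np.exp(spec.count_scale * noisy + spec.count_shift)) - 1.0, 0.0
        )
    raise ValueError(f"unknown value kind {kind!r}")


def simulate_collection(spec: SynthSpec,
                        factors: dict[str, np.ndarray] | None = None
                        ) -> tuple[MatrixCollection, dict[str, np.ndarray]]:
    """Views X_m = U*_r U*_c^T (+ noise), transformed per value kind.

    Count views use shifted exponentiation then rounding; binary views
    threshold at the configured quantile.  Returns the collection and the
    planted factors.
    """
    factors = factors if factors is not None else draw_factors(spec)
    rng = np.random.default_rng([spec.seed, _S_VIEWS])
    arrays, kinds = {}, {}
    for vid, row, col, kind in spec.views:
        for ent in (row, col):
            if ent not in factors:
                raise ValueError(f"view {vid!r} references undeclared entity {ent!r}")
        base = factors[row] @ factors[col].T
        arrays[vid] = (row, col, _materialize_view(base, kind, spec, rng))
        kinds[vid] = kind
    return collection_from_arrays(arrays, kinds), factors


def simulate_kg(spec: SynthSpec, concept_factors: dict[str, np.ndarray],
                concept_ids: dict[str, list[str]]
                ) -> tuple[list[kg.Triplet], Graph, dict[str, str]]:
    """Triplets and the filtered graph over all concept entities.

    ``concept_factors`` maps entity -> planted factor rows and
    ``concept_ids`` maps entity -> node ids (aligned to factor rows).
    Each sampled pair becomes a triplet; a configurable fraction carry
    NEG-prefixed or excluded predicates, which the standard filter then
    removes, so the returned graph contains only the surviving edges.
    """
    rng = np.random.default_rng(
        [spec.seed if spec.kg_seed is None else spec.kg_seed, _S_KG]
    )
    rule = spec.kg_edge_rule
    ids, rows, types = [], [], {}
    for ent in concept_factors:
        ids.extend(concept_ids[ent])
        rows.append(concept_factors[ent])
        for cid in concept_ids[ent]:
            types[cid] = ent
    u = np.vstack(rows)
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    un = u / np.maximum(norm, 1e-12)
    cos = un @ un.T
    n = len(ids)
    prob = rule.floor + (1.0 - rule.floor) * _sigmoid(
        rule.steepness * (cos - rule.threshold)
    )
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < prob[iu, ju]
    triplets: list[kg.Triplet] = []
    for a, b in zip(iu[hit], ju[hit]):
        r = rng.random()
        if r < rule.fraction_neg:
            pred = "NEG_ASSOCIATED_WITH"
        elif r < rule.fraction_neg + rule.fraction_excluded:
            pred = "PART_OF"
        else:
            pred = "ASSOCIATED_WITH"
        triplets.append(kg.Triplet(ids[a], pred, ids[b]))
    pf = kg.PredicateFilter(vocabulary=types)
    survivors, _ = kg.filter_triplets(triplets, pf)
    graph = kg.build_graph(survivors, types)
    for cid in ids:  # keep isolated concepts as typed nodes for alignment
        graph.add_node(cid, types[cid])
    return triplets, graph, types


def simulate_labels(patient_factors: np.ndarray, label_model: LabelModel,
                    seed: int, n_reference: int = 100_000,
                    return_coefficients: bool = False):
    """Labels from the planted patient factors plus a Bayes-rule reference
    accuracy estimated by Monte Carlo on a fresh holdout.

    With ``return_coefficients`` the drawn coefficient matrix is appended
    to the return tuple so the generative rule can be inspected."""
    if label_model.n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng([seed, _S_LABELS])
    k = patient_factors.shape[1]
    if label_model.n_classes == 2:
        beta = rng.normal(0.0, label_model.scale, size=k)
        p = _sigmoid(patient_factors @ beta + label_model.intercept)
        labels = (rng.random(len(p)) < p).astype(int)
        z = rng.standard_normal((n_reference, k))
        ph = _sigmoid(z @ beta + label_model.intercept)
        bayes = float(np.mean(np.maximum(ph, 1.0 - ph)))
    else:
        beta = rng.normal(0.0, label_model.scale, size=(k, label_model.n_classes))
        scores = patient_factors @ beta + label_model.intercept
        labels = scores.argmax(axis=1)
        bayes = 1.0  # argmax labels are a deterministic function of the factors
    if return_coefficients:
        return labels, bayes, beta
    return labels, bayes


def aligned_similarity(sim: SimilarityMatrix, concept_order: list[str]
                       ) -> np.ndarray:
    """Embed a similarity matrix into a fixed concept order; concepts
    absent from the matrix get zero rows/columns."""
    n = len(concept_order)
    out = np.zeros((n, n))
    pos = {c: i for i, c in enumerate(concept_order)}
    present = [c for c in sim.node_ids if c in pos]
    src = [sim.node_ids.index(c) for c in present]
    dst = [pos[c] for c in present]
    out[np.ix_(dst, dst)] = sim.values[np.ix_(src, src)]
    return out


@dataclass
class Bundle:
    """A full synthetic study: three nested view levels plus ground truth."""

    spec: SynthSpec
    collections: dict[int, MatrixCollection]
    labels: np.ndarray
    bayes_accuracy: float
    factors: dict[str, np.ndarray]
    concept_ids: dict[str, list[str]]
    triplets: list
    graph: Graph


_CONCEPT_PREFIX = {"diseases": "d", "medications": "m", "procedures": "r",
                   "labs": "l"}


def simulate_three_views(spec: SynthSpec | None = None) -> Bundle:
    """Emulate the three nested input configurations.

    Level 1: notes-style concept views (binary diseases, medication and
    procedure counts), TF-IDF transformed.  Level 2: level 1 plus one GRA
    similarity square view per concept type from the simulated knowledge
    graph.  Level 3: level 2 plus structured count views (labs and
    prescribed medications), used raw.
    """
    spec = spec or SynthSpec()
    for ent in ("patients", "diseases", "medications", "procedures", "labs"):
        if ent not in spec.entities:
            raise ValueError(f"three-view bundle needs entity {ent!r}")
    base_views = (
        ("v1_diseases", "patients", "diseases", "binary"),
        ("v2_medications", "patients", "medications", "count"),
        ("v3_procedures", "patients", "procedures", "count"),
        ("v7_labs", "patients", "labs", "count"),
        ("v8_rx", "patients", "medications", "count"),
    )
    spec_all = replace(spec, views=base_views)
    raw, factors = simulate_collection(spec_all)

    concept_ids = {
        ent: [f"{_CONCEPT_PREFIX[ent]}{i:03d}" for i in range(spec.entities[ent])]
        for ent in ("diseases", "medications", "procedures")
    }
    triplets, graph, _types = simulate_kg(
        spec, {e: factors[e] for e in concept_ids}, concept_ids
    )
    # rowmax diagonal: a zero diagonal would drive concept-factor norms to
    # zero through the squared loss on S ~ U_e U_e^T
    sims = kg.type_similarity_matrices(graph, spec.gra_params, diagonal="rowmax")

    tf = {
        vid: features.tfidf(raw.view(vid))
        for vid in ("v1_diseases", "v2_medications", "v3_procedures")
    }
    level1 = {
        vid: (v.row_entity, v.col_entity, v.values)
        for vid, v in tf.items()
    }
    level2 = dict(level1)
    for i, ent in enumerate(("diseases", "medications", "procedures")):
        mat = aligned_similarity(sims[ent], concept_ids[ent])
        level2[f"v{4 + i}_sim_{ent}"] = (ent, ent, mat)
    level3 = dict(level2)
    for vid in ("v7_labs", "v8_rx"):
        v = raw.view(vid)
        level3[vid] = (v.row_entity, v.col_entity, v.values)

    collections = {
        1: collection_from_arrays(level1),
        2: collection_from_arrays(level2),
        3: collection_from_arrays(level3),
    }
    label_seed = spec.seed if spec.label_seed is None else spec.label_seed
    labels, bayes = simulate_labels(factors["patients"], spec.label_model,
                                    label_seed)
    return Bundle(spec, collections, labels, bayes, factors, concept_ids,
                  triplets, graph)


def write_bundle(bundle: Bundle, out_dir: str) -> None:
    """Write manifests, Matrix Market views, triplets and labels so every
    file is consumable by the other command-line entry points."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(out_dir, exist_ok=True)
    written: set[str] = set()
    for level, coll in bundle.collections.items():
        manifest = {}
        for v in coll.views:
            fname = f"{v.id}.mtx"
            if fname not in written:
                mmwrite(os.path.join(out_dir, fname), csr_matrix(v.dense()))
                written.add(fname)
            manifest[v.id] = {
                "file": fname,
                "row_entity": v.row_entity,
                "col_entity": v.col_entity,
                "value_kind": v.value_kind,
            }
        with open(os.path.join(out_dir, f"view{level}.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(os.path.join(out_dir, "triplets.tsv"), "w") as fh:
        fh.write("SUBJECT_CUI\tPREDICATE\tOBJECT_CUI\n")
        for t in bundle.triplets:
            fh.write(f"{t.subject}\t{t.predicate}\t{t.object}\n")
    with open(os.path.join(out_dir, "vocab.tsv"), "w") as fh:
        fh.write("CONCEPT\tTYPE\n")
        for ent, ids in bundle.concept_ids.items():
            for cid in ids:
                fh.write(f"{cid}\t{ent}\n")
    np.savetxt(
        os.path.join(out_dir, "labels.csv"),
        bundle.labels.reshape(len(bundle.labels), -1),
        delimiter=",",
        fmt="%g",
        header="label",
        comments="",
    )
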