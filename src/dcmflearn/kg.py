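"""Knowledge-graph triplet ingestion, filtering, and per-type similarity.

Literature-derived knowledge bases such as SemMedDB organize assertions as
subject-predicate-object triplets over clinical concepts (CUIs).  This
module filters such triplets (dropping ontological predicates, negated
NEG-prefixed assertions, and concepts outside a study vocabulary), builds
an undirected untyped-edge graph from the survivors, and computes one GRA
similarity matrix per concept type over the full heterogeneous graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .gra import Graph, GRAParams, SimilarityMatrix, gra_matrix

DEFAULT_EXCLUDED_PREDICATES = frozenset({"PART_OF", "LOCATION_OF", "PROCESS_OF"})


class Triplet(NamedTuple):
    subject: str
    predicate: str
    object: str


@dataclass
class PredicateFilter:
    """Filtering rules applied to raw triplets.

    Predicates are upper-cased before matching; the negation prefix check
    is case-sensitive on the upper-cased name.  ``vocabulary`` maps allowed
    concept ids to their types; triplets touching a concept outside it are
    dropped.
    """

    excluded_predicates: frozenset = DEFAULT_EXCLUDED_PREDICATES
    negation_prefix: str = "NEG"
    vocabulary: dict[str, str] = field(default_factory=dict)


@dataclass
class FilterTally:
    kept: int = 0
    excluded_predicate: int = 0
    negation: int = 0
    out_of_vocabulary: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_triplets(triplets, pred_filter: PredicateFilter
                    ) -> tuple[list[Triplet], FilterTally]:
    """Apply the predicate and vocabulary filters.

    Checks run in order excluded-predicate, negation, vocabulary; each
    removed triplet is tallied under the first rule it violates.
    Idempotent: survivors pass all three rules.
    """
    kept: list[Triplet] = []
    tally = FilterTally()
    vocab = pred_filter.vocabulary
    for t in triplets:
        t = Triplet(*t)
        pred = t.predicate.upper()
        if pred in pred_filter.excluded_predicates:
            tally.excluded_predicate += 1
        elif pred.startswith(pred_filter.negation_prefix):
            tally.negation += 1
        elif vocab and (t.subject not in vocab or t.object not in vocab):
            tally.out_of_vocabulary += 1
        else:
            kept.append(t)
            tally.kept += 1
    return kept, tally


def build_graph(triplets, types: dict[str, str]) -> Graph:
    """Undirected untyped-edge graph from filtered triplets.

    Multiple triplets between the same concept pair collapse to one edge
    (edges record only that some relation exists); self-relations are
    dropped; concepts in ``types`` but in no surviving triplet are not
    added as nodes.
    """
    graph = Graph()
    for t in triplets:
        t = Triplet(*t)
        if t.subject == t.object:
            continue
        for concept in (t.subject, t.object):
            if concept not in types:
                raise KeyError(f"concept {concept!r} missing from the type map")
            graph.add_node(concept, types[concept])
        graph.add_edge(t.subject, t.object)
    return graph


def type_similarity_matrices(graph: Graph, params: GRAParams,
                             diagonal: str = "zero"
                             ) -> dict[str, SimilarityMatrix]:
    """One square GRA similarity matrix per node type.

    Similarities are computed on the full heterogeneous graph, so paths may
    pass through nodes of other types.  Types with fewer than two nodes are
    omitted with a warning.  Node order within each matrix follows node
    insertion order, for stable alignment with patient-view columns.
    """
    if not graph.node_types:
        raise ValueError("empty graph")
    out: dict[str, SimilarityMatrix] = {}
    for node_type in dict.fromkeys(graph.node_types.values()):
        members = graph.nodes_of_type(node_type)
        if len(members) < 2:
            warnings.warn(
                f"type {node_type!r} has {len(members)} node(s); similarity "
                "matrix omitted",
                stacklevel=2,
            )
            continue
        out[node_type] = gra_matrix(graph, members, params, diagonal=diagonal)
    return out


def read_triplets_tsv(path) -> list[Triplet]:
    """TSV with columns SUBJECT_CUI, PREDICATE, OBJECT_CUI."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Triplet(r.SUBJECT_CUI, r.PREDICATE, r.OBJECT_CUI)
        for r in df.itertuples(index=False)
    ]


def read_vocabulary_tsv(path) -> dict[str, str]:
    """TSV with columns CONCEPT, TYPE -> concept-to-type mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["CONCEPT"], df["TYPE"]))


def load_example_triplets() -> tuple[list[Triplet], dict[str, str]]:
    """The packaged 10-triplet example with its 6-concept vocabulary.

    Synthetic fixture mimicking PREDICATION-table extracts: exactly two
    triplets carry excluded predicates, one is NEG-prefixed, and two touch
    out-of-vocabulary concepts, leaving five survivors.
    """
    data = resources.files("dcmflearn").joinpath("data")
    with resources.as_file(data.joinpath("example_triplets.tsv")) as p:
        triplets = read_triplets_tsv(p)
    with resources.as_file(data.joinpath("example_vocab.tsv")) as p:
        vocab = read_vocabulary_tsv(p)
    return triplets, vocab
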