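"""Per-episode concept matrices and TF-IDF weighting.

Concept-mention records (one row per episode/concept pair with a mention
count, as produced by clinical NLP concept extraction) are assembled into
episode x concept views: presence/absence for diseases, raw counts for
medications, procedures and labs.  Each episode is treated as a document
and each concept as a term for the TF-IDF transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .schema import ViewMatrix

CONCEPT_TYPES = ("disease", "medication", "procedure", "lab")


class ConceptMention(NamedTuple):
    episode: str
    concept: str
    concept_type: str
    count: int


@dataclass(frozen=True)
class TfidfConfig:
    """``smooth`` idf is ln((1+N)/(1+df)) + 1; ``plain`` is ln(N/df) + 1.
    ``raw`` tf uses the cell value; ``log`` uses 1 + ln(value) on nonzero
    cells."""

    idf_variant: str = "smooth"
    tf_variant: str = "raw"

    def __post_init__(self) -> None:
        if self.idf_variant not in ("smooth", "plain"):
            raise ValueError(f"unknown idf_variant {self.idf_variant!r}")
        if self.tf_variant not in ("raw", "log"):
            raise ValueError(f"unknown tf_variant {self.tf_variant!r}")


def build_concept_matrix(mentions, concept_type: str, episodes: list[str],
                         concepts: list[str], view_id: str | None = None,
                         row_entity: str = "episodes",
                         col_entity: str | None = None) -> ViewMatrix:
    """Assemble the episode x concept view for one concept type.

    Disease views are binary (presence of the concept in the episode);
    other types are count views summing mention counts.  Rows follow
    ``episodes``, columns follow ``concepts``; pairs without mentions are
    zero.  Mentions of other concept types are ignored; an unknown episode
    or concept id raises ``KeyError`` naming it.
    """
    if concept_type not in CONCEPT_TYPES:
        raise ValueError(f"unknown concept_type {concept_type!r}")
    erow = {e: i for i, e in enumerate(episodes)}
    ccol = {c: j for j, c in enumerate(concepts)}
    mat = np.zeros((len(episodes), len(concepts)))
    for m in mentions:
        m = ConceptMention(*m)
        if m.concept_type != concept_type:
            continue
        if m.episode not in erow:
            raise KeyError(f"unknown episode id {m.episode!r}")
        if m.concept not in ccol:
            raise KeyError(f"unknown concept id {m.concept!r}")
        if m.count < 1:
            raise ValueError(f"mention count must be >= 1, got {m.count}")
        mat[erow[m.episode], ccol[m.concept]] += m.count
    kind = "binary" if concept_type == "disease" else "count"
    if kind == "binary":
        mat = (mat > 0).astype(float)
    return ViewMatrix(
        view_id or f"{concept_type}_mentions",
        row_entity,
        col_entity or concept_type,
        mat,
        kind,
    )


def read_mentions_tsv(path) -> list[ConceptMention]:
    """TSV with columns EPISODE, CONCEPT, TYPE, COUNT."""
    df = pd.read_csv(path, sep="\t", dtype={"EPISODE": str, "CONCEPT": str})
    return [
        ConceptMention(r.EPISODE, r.CONCEPT, r.TYPE, int(r.COUNT))
        for r in df.itertuples(index=False)
    ]


def tfidf(view: ViewMatrix, config: TfidfConfig = TfidfConfig()) -> ViewMatrix:
    """TF-IDF weighting of a non-negative episode x concept view.

    cell(i, j) = tf(i, j) * idf(j) with N = number of episodes and
    df_j = number of episodes mentioning concept j.  The smooth variant
    keeps idf finite for all-zero columns; zero cells stay zero either
    way.  Returns a real-valued view with the same shape and entities.
    """
    x = view.dense()
    if (x < 0).any():
        raise ValueError("tfidf requires a non-negative input view")
    n = x.shape[0]
    df = (x > 0).sum(axis=0).astype(float)
    if config.idf_variant == "smooth":
        idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    else:
        idf = np.where(df > 0, np.log(n / np.maximum(df, 1.0)) + 1.0, 0.0)
    if config.tf_variant == "log":
        tf = np.where(x > 0, 1.0 + np.log(x, out=np.zeros_like(x), where=x > 0), 0.0)
    else:
        tf = x
    return ViewMatrix(
        view.id + "_tfidf", view.row_entity, view.col_entity, tf * idf, "real"
    )
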