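"""Data model for augmented multi-view matrix collections.

A *view* is a matrix relating two entity types (e.g. patients x diseases);
a *collection* is an arbitrary set of views over a shared pool of entities.
The input-transformation step assembles, for each entity ``e``, the
concatenated matrix ``C^(e)`` from every view touching ``e`` (transposed
where ``e`` indexes the columns).  ``C^(e)`` is the input to the entity's
autoencoder during collective factorization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

VALUE_KINDS = ("binary", "count", "real")


class SchemaError(ValueError):
    """Invalid collection structure (dimension conflicts, unknown entities...)."""


@dataclass(frozen=True)
class EntityType:
    """An entity type whose ``dim`` instances index matrix rows or columns."""

    id: str
    dim: int

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise SchemaError(f"entity {self.id!r}: dim must be >= 1, got {self.dim}")


@dataclass
class ViewMatrix:
    """A single matrix relating a row entity to a column entity.

    ``values`` may be a dense ndarray or a scipy sparse matrix; ``value_kind``
    declares the measurement type and is validated against the cells.
    """

    id: str
    row_entity: str
    col_entity: str
    values: object
    value_kind: str = "real"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(
                f"view {self.id!r}: value_kind must be one of {VALUE_KINDS}"
            )
        if not (sp.issparse(self.values) or isinstance(self.values, np.ndarray)):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError(f"view {self.id!r}: values must be 2-D")
        data = self.values.data if sp.issparse(self.values) else self.values
        if self.value_kind == "binary":
            if data.size and not np.isin(np.unique(data), (0, 1)).all():
                raise SchemaError(f"view {self.id!r}: binary view has non-0/1 cells")
        elif self.value_kind == "count":
            if data.size and ((data < 0).any() or np.any(data != np.round(data))):
                raise SchemaError(
                    f"view {self.id!r}: count view has negative or non-integer cells"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class MatrixCollection:
    """The set of entities and the views relating them."""

    entities: dict[str, EntityType]
    views: list[ViewMatrix]

    def __post_init__(self) -> None:
        for v in self.views:
            for side in (v.row_entity, v.col_entity):
                if side not in self.entities:
                    raise SchemaError(f"view {v.id!r}: unknown entity {side!r}")
            er, ec = self.entities[v.row_entity], self.entities[v.col_entity]
            if v.shape != (er.dim, ec.dim):
                raise SchemaError(
                    f"view {v.id!r}: shape {v.shape} conflicts with entity dims "
                    f"({v.row_entity}={er.dim}, {v.col_entity}={ec.dim})"
                )
        ids = [v.id for v in self.views]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate view ids in collection")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.entities)

    def view(self, view_id: str) -> ViewMatrix:
        for v in self.views:
            if v.id == view_id:
                return v
        raise KeyError(view_id)

    def views_for_entity(self, entity: str) -> list[ViewMatrix]:
        return [
            v for v in self.views if entity in (v.row_entity, v.col_entity)
        ]

    def entity_view_graph(self) -> nx.Graph:
        """Bipartite graph with entity nodes and view nodes."""
        g = nx.Graph()
        for e in self.entities:
            g.add_node(("entity", e))
        for v in self.views:
            g.add_node(("view", v.id))
            g.add_edge(("entity", v.row_entity), ("view", v.id))
            g.add_edge(("entity", v.col_entity), ("view", v.id))
        return g


@dataclass(frozen=True)
class Block:
    """One column block of a concatenated matrix."""

    view_id: str
    orientation: str  # "as-is" | "transposed"
    offset: int
    width: int


@dataclass
class ConcatenatedMatrix:
    """``C^(e)``: side-by-side assembly of all views touching one entity."""

    entity: str
    values: object
    blocks: list[Block]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def block_values(self, view_id: str) -> np.ndarray:
        """Recover one original view (re-transposed) from its block."""
        for b in self.blocks:
            if b.view_id == view_id:
                sub = self.dense()[:, b.offset : b.offset + b.width]
                return sub.T if b.orientation == "transposed" else sub
        raise KeyError(view_id)


@dataclass
class Diagnostics:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def load_matrix(path: str):
    """Read a matrix from Matrix Market (.mtx) or labelled CSV.

    CSV files carry a header row of column labels and row labels in the first
    column; only the numeric body is returned.
    """
    if path.endswith((".mtx", ".mtx.gz")):
        from scipy.io import mmread

        return mmread(path)
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float)


def collection_from_arrays(
    views: dict[str, tuple[str, str, object]],
    value_kinds: dict[str, str] | None = None,
) -> MatrixCollection:
    """Build a collection from in-memory arrays.

    ``views`` maps view id -> (row_entity, col_entity, matrix).  Entity dims
    are inferred from the matrices and cross-checked.
    """
    value_kinds = value_kinds or {}
    dims: dict[str, int] = {}
    vms: list[ViewMatrix] = []
    for vid, (re_, ce, mat) in views.items():
        mat = mat if sp.issparse(mat) else np.asarray(mat, dtype=float)
        for ent, d in ((re_, mat.shape[0]), (ce, mat.shape[1])):
            if ent in dims and dims[ent] != d:
                raise SchemaError(
                    f"view {vid!r}: entity {ent!r} dim {d} conflicts with "
                    f"previously inferred dim {dims[ent]}"
                )
            dims.setdefault(ent, d)
        vms.append(ViewMatrix(vid, re_, ce, mat, value_kinds.get(vid, "real")))
    entities = {e: EntityType(e, d) for e, d in dims.items()}
    return MatrixCollection(entities, vms)


def build_collection(manifest, base_dir: str | None = None) -> MatrixCollection:
    """Load a collection from a YAML manifest (path or parsed mapping).

    The manifest maps view id -> ``{file, row_entity, col_entity, value_kind}``.
    Entity dims are inferred from the matrix files and cross-checked; a
    conflict between two views sharing an entity raises :class:`SchemaError`
    naming both views.
    """
    if isinstance(manifest, (str, os.PathLike)):
        base_dir = base_dir or os.path.dirname(os.fspath(manifest))
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    base_dir = base_dir or "."

    dims: dict[str, tuple[int, str]] = {}  # entity -> (dim, first view id)
    vms: list[ViewMatrix] = []
    for vid, entry in manifest.items():
        path = os.path.join(base_dir, entry["file"])
        mat = load_matrix(path)
        re_, ce = entry["row_entity"], entry["col_entity"]
        for ent, d in ((re_, mat.shape[0]), (ce, mat.shape[1])):
            if ent in dims and dims[ent][0] != d:
                raise SchemaError(
                    f"entity {ent!r}: dim {d} in view {vid!r} conflicts with dim "
                    f"{dims[ent][0]} in view {dims[ent][1]!r}"
                )
            dims.setdefault(ent, (d, vid))
        vms.append(ViewMatrix(str(vid), re_, ce, mat, entry.get("value_kind", "real")))
    entities = {e: EntityType(e, d) for e, (d, _) in dims.items()}
    return MatrixCollection(entities, vms)


def validate_collection(collection: MatrixCollection) -> Diagnostics:
    """Structural diagnostics: reports, never raises.

    Errors: entities in zero views.  Warnings: disconnected entity-view
    graph, constant columns within a view.
    """
    diag = Diagnostics()
    for e in collection.entities:
        if not collection.views_for_entity(e):
            diag.errors.append(f"entity {e!r} appears in no view")
    g = collection.entity_view_graph()
    if g.number_of_nodes() and not nx.is_connected(g):
        n = nx.number_connected_components(g)
        diag.warnings.append(f"entity-view graph has {n} connected components")
    for v in collection.views:
        dense = v.dense()
        n_const = int(np.sum(np.ptp(dense, axis=0) == 0)) if dense.shape[0] > 1 else 0
        if n_const:
            diag.warnings.append(f"view {v.id!r} has {n_const} constant column(s)")
    return diag


def concatenate_for_entity(
    collection: MatrixCollection, entity: str
) -> ConcatenatedMatrix:
    """Assemble ``C^(e)`` for one entity.

    Views with ``e`` on the rows contribute as-is, views with ``e`` on the
    columns contribute transposed; a square self-view (``e`` on both sides)
    contributes exactly one block, as-is.  Blocks are ordered by position in
    the collection's view list, so the result is deterministic for a given
    collection.
    """
    if entity not in collection.entities:
        raise SchemaError(f"unknown entity {entity!r}")
    parts, blocks, offset = [], [], 0
    for v in collection.views:
        if entity not in (v.row_entity, v.col_entity):
            continue
        if v.row_entity == entity:
            mat, orient = v.values, "as-is"
        else:
            mat, orient = v.values.T, "transposed"
        w = mat.shape[1]
        parts.append(mat)
        blocks.append(Block(v.id, orient, offset, w))
        offset += w
    if not parts:
        raise SchemaError(f"entity {entity!r} participates in no view")
    if any(sp.issparse(p) for p in parts):
        values = sp.hstack([sp.csr_matrix(p) for p in parts], format="csr")
    else:
        values = np.hstack([np.asarray(p, dtype=float) for p in parts])
    return ConcatenatedMatrix(entity, values, blocks)
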