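"""Directed kNN spatial graphs with node/edge features, normalization, merging.

Each cell is a node; directed edges point from a cell to its k nearest
other cells by Euclidean centroid distance.  Node features are the
confidence plus the ten morphology columns (N x 11).  Each edge carries a
categorical type code (``src_type * T + dst_type``), a closeness
(reciprocal centroid distance in 1/pixels) and a parallelism (|cos| of the
angle between the two major axes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ceograph.cell_io import CellTable, CellTypeScheme, NODE_FEATURES, wrap_orientation

DEFAULT_K = 8  # neighbor count covering the adjacent nuclei of each cell


class DegenerateInputError(ValueError):
    """Graph construction needs at least two cells."""


@dataclass
class SpatialGraph:
    """A directed cell spatial graph for one image patch (or merged slide)."""

    node_features: np.ndarray  # (N, 11) float64, columns = NODE_FEATURES
    node_types: np.ndarray  # (N,) int64 indices into scheme.names
    node_xy: np.ndarray  # (N, 2) float64 centroids, pixels
    node_orientation: np.ndarray  # (N,) float64 degrees in [0, 180)
    edges: np.ndarray  # (e, 2) int64 [source, target]
    edge_type: np.ndarray  # (e,) int64 codes in [0, T^2)
    edge_closeness: np.ndarray  # (e,) float64 > 0
    edge_parallelism: np.ndarray  # (e,) float64 in [0, 1]
    scheme: CellTypeScheme
    k: int
    patch_id: str = ""
    slide_id: str = ""
    patient_id: str = ""
    label: int | None = None
    normalized: bool = False

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    def subgroup_mask(self) -> np.ndarray:
        idx = self.scheme.subgroup_indices()
        return np.isin(self.node_types, idx)


def edge_parallelism(theta_n: float | np.ndarray, theta_m: float | np.ndarray) -> float | np.ndarray:
    """|cos| of the angle between two nuclear major axes given in degrees.

    Axial quantity: adding 180 degrees to either angle leaves it unchanged;
    identical orientations give 1, perpendicular ones give 0.
    """
    delta = np.deg2rad(np.asarray(theta_n, dtype=float) - np.asarray(theta_m, dtype=float))
    out = np.abs(np.cos(delta))
    return float(out) if out.ndim == 0 else out


def edge_closeness(p_n: Sequence[float], p_m: Sequence[float], *, clamp_px: float | None = None) -> float:
    """Reciprocal Euclidean distance between two centroids, in 1/pixels.

    Coincident centroids are an error unless ``clamp_px`` gives a minimum
    distance to clamp to.
    """
    d = float(np.hypot(p_n[0] - p_m[0], p_n[1] - p_m[1]))
    if d == 0.0:
        if clamp_px is None:
            raise ValueError("closeness undefined for coincident centroids")
        d = clamp_px
    elif clamp_px is not None:
        d = max(d, clamp_px)
    return 1.0 / d


def edge_type_code(src_type: int, dst_type: int, n_types: int) -> int:
    """Categorical edge-type code ``src * T + dst``; bijective over [0, T^2)."""
    if not (0 <= src_type < n_types and 0 <= dst_type < n_types):
        raise IndexError(f"type index out of range for T={n_types}: ({src_type}, {dst_type})")
    return src_type * n_types + dst_type


def _knn_edges(xy: np.ndarray, k: int) -> np.ndarray:
    """Directed kNN edge list with deterministic (distance, index) tie-break."""
    n = xy.shape[0]
    k_eff = min(k, n - 1)
    dist = cdist(xy, xy)
    np.fill_diagonal(dist, np.inf)
    # lexsort-based argsort: primary key distance, secondary ascending index
    idx = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
    src = np.repeat(np.arange(n, dtype=np.int64), k_eff)
    dst = idx.astype(np.int64).reshape(-1)
    return np.stack([src, dst], axis=1)


def build_graph(
    table: CellTable,
    scheme: CellTypeScheme,
    k: int = DEFAULT_K,
    *,
    coincident_clamp_px: float | None = None,
    label: int | None = None,
) -> SpatialGraph:
    """Build the directed kNN spatial graph of one cell table.

    Every node gets out-edges to its ``min(k, N-1)`` nearest other cells;
    distance ties are broken by ascending cell index.  Raises
    :class:`DegenerateInputError` for tables with fewer than two cells.
    """
    n = len(table)
    if n < 2:
        raise DegenerateInputError(f"patch {table.patch_id!r}: need >= 2 cells to build a graph, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")

    xy = np.array([[r.x, r.y] for r in table.records], dtype=np.float64)
    types = np.array([scheme.index(r.cell_type) for r in table.records], dtype=np.int64)
    orient = wrap_orientation(np.array([r.orientation for r in table.records], dtype=np.float64))
    feats = np.array(
        [[r.confidence, *r.morphology] for r in table.records], dtype=np.float64
    )
    assert feats.shape[1] == len(NODE_FEATURES)

    edges = _knn_edges(xy, k)
    src, dst = edges[:, 0], edges[:, 1]
    d = np.linalg.norm(xy[src] - xy[dst], axis=1)
    if np.any(d == 0.0):
        if coincident_clamp_px is None:
            raise ValueError(f"patch {table.patch_id!r}: coincident centroids make closeness undefined")
        d = np.maximum(d, coincident_clamp_px)
    closeness = 1.0 / d
    parallelism = edge_parallelism(orient[src], orient[dst])
    etype = types[src] * scheme.n_types + types[dst]

    return SpatialGraph(
        node_features=feats,
        node_types=types,
        node_xy=xy,
        node_orientation=orient,
        edges=edges,
        edge_type=etype,
        edge_closeness=closeness,
        edge_parallelism=np.asarray(parallelism, dtype=np.float64),
        scheme=scheme,
        k=k,
        patch_id=table.patch_id,
        slide_id=table.slide_id,
        patient_id=table.patient_id,
        label=label,
    )


@dataclass
class NormalizationStats:
    """Per-column node-feature moments fitted on a training corpus."""

    mean: np.ndarray  # (F,)
    std: np.ndarray  # (F,) epsilon-guarded, always >= epsilon
    epsilon: float = 1e-8

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist(), "epsilon": self.epsilon}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=np.asarray(d["mean"], dtype=np.float64), std=np.asarray(d["std"], dtype=np.float64), epsilon=float(d["epsilon"]))


def fit_normalization(graphs: Iterable[SpatialGraph], epsilon: float = 1e-8) -> NormalizationStats:
    """Fit global center/scale stats over all nodes of a training corpus."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot fit normalization on an empty corpus")
    stacked = np.concatenate([g.node_features for g in graphs], axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    if np.any(std < epsilon):
        constant = [NODE_FEATURES[i] for i in np.nonzero(std < epsilon)[0]]
        warnings.warn(f"constant node-feature column(s) guarded with epsilon: {constant}", stacklevel=2)
    std = np.maximum(std, epsilon)
    return NormalizationStats(mean=mean, std=std, epsilon=epsilon)


def apply_normalization(graph: SpatialGraph, stats: NormalizationStats) -> SpatialGraph:
    """Return a copy of ``graph`` with globally centered and scaled node features."""
    feats = (graph.node_features - stats.mean) / stats.std
    return replace(graph, node_features=feats, normalized=True)


def merge_slide_graphs(graphs: Sequence[SpatialGraph]) -> SpatialGraph:
    """Disjoint-union merge of all patch graphs of one slide.

    Node indices are offset per component; no cross-component edges are
    introduced.  All inputs must share ``slide_id`` and scheme.
    """
    if not graphs:
        raise ValueError("merge_slide_graphs needs a non-empty list")
    slide_ids = {g.slide_id for g in graphs}
    if len(slide_ids) > 1:
        raise ValueError(f"cannot merge graphs from different slides: {sorted(slide_ids)}")
    schemes = {g.scheme.names for g in graphs}
    if len(schemes) > 1:
        raise ValueError("cannot merge graphs with different cell-type schemes")

    offsets = np.cumsum([0] + [g.n_nodes for g in graphs[:-1]])
    edges = np.concatenate([g.edges + off for g, off in zip(graphs, offsets)], axis=0)
    labels = {g.label for g in graphs}
    g0 = graphs[0]
    return SpatialGraph(
        node_features=np.concatenate([g.node_features for g in graphs], axis=0),
        node_types=np.concatenate([g.node_types for g in graphs]),
        node_xy=np.concatenate([g.node_xy for g in graphs], axis=0),
        node_orientation=np.concatenate([g.node_orientation for g in graphs]),
        edges=edges,
        edge_type=np.concatenate([g.edge_type for g in graphs]),
        edge_closeness=np.concatenate([g.edge_closeness for g in graphs]),
        edge_parallelism=np.concatenate([g.edge_parallelism for g in graphs]),
        scheme=g0.scheme,
        k=g0.k,
        patch_id=g0.slide_id,
        slide_id=g0.slide_id,
        patient_id=g0.patient_id,
        label=labels.pop() if len(labels) == 1 else None,
        normalized=all(g.normalized for g in graphs),
    )


# ---------------------------------------------------------------------------
# On-disk bundle: one JSON file per graph so graphs stay inspectable as text.

def save_graph(graph: SpatialGraph, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format": "ceograph-graph/1",
        "patch_id": graph.patch_id,
        "slide_id": graph.slide_id,
        "patient_id": graph.patient_id,
        "label": graph.label,
        "k": graph.k,
        "normalized": graph.normalized,
        "scheme": {"names": list(graph.scheme.names), "subgroup": sorted(graph.scheme.subgroup)},
        "node_features": graph.node_features.tolist(),
        "node_types": graph.node_types.tolist(),
        "node_xy": graph.node_xy.tolist(),
        "node_orientation": graph.node_orientation.tolist(),
        "edges": graph.edges.tolist(),
        "edge_type": graph.edge_type.tolist(),
        "edge_closeness": graph.edge_closeness.tolist(),
        "edge_parallelism": graph.edge_parallelism.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_graph(path: str | Path) -> SpatialGraph:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ceograph-graph/1":
        raise ValueError(f"{path}: not a ceograph graph bundle")
    scheme = CellTypeScheme(names=tuple(payload["scheme"]["names"]), subgroup=frozenset(payload["scheme"]["subgroup"]))
    return SpatialGraph(
        node_features=np.asarray(payload["node_features"], dtype=np.float64),
        node_types=np.asarray(payload["node_types"], dtype=np.int64),
        node_xy=np.asarray(payload["node_xy"], dtype=np.float64),
        node_orientation=np.asarray(payload["node_orientation"], dtype=np.float64),
        edges=np.asarray(payload["edges"], dtype=np.int64).reshape(-1, 2),
        edge_type=np.asarray(payload["edge_type"], dtype=np.int64),
        edge_closeness=np.asarray(payload["edge_closeness"], dtype=np.float64),
        edge_parallelism=np.asarray(payload["edge_parallelism"], dtype=np.float64),
        scheme=scheme,
        k=int(payload["k"]),
        patch_id=payload["patch_id"],
        slide_id=payload["slide_id"],
        patient_id=payload["patient_id"],
        label=payload["label"],
        normalized=bool(payload["normalized"]),
    )
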