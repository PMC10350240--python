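import numpy as np
import pytest

from ceograph.cell_io import LUNG6
from ceograph.graph_build import SpatialGraph, apply_normalization, build_graph, fit_normalization
from ceograph.synthetic import SyntheticSpec, generate_patch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(n_cells: int, seed: int = 0, **spec_kwargs):
    spec = SyntheticSpec(cells_per_patch=(n_cells, n_cells), **spec_kwargs)
    return generate_patch(spec, 0, seed)


def make_graph(n_cells: int, seed: int = 0, k: int = 8, normalized: bool = False, **spec_kwargs):
    g = build_graph(make_table(n_cells, seed, **spec_kwargs), LUNG6, k=k)
    if normalized:
        g = apply_normalization(g, fit_normalization([g]))
    return g


def random_graph(rng: np.random.Generator, n: int, k: int = 4, n_types: int = 6) -> SpatialGraph:
    """A small random spatial graph with arbitrary (non-physical) features."""
    from ceograph.cell_io import CellTypeScheme

    scheme = CellTypeScheme(names=tuple(f"t{i}" for i in range(n_types)), subgroup=frozenset({"t0"}))
    xy = rng.uniform(0, 500, size=(n, 2))
    types = rng.integers(n_types, size=n)
    types[0] = 0  # guarantee a non-empty pooling subgroup
    orient = rng.uniform(0, 180, size=n)
    from ceograph.graph_build import _knn_edges

    edges = _knn_edges(xy, k)
    src, dst = edges[:, 0], edges[:, 1]
    d = np.linalg.norm(xy[src] - xy[dst], axis=1)
    return SpatialGraph(
        node_features=rng.normal(size=(n, 11)),
        node_types=types,
        node_xy=xy,
        node_orientation=orient,
        edges=edges,
        edge_type=types[src] * n_types + types[dst],
        edge_closeness=1.0 / d,
        edge_parallelism=np.abs(np.cos(np.deg2rad(orient[src] - orient[dst]))),
        scheme=scheme,
        k=k,
        patch_id="rand",
        slide_id="rand",
        patient_id="rand",
        label=0,
        normalized=True,
    )


@pytest.fixture
def small_graph():
    return make_graph(30, seed=1, k=4, normalized=True)
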