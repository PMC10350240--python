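import dataclasses

import numpy as np
import pandas as pd
import pytest

from ceograph.autodiff import cross_entropy_with_logits
from ceograph.cell_io import CellTypeScheme, NODE_FEATURES
from ceograph.graph_build import SpatialGraph
from ceograph.interpret import (
    ContributionReport,
    feature_contributions,
    node_probabilities,
    spatial_contribution_map,
    summarize_contributions,
)
from ceograph.model import CeographModel, ModelConfig

from conftest import random_graph


def make_model(rng, n_layers=3, hidden=8, pooling="subgroup"):
    preset = {3: "lung_subtype", 4: "opmd_risk"}[n_layers]
    cfg = ModelConfig.preset(preset, hidden=hidden, pooling=pooling)
    model = CeographModel(cfg, 36, 11, rng)
    for layer in model.layers:  # nonzero modulation so edge gradients are exercised
        layer.film_scale_weight.data = rng.normal(0, 0.3, layer.film_scale_weight.data.shape)
        layer.film_shift_weight.data = rng.normal(0, 0.3, layer.film_shift_weight.data.shape)
    return model


def chain_graph(n_nodes: int) -> SpatialGraph:
    """Directed path 0 -> 1 -> ... -> n-1; only node 0 is in the subgroup."""
    scheme = CellTypeScheme(names=tuple(f"t{i}" for i in range(6)), subgroup=frozenset({"t0"}))
    types = np.ones(n_nodes, dtype=np.int64)
    types[0] = 0
    edges = np.array([[i, i + 1] for i in range(n_nodes - 1)], dtype=np.int64)
    rng = np.random.default_rng(0)
    return SpatialGraph(
        node_features=rng.normal(size=(n_nodes, 11)),
        node_types=types,
        node_xy=np.column_stack([np.arange(n_nodes) * 10.0, np.zeros(n_nodes)]),
        node_orientation=np.zeros(n_nodes),
        edges=edges,
        edge_type=types[edges[:, 0]] * 6 + types[edges[:, 1]],
        edge_closeness=np.full(n_nodes - 1, 0.1),
        edge_parallelism=np.ones(n_nodes - 1),
        scheme=scheme,
        k=1,
        patch_id="chain",
        normalized=True,
    )


class TestNodeProbabilities:
    def test_zero_outputs_uniform(self):
        assert np.allclose(node_probabilities(np.zeros((1, 2))), [[0.5, 0.5]])

    def test_rows_sum_to_one(self, rng):
        p = node_probabilities(rng.normal(size=(20, 3)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_independent_softmax(self, rng):
        x = rng.normal(size=(10, 4))
        expected = np.exp(x) / np.exp(x).sum(axis=1, keepdims=True)
        assert np.allclose(node_probabilities(x), expected)


class TestFeatureContributions:
    def test_finite_difference_agreement(self, rng):
        g = random_graph(rng, 15, k=3)
        model = make_model(rng)
        report = feature_contributions(g, model, 0, raw_scale=False)

        def loss(graph):
            logits, _ = model.forward_tensors(graph)
            return float(cross_entropy_with_logits(logits, 0).data)

        eps = 1e-5
        for _ in range(10):
            if rng.uniform() < 0.7:
                i, j = int(rng.integers(g.n_nodes)), int(rng.integers(11))
                up, down = g.node_features.copy(), g.node_features.copy()
                up[i, j] += eps
                down[i, j] -= eps
                fd = (loss(dataclasses.replace(g, node_features=up)) - loss(dataclasses.replace(g, node_features=down))) / (2 * eps)
                an = report.node_feature_gradients.iloc[i, j]
            else:
                e = int(rng.integers(g.n_edges))
                col = int(rng.integers(2))
                arr = g.edge_closeness if col == 0 else g.edge_parallelism
                up, down = arr.copy(), arr.copy()
                up[e] += eps
                down[e] -= eps
                key = "edge_closeness" if col == 0 else "edge_parallelism"
                fd = (loss(dataclasses.replace(g, **{key: up})) - loss(dataclasses.replace(g, **{key: down}))) / (2 * eps)
                an = report.edge_feature_gradients.iloc[e, col]
            if abs(fd) > 1e-10:
                assert abs(fd - an) / abs(fd) < 1e-4

    def test_receptive_field_locality(self, rng):
        # chain 0 <- pooled; with 3 layers only nodes 0..3 can influence the loss
        g = chain_graph(8)
        model = make_model(rng, n_layers=3)
        report = feature_contributions(g, model, 0, raw_scale=False)
        grads = report.node_feature_gradients.to_numpy()
        assert np.any(grads[:4] != 0.0)
        assert np.all(grads[4:] == 0.0)
        # edge gradients beyond the horizon vanish too: edges 4.. start past the field
        edge_grads = report.edge_feature_gradients.to_numpy()
        assert np.all(edge_grads[3:] == 0.0)

    def test_four_layer_model_sees_one_hop_further(self, rng):
        g = chain_graph(8)
        model = make_model(rng, n_layers=4)
        grads = feature_contributions(g, model, 0, raw_scale=False).node_feature_gradients.to_numpy()
        assert np.any(grads[4] != 0.0)
        assert np.all(grads[5:] == 0.0)

    def test_reference_class_sign_flip(self, rng):
        g = random_graph(rng, 12, k=3)
        model = make_model(rng)
        r0 = feature_contributions(g, model, 0, raw_scale=False)
        r1 = feature_contributions(g, model, 1, raw_scale=False)
        a = r0.node_feature_gradients.to_numpy()
        b = r1.node_feature_gradients.to_numpy()
        nz = np.abs(a) > 1e-12
        assert np.all(np.sign(a[nz]) == -np.sign(b[nz]))

    def test_raw_scale_chain_rule(self, rng):
        from ceograph.graph_build import NormalizationStats

        g = random_graph(rng, 10, k=3)
        model = make_model(rng)
        std = rng.uniform(0.5, 2.0, size=11)
        stats = NormalizationStats(mean=np.zeros(11), std=std)
        norm = feature_contributions(g, model, 0, raw_scale=False).node_feature_gradients.to_numpy()
        raw = feature_contributions(g, model, 0, stats=stats, raw_scale=True).node_feature_gradients.to_numpy()
        assert np.allclose(raw, norm / std)

    def test_normalized_graph_requires_stats(self, rng):
        g = random_graph(rng, 10)
        model = make_model(rng)
        with pytest.raises(ValueError, match="NormalizationStats"):
            feature_contributions(g, model, 0, raw_scale=True)

    def test_reference_class_out_of_range(self, rng):
        g = random_graph(rng, 10)
        model = make_model(rng)
        with pytest.raises(IndexError):
            feature_contributions(g, model, 5, raw_scale=False)

    def test_node_probability_rows_sum_to_one(self, rng):
        g = random_graph(rng, 10)
        model = make_model(rng)
        report = feature_contributions(g, model, 0, raw_scale=False)
        assert np.allclose(report.node_probabilities.sum(axis=1), 1.0, atol=1e-9)


class TestSummaries:
    def _report(self, grads, types, patch="p"):
        n = len(types)
        return ContributionReport(
            node_probabilities=np.full((n, 2), 0.5),
            node_feature_gradients=pd.DataFrame(grads, columns=list(NODE_FEATURES)),
            edge_feature_gradients=pd.DataFrame(columns=["closeness", "parallelism"], dtype=float),
            reference_class=0,
            node_types=np.asarray(types),
            edge_types=np.zeros(0, dtype=int),
            type_names=("tumor", "stroma", "lymphocyte", "red_blood_cell", "macrophage", "karyorrhexis"),
            patch_id=patch,
        )

    def test_single_report_single_group(self, rng):
        grads = rng.normal(size=(9, 11))
        report = self._report(grads, [0] * 9)
        out = summarize_contributions([report], "cell_type", "eccentricity")
        assert len(out) == 1
        col = grads[:, list(NODE_FEATURES).index("eccentricity")]
        assert out["median"].iloc[0] == pytest.approx(np.median(col))
        assert out["count"].iloc[0] == 9

    def test_disjoint_sign_groups(self):
        grads = np.zeros((6, 11))
        idx = list(NODE_FEATURES).index("area")
        grads[:3, idx] = [1.0, 2.0, 3.0]
        grads[3:, idx] = [-1.0, -2.0, -3.0]
        report = self._report(grads, [0, 0, 0, 1, 1, 1])
        out = summarize_contributions([report], "cell_type", "area").set_index("group")
        assert out.loc["tumor", "median"] > 0 > out.loc["stroma", "median"]

    def test_matches_brute_force_pooling(self, rng):
        reports = [self._report(rng.normal(size=(12, 11)), rng.integers(3, size=12), patch=f"p{i}") for i in range(4)]
        out = summarize_contributions(reports, "cell_type", "solidity").set_index("group")
        idx = list(NODE_FEATURES).index("solidity")
        pooled = {}
        for r in reports:
            for t, v in zip(r.node_types, r.node_feature_gradients.iloc[:, idx]):
                pooled.setdefault(r.type_names[t], []).append(v)
        for name, vals in pooled.items():
            assert out.loc[name, "median"] == pytest.approx(np.median(vals))
            assert out.loc[name, "q1"] == pytest.approx(np.quantile(vals, 0.25))

    def test_unknown_feature_raises(self, rng):
        report = self._report(rng.normal(size=(3, 11)), [0, 0, 0])
        with pytest.raises(KeyError):
            summarize_contributions([report], "cell_type", "nope")


class TestSpatialMap:
    def test_table_has_n_finite_rows(self, rng, tmp_path):
        g = random_graph(rng, 20)
        model = make_model(rng)
        report = feature_contributions(g, model, 0, raw_scale=False)
        fig, table = spatial_contribution_map(
            g, report, out_path=tmp_path / "map.png", table_path=tmp_path / "map.csv"
        )
        assert len(table) == g.n_nodes
        assert np.all(np.isfinite(table["score"]))
        assert (tmp_path / "map.png").exists()
        assert (tmp_path / "map.csv").exists()

    def test_uniform_probabilities_uniform_scores(self, rng):
        g = random_graph(rng, 10)
        model = make_model(rng)
        report = feature_contributions(g, model, 0, raw_scale=False)
        report.node_probabilities[:] = 0.5
        _, table = spatial_contribution_map(g, report)
        assert np.allclose(table["score"], table["score"].iloc[0])

    def test_colors_monotone_in_score(self, rng):
        g = random_graph(rng, 15)
        model = make_model(rng)
        report = feature_contributions(g, model, 0, raw_scale=False)
        fig, table = spatial_contribution_map(g, report, color_by="gradient")
        score = table["score"].to_numpy()
        mapped = np.asarray(fig.axes[0].collections[0].get_array())
        # the scatter's color-mapped values are exactly the scores, with a
        # symmetric diverging normalization, so color position is monotone
        assert np.allclose(mapped, score)
        norm = fig.axes[0].collections[0].norm
        positions = norm(score)
        order = np.argsort(score)
        assert np.all(np.diff(np.asarray(positions)[order]) >= 0)
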