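"""Prediction interpretation: node probabilities and input-gradient contributions.

Two complementary views.  First, because graph-level supervision acts as
weak supervision at the node level, a per-nucleus probability is the
softmax of each node's last-layer output.  Second, the contribution of
every continuous input feature is the exact partial derivative of the
cross-entropy between the graph probability and a chosen reference class,
taken with respect to that feature: a positive derivative means that
increasing the feature pushes the prediction away from the reference
class.  Node-feature gradients are reported on the raw (pre-normalization)
scale by default via the chain rule through the persisted normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ceograph.autodiff import Tensor, cross_entropy_with_logits, softmax
from ceograph.cell_io import NODE_FEATURES
from ceograph.graph_build import NormalizationStats, SpatialGraph
from ceograph.model import CeographModel

EDGE_FEATURES = ("closeness", "parallelism")


@dataclass
class ContributionReport:
    """Per-node probabilities plus input-feature gradients for one graph."""

    node_probabilities: np.ndarray  # (N, K)
    node_feature_gradients: pd.DataFrame  # N rows x NODE_FEATURES columns
    edge_feature_gradients: pd.DataFrame  # e rows x (closeness, parallelism)
    reference_class: int
    node_types: np.ndarray  # (N,) type indices (grouping key)
    edge_types: np.ndarray  # (e,) type codes (grouping key)
    type_names: tuple[str, ...]
    patch_id: str = ""
    raw_scale: bool = True

    def node_type_names(self) -> np.ndarray:
        return np.asarray(self.type_names)[self.node_types]

    def edge_type_names(self) -> np.ndarray:
        t = len(self.type_names)
        names = np.asarray(self.type_names)
        return np.array([f"{names[c // t]}->{names[c % t]}" for c in self.edge_types])


def node_probabilities(node_outputs: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the last-layer node outputs."""
    return softmax(np.asarray(node_outputs, dtype=np.float64), axis=-1)


def feature_contributions(
    graph: SpatialGraph,
    model: CeographModel,
    reference_class: int,
    *,
    stats: NormalizationStats | None = None,
    raw_scale: bool = True,
) -> ContributionReport:
    """Exact input-feature gradients of the reference-class cross-entropy.

    One backward pass yields the derivative of the loss with respect to
    every continuous node feature and every continuous edge feature
    (closeness, parallelism); the categorical edge type has no derivative
    and serves only as a grouping key.  Dropout is disabled (evaluation
    mode).  With ``raw_scale`` and fitted ``stats``, node gradients are
    divided by the per-column standard deviation so they refer to the
    original feature units.
    """
    if not (0 <= reference_class < model.config.k_categories):
        raise IndexError(f"reference class {reference_class} out of range")
    x = Tensor(graph.node_features, requires_grad=True)
    edge_wa = Tensor(
        np.stack([graph.edge_closeness, graph.edge_parallelism], axis=1)
        if graph.n_edges
        else np.zeros((0, 2)),
        requires_grad=True,
    )
    logits, h = model.forward_tensors(graph, training=False, x=x, edge_wa=edge_wa)
    loss = cross_entropy_with_logits(logits, reference_class)
    loss.backward()

    node_grad = x.grad if x.grad is not None else np.zeros_like(x.data)
    edge_grad = edge_wa.grad if edge_wa.grad is not None else np.zeros_like(edge_wa.data)
    if raw_scale:
        if graph.normalized and stats is None:
            raise ValueError("raw-scale gradients on a normalized graph require NormalizationStats")
        if stats is not None:
            node_grad = node_grad / stats.std
    return ContributionReport(
        node_probabilities=node_probabilities(h.data),
        node_feature_gradients=pd.DataFrame(node_grad, columns=list(NODE_FEATURES)),
        edge_feature_gradients=pd.DataFrame(edge_grad, columns=list(EDGE_FEATURES)),
        reference_class=reference_class,
        node_types=graph.node_types.copy(),
        edge_types=graph.edge_type.copy(),
        type_names=graph.scheme.names,
        patch_id=graph.patch_id,
        raw_scale=raw_scale,
    )


def summarize_contributions(
    reports: Iterable[ContributionReport],
    group_by: Literal["cell_type", "edge_type"],
    feature: str,
) -> pd.DataFrame:
    """Quartiles, median and counts of one feature's contributions per group.

    Groups are cell types (node features) or source->target edge types
    (edge features), pooled over all supplied reports.
    """
    frames = []
    for r in reports:
        if group_by == "cell_type":
            if feature not in r.node_feature_gradients.columns:
                raise KeyError(f"unknown node feature {feature!r}")
            frames.append(pd.DataFrame({"group": r.node_type_names(), "value": r.node_feature_gradients[feature]}))
        elif group_by == "edge_type":
            if feature not in r.edge_feature_gradients.columns:
                raise KeyError(f"unknown edge feature {feature!r}")
            frames.append(pd.DataFrame({"group": r.edge_type_names(), "value": r.edge_feature_gradients[feature]}))
        else:
            raise KeyError(f"unknown grouping key {group_by!r}")
    if not frames:
        raise ValueError("summarize_contributions needs a non-empty corpus")
    pooled = pd.concat(frames, ignore_index=True)
    summary = pooled.groupby("group")["value"].agg(
        count="count",
        q1=lambda v: v.quantile(0.25),
        median="median",
        q3=lambda v: v.quantile(0.75),
        mean="mean",
    )
    return summary.reset_index().sort_values("group").reset_index(drop=True)


def spatial_contribution_map(
    graph: SpatialGraph,
    report: ContributionReport,
    out_path: str | Path | None = None,
    *,
    color_by: Literal["probability", "gradient"] = "probability",
    feature: str = "eccentricity",
    table_path: str | Path | None = None,
):
    """Scatter overlay of per-node scores at cell centroids.

    ``probability`` colors by the signed difference between the non-reference
    and reference class node probability (binary tasks); ``gradient`` colors
    by the gradient of the chosen node feature.  Returns the matplotlib
    figure and the per-node table also written to ``table_path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if color_by == "probability":
        k = report.reference_class
        other = 1 - k if report.node_probabilities.shape[1] == 2 else np.argmax(
            np.delete(np.arange(report.node_probabilities.shape[1]), k)
        )
        score = report.node_probabilities[:, other] - report.node_probabilities[:, k]
        label = "P(non-reference) - P(reference)"
    else:
        score = report.node_feature_gradients[feature].to_numpy()
        label = f"dL/d({feature})"

    table = pd.DataFrame(
        {
            "x": graph.node_xy[:, 0],
            "y": graph.node_xy[:, 1],
            "cell_type": report.node_type_names(),
            "score": score,
        }
    )
    if table_path is not None:
        table_path = Path(table_path)
        table_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(table_path, index=False)

    fig, ax = plt.subplots(figsize=(6, 6))
    lim = max(float(np.abs(score).max()), 1e-12)
    sc = ax.scatter(table["x"], table["y"], c=score, cmap="coolwarm", vmin=-lim, vmax=lim, s=12)
    ax.invert_yaxis()  # image convention: y downward
    ax.set_aspect("equal")
    ax.set_title(f"{graph.patch_id} ({label})")
    fig.colorbar(sc, ax=ax, label=label)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig, table
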