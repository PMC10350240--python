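"""Task-level networks: stacked convolution layers, pooling readout, softmax.

The last layer's width equals the number of prediction categories K, so
subgroup (or global) mean pooling of the final node outputs directly gives
the graph logits, and a softmax turns them into the graph probability.
The per-node outputs are retained so the interpretation module can form
per-nucleus probabilities from the same quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ceograph.autodiff import Tensor, mean_rows, softmax
from ceograph.csigc import CSIGCParams, LayerConfig, count_parameters, csigc_forward
from ceograph.graph_build import SpatialGraph


@dataclass
class ModelConfig:
    """Architecture description for one task preset."""

    n_layers: int
    channels: tuple[int, ...]  # per-layer widths; last equals K
    pooling: Literal["subgroup", "global"]
    k_categories: int
    dropout_rate: float = 0.2
    message_source: Literal["neighbor", "self_as_printed"] = "neighbor"
    film_per_element: bool = False
    final_activation: bool = False  # last layer defaults to pass-through logits
    task_preset: str | None = None

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_layers:
            raise ValueError("channels must list one width per layer")
        if self.channels[-1] != self.k_categories:
            raise ValueError("last layer width must equal the category count K")

    @classmethod
    def preset(cls, name: str, *, k_categories: int = 2, hidden: int = 16, **overrides) -> "ModelConfig":
        """Instantiate a task preset.

        ``lung_subtype``: 3 layers, tumor-subgroup pooling.
        ``opmd_risk``: 4 layers (larger receptive field), epithelial pooling.
        ``tki_response``: 3 layers, global pooling over merged slide graphs.
        """
        if name == "lung_subtype":
            cfg = dict(n_layers=3, channels=(hidden, hidden, k_categories), pooling="subgroup")
        elif name == "opmd_risk":
            cfg = dict(n_layers=4, channels=(hidden, hidden, hidden, k_categories), pooling="subgroup")
        elif name == "tki_response":
            cfg = dict(n_layers=3, channels=(hidden, hidden, k_categories), pooling="global")
        else:
            raise ValueError(f"unknown task preset {name!r}")
        cfg.update(overrides)
        return cls(k_categories=k_categories, task_preset=name, **cfg)


def subgroup_mean_pool(node_outputs: np.ndarray, node_types: np.ndarray, subgroup_indices: Sequence[int]) -> np.ndarray:
    """Average node outputs over nodes whose type is in the subgroup.

    Global pooling is the special case where the subgroup covers all types.
    """
    mask = np.isin(node_types, np.asarray(list(subgroup_indices), dtype=np.int64))
    if not mask.any():
        raise ValueError("subgroup mean pooling over an empty subgroup")
    return np.asarray(node_outputs)[mask].mean(axis=0)


def graph_probability(x_graph: np.ndarray) -> np.ndarray:
    """Softmax of the pooled graph logits."""
    x_graph = np.asarray(x_graph, dtype=np.float64)
    if not np.all(np.isfinite(x_graph)):
        raise ValueError("graph logits must be finite")
    return softmax(x_graph)


class CeographModel:
    """A stack of edge-conditioned convolution layers with a pooling readout."""

    def __init__(self, config: ModelConfig, n_edge_types: int, f_in: int, rng: np.random.Generator | None = None):
        self.config = config
        self.n_edge_types = n_edge_types
        self.f_in = f_in
        rng = rng or np.random.default_rng(0)
        self.layers: list[CSIGCParams] = []
        self.layer_configs: list[LayerConfig] = []
        width = f_in
        for i, c in enumerate(config.channels):
            last = i == config.n_layers - 1
            self.layers.append(
                CSIGCParams.init(n_edge_types, width, c, rng, film_per_element=config.film_per_element)
            )
            self.layer_configs.append(
                LayerConfig(
                    c=c,
                    dropout_rate=config.dropout_rate,
                    activation=(not last) or config.final_activation,
                    message_source=config.message_source,
                    film_per_element=config.film_per_element,
                )
            )
            width = c

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [t for layer in self.layers for t in layer.tensors()]

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.zero_grad()

    def n_parameters(self) -> int:
        return sum(count_parameters(layer) for layer in self.layers)

    # -- forward ------------------------------------------------------------

    def _pool_mask(self, graph: SpatialGraph) -> np.ndarray:
        if self.config.pooling == "global":
            mask = np.ones(graph.n_nodes, dtype=bool)
        else:
            mask = graph.subgroup_mask()
            if not mask.any():
                raise ValueError(f"patch {graph.patch_id!r}: no pooling-subgroup nodes; apply patch filters first")
        return mask

    def forward_tensors(
        self,
        graph: SpatialGraph,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
        x: Tensor | None = None,
        edge_wa: Tensor | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Run the stack; return (graph logits, last-layer node outputs) as tensors.

        ``x``/``edge_wa`` let callers pass leaf tensors with
        ``requires_grad`` for input-feature attribution.
        """
        if x is None:
            x = Tensor(graph.node_features)
        h = x
        for params, cfg in zip(self.layers, self.layer_configs):
            h = csigc_forward(graph, h, params, cfg, training=training, edge_wa=edge_wa, rng=rng)
        logits = mean_rows(h, self._pool_mask(graph))
        return logits, h

    def forward(
        self, graph: SpatialGraph, *, training: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (P_graph, last-layer node outputs) as plain arrays."""
        logits, h = self.forward_tensors(graph, training=training, rng=rng)
        return graph_probability(logits.data), h.data

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_layers": self.config.n_layers,
                "channels": list(self.config.channels),
                "pooling": self.config.pooling,
                "k_categories": self.config.k_categories,
                "dropout_rate": self.config.dropout_rate,
                "message_source": self.config.message_source,
                "film_per_element": self.config.film_per_element,
                "final_activation": self.config.final_activation,
                "task_preset": self.config.task_preset,
            },
            "n_edge_types": self.n_edge_types,
            "f_in": self.f_in,
            "layers": [layer.to_dict() for layer in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CeographModel":
        cfg = d["config"]
        config = ModelConfig(
            n_layers=cfg["n_layers"],
            channels=tuple(cfg["channels"]),
            pooling=cfg["pooling"],
            k_categories=cfg["k_categories"],
            dropout_rate=cfg["dropout_rate"],
            message_source=cfg["message_source"],
            film_per_element=cfg["film_per_element"],
            final_activation=cfg["final_activation"],
            task_preset=cfg.get("task_preset"),
        )
        model = cls(config, n_edge_types=d["n_edge_types"], f_in=d["f_in"])
        model.layers = [CSIGCParams.from_dict(ld) for ld in d["layers"]]
        return model

    def state_copy(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for t, arr in zip(self.parameters(), state):
            t.data = arr.copy()
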