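"""Edge-conditioned graph convolution over cell spatial graphs.

One layer maps N x F_in node features to N x c outputs.  Per directed edge
(n -> m) the categorical edge type selects a flattened F_in x c modulator
from an embedding table; the modulator is adjusted by feature-wise linear
modulation driven by the edge's closeness and parallelism; the neighbor's
feature vector is multiplied through it to form a message.  Each node adds
its self-transform to the average of its out-edge messages, followed by an
optional ReLU and training-time dropout.

:func:`csigc_forward_naive` is a literal per-node/per-edge loop kept as an
independent reference for testing the vectorized path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ceograph.autodiff import Tensor, segment_mean
from ceograph.graph_build import SpatialGraph


@dataclass
class LayerConfig:
    """Per-layer behavior switches."""

    c: int
    dropout_rate: float = 0.2
    activation: bool = True  # ReLU + dropout; final layers pass through
    message_source: Literal["neighbor", "self_as_printed"] = "neighbor"
    film_per_element: bool = False  # per-(F_in x c)-element modulation instead of per-channel

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("output channel count c must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class CSIGCParams:
    """Learnable state of one layer.

    ``edge_type_embedding`` has one flattened (F_in * c) modulator row per
    edge-type code.  ``film_scale/shift`` map the 2-vector (closeness,
    parallelism) to per-channel gamma/beta; modulation is applied as
    ``mo * (1 + gamma) + beta`` so zero-initialized modulation is identity.
    """

    edge_type_embedding: Tensor  # (T^2, F_in * c)
    self_transform: Tensor  # (F_in, c)
    film_scale_weight: Tensor  # (2, c) or (2, F_in * c) per-element
    film_scale_bias: Tensor  # (c,) or (F_in * c,)
    film_shift_weight: Tensor
    film_shift_bias: Tensor
    f_in: int
    c: int
    n_edge_types: int

    @classmethod
    def init(
        cls,
        n_edge_types: int,
        f_in: int,
        c: int,
        rng: np.random.Generator,
        *,
        film_per_element: bool = False,
    ) -> "CSIGCParams":
        if c < 1:
            raise ValueError("output channel count c must be >= 1")
        if f_in < 1 or n_edge_types < 1:
            raise ValueError("f_in and n_edge_types must be >= 1")
        width = f_in * c if film_per_element else c
        scale = 1.0 / np.sqrt(f_in)
        return cls(
            edge_type_embedding=Tensor(rng.normal(0.0, scale, size=(n_edge_types, f_in * c)), requires_grad=True),
            self_transform=Tensor(rng.normal(0.0, scale, size=(f_in, c)), requires_grad=True),
            film_scale_weight=Tensor(np.zeros((2, width)), requires_grad=True),
            film_scale_bias=Tensor(np.zeros(width), requires_grad=True),
            film_shift_weight=Tensor(np.zeros((2, width)), requires_grad=True),
            film_shift_bias=Tensor(np.zeros(width), requires_grad=True),
            f_in=f_in,
            c=c,
            n_edge_types=n_edge_types,
        )

    def tensors(self) -> list[Tensor]:
        return [
            self.edge_type_embedding,
            self.self_transform,
            self.film_scale_weight,
            self.film_scale_bias,
            self.film_shift_weight,
            self.film_shift_bias,
        ]

    def to_dict(self) -> dict:
        return {
            "edge_type_embedding": self.edge_type_embedding.data.tolist(),
            "self_transform": self.self_transform.data.tolist(),
            "film_scale_weight": self.film_scale_weight.data.tolist(),
            "film_scale_bias": self.film_scale_bias.data.tolist(),
            "film_shift_weight": self.film_shift_weight.data.tolist(),
            "film_shift_bias": self.film_shift_bias.data.tolist(),
            "f_in": self.f_in,
            "c": self.c,
            "n_edge_types": self.n_edge_types,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSIGCParams":
        def t(key: str) -> Tensor:
            return Tensor(np.asarray(d[key], dtype=np.float64), requires_grad=True)

        return cls(
            edge_type_embedding=t("edge_type_embedding"),
            self_transform=t("self_transform"),
            film_scale_weight=t("film_scale_weight"),
            film_scale_bias=t("film_scale_bias"),
            film_shift_weight=t("film_shift_weight"),
            film_shift_bias=t("film_shift_bias"),
            f_in=int(d["f_in"]),
            c=int(d["c"]),
            n_edge_types=int(d["n_edge_types"]),
        )


def count_parameters(params: CSIGCParams) -> int:
    """Number of stored scalar parameters of one layer.

    Per-channel modulation: ``T^2 * F_in * c + F_in * c + 2 * (2 + 1) * c``
    (embedding table, self transform, and two affine maps from the
    closeness/parallelism pair to c channels, each with bias).
    """
    if params.c < 1:
        raise ValueError("output channel count c must be >= 1")
    return sum(int(np.prod(t.data.shape)) for t in params.tensors())


def _validate_shapes(graph: SpatialGraph, params: CSIGCParams, x_shape: tuple[int, ...]) -> None:
    if x_shape[1] != params.f_in:
        raise ValueError(f"node feature width {x_shape[1]} != layer F_in {params.f_in}")
    if graph.n_edges and int(graph.edge_type.max()) >= params.n_edge_types:
        raise ValueError(
            f"edge type code {int(graph.edge_type.max())} out of range for {params.n_edge_types} edge types"
        )


def csigc_forward(
    graph: SpatialGraph,
    x: Tensor,
    params: CSIGCParams,
    config: LayerConfig,
    *,
    training: bool = False,
    edge_wa: Tensor | None = None,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Vectorized layer forward pass.

    ``x`` is the (N, F_in) node-feature tensor (layer input, possibly the
    previous layer's output).  ``edge_wa`` optionally supplies the (e, 2)
    closeness/parallelism tensor so callers can differentiate with respect
    to edge features; by default it is taken from the graph as constants.
    """
    _validate_shapes(graph, params, x.shape)
    n, f_in, c = x.shape[0], params.f_in, config.c
    src, dst = graph.edges[:, 0], graph.edges[:, 1]

    if graph.n_edges > 0:
        if edge_wa is None:
            edge_wa = Tensor(np.stack([graph.edge_closeness, graph.edge_parallelism], axis=1))
        mo = params.edge_type_embedding.gather_rows(graph.edge_type)  # (e, F_in*c)
        gamma = edge_wa @ params.film_scale_weight + params.film_scale_bias
        beta = edge_wa @ params.film_shift_weight + params.film_shift_bias
        if config.film_per_element:
            mo = mo * (gamma + 1.0) + beta
            mo = mo.reshape(-1, f_in, c)
        else:
            mo = mo.reshape(-1, f_in, c)
            mo = mo * (gamma + 1.0).reshape(-1, 1, c) + beta.reshape(-1, 1, c)
        x_msg = x.gather_rows(dst if config.message_source == "neighbor" else src)  # (e, F_in)
        me = (x_msg.reshape(-1, f_in, 1) * mo).sum(axis=1)  # (e, c)
        agg = segment_mean(me, src, n)
    else:
        agg = Tensor(np.zeros((n, c)))

    out = x @ params.self_transform + agg
    if config.activation:
        out = out.relu()
        if training and config.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training dropout requires an rng")
            keep = 1.0 - config.dropout_rate
            mask = (rng.random(out.shape) < keep) / keep
            out = out * Tensor(mask)
    return out


def csigc_forward_naive(
    graph: SpatialGraph,
    x: np.ndarray,
    params: CSIGCParams,
    config: LayerConfig,
    *,
    training: bool = False,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Literal per-node, per-edge loop transcription of the layer; test oracle.

    Deterministic: training-time dropout must be supplied as an explicit
    mask (already scaled), since the naive path owns no RNG.
    """
    _validate_shapes(graph, params, x.shape)
    n, f_in, c = x.shape[0], params.f_in, config.c
    em = params.edge_type_embedding.data
    theta = params.self_transform.data
    wg, bg = params.film_scale_weight.data, params.film_scale_bias.data
    wb, bb = params.film_shift_weight.data, params.film_shift_bias.data

    out = np.zeros((n, c), dtype=np.float64)
    for node in range(n):
        messages = []
        for ei in np.nonzero(graph.edges[:, 0] == node)[0]:
            m = graph.edges[ei, 1]
            wa = np.array([graph.edge_closeness[ei], graph.edge_parallelism[ei]])
            mo = em[graph.edge_type[ei]].copy()  # flattened (F_in*c)
            gamma = wa @ wg + bg
            beta = wa @ wb + bb
            if config.film_per_element:
                mo = mo * (1.0 + gamma) + beta
                mo = mo.reshape(f_in, c)
            else:
                mo = mo.reshape(f_in, c)
                mo = mo * (1.0 + gamma)[None, :] + beta[None, :]
            x_source = x[m] if config.message_source == "neighbor" else x[node]
            messages.append(x_source @ mo)
        me_self = x[node] @ theta
        if messages:
            out[node] = me_self + np.mean(messages, axis=0)
        else:
            out[node] = me_self  # empty neighbor average defined as zero
    if config.activation:
        out = np.maximum(out, 0.0)
        if training and dropout_mask is not None:
            out = out * dropout_mask
    return out
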