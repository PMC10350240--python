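"""Training: outcome labeling, optimizers, epoch loop, and model selection.

Cross-entropy on the graph probability is the loss for every task.
Optimizers are SGD with momentum (subtype/risk presets) and AdaDelta with
a learning-rate scaling factor (treatment-response preset).  Model
selection keeps the epoch with the highest validation accuracy, earliest
epoch on ties.  All randomness (init, dropout, batch order, per-epoch
patch resampling) flows from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ceograph.autodiff import Tensor, cross_entropy_with_logits
from ceograph.graph_build import NormalizationStats, SpatialGraph
from ceograph.model import CeographModel, ModelConfig


@dataclass
class TrainConfig:
    optimizer: Literal["sgd_momentum", "adadelta"] = "sgd_momentum"
    learning_rate: float = 1e-4
    momentum: float = 0.9
    adadelta_scale: float = 2.0
    adadelta_rho: float = 0.9
    adadelta_eps: float = 1e-6
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    resample_per_epoch: bool = False

    def __post_init__(self) -> None:
        if self.optimizer == "sgd_momentum" and self.learning_rate <= 0:
            raise ValueError("SGD learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class OutcomeLabeler:
    """Map survival times to binary class labels.

    ``opmd_risk``: cancer-free survival <= ``low_cut`` months is high-risk
    (class 1), > ``high_cut`` is low-risk (class 0); the in-between gap is
    excluded.  ``tki_response``: overall survival <= ``cut`` months is
    non-benefitting (class 0), otherwise benefitting (class 1).
    """

    task: Literal["opmd_risk", "tki_response"]
    opmd_low_cut: float = 42.3
    opmd_high_cut: float = 68.5
    tki_cut: float = 31.0

    def __post_init__(self) -> None:
        if self.task == "opmd_risk" and not (self.opmd_low_cut <= self.opmd_high_cut):
            raise ValueError("OPMD gap bounds out of order")


OPMD_CLASSES = ("low_risk", "high_risk")
TKI_CLASSES = ("non_benefitting", "benefitting")


def make_labels(clinical: pd.DataFrame, labeler: OutcomeLabeler, *, time_column: str = "time") -> pd.DataFrame:
    """Return a copy of ``clinical`` with a ``label`` column (rows in the
    OPMD gap are dropped; an ``excluded`` report is attached via attrs)."""
    if (clinical[time_column] < 0).any():
        bad = clinical.index[clinical[time_column] < 0].tolist()
        raise ValueError(f"negative survival time at rows {bad}")
    t = clinical[time_column].to_numpy(dtype=float)
    if labeler.task == "opmd_risk":
        high = t <= labeler.opmd_low_cut
        low = t > labeler.opmd_high_cut
        keep = high | low
        out = clinical.loc[keep].copy()
        out["label"] = np.where(t[keep] <= labeler.opmd_low_cut, 1, 0)
        out.attrs["excluded"] = clinical.index[~keep].tolist()
        out.attrs["classes"] = OPMD_CLASSES
    elif labeler.task == "tki_response":
        out = clinical.copy()
        out["label"] = np.where(t <= labeler.tki_cut, 0, 1)
        out.attrs["excluded"] = []
        out.attrs["classes"] = TKI_CLASSES
    else:
        raise ValueError(f"unknown labeling task {labeler.task!r}")
    return out


def check_split_integrity(splits: Mapping[str, Sequence[SpatialGraph]]) -> None:
    """Raise if any slide (or patient) appears in more than one split."""
    for key in ("slide_id", "patient_id"):
        seen: dict[str, str] = {}
        offending = set()
        for split_name, graphs in splits.items():
            for g in graphs:
                ident = getattr(g, key)
                if ident in seen and seen[ident] != split_name:
                    offending.add(ident)
                seen.setdefault(ident, split_name)
        if offending:
            raise ValueError(f"{key} leakage across splits: {sorted(offending)}")


def resample_epoch_patches(
    patient_pools: Mapping[str, Sequence[SpatialGraph]], seed: int, epoch: int
) -> list[SpatialGraph]:
    """Draw one patch graph per patient, deterministically in (seed, epoch)."""
    rng = np.random.default_rng([seed, epoch])
    picks = []
    for patient in sorted(patient_pools):
        pool = patient_pools[patient]
        if len(pool) == 0:
            raise ValueError(f"patient {patient!r} has an empty patch pool")
        picks.append(pool[int(rng.integers(len(pool)))])
    return picks


class _SGDMomentum:
    def __init__(self, params: list[Tensor], lr: float, momentum: float):
        self.params, self.lr, self.momentum = params, lr, momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class _AdaDelta:
    """AdaDelta with a learning-rate scaling factor applied to each update."""

    def __init__(self, params: list[Tensor], scale: float, rho: float, eps: float):
        self.params, self.scale, self.rho, self.eps = params, scale, rho, eps
        self.acc_grad = [np.zeros_like(p.data) for p in params]
        self.acc_delta = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self.acc_grad, self.acc_delta):
            if p.grad is None:
                continue
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            p.data += self.scale * delta


def _make_optimizer(config: TrainConfig, params: list[Tensor]):
    if config.optimizer == "sgd_momentum":
        return _SGDMomentum(params, config.learning_rate, config.momentum)
    if config.optimizer == "adadelta":
        return _AdaDelta(params, config.adadelta_scale, config.adadelta_rho, config.adadelta_eps)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def evaluate_accuracy(model: CeographModel, graphs: Sequence[SpatialGraph]) -> float:
    correct = 0
    for g in graphs:
        p, _ = model.forward(g)
        correct += int(np.argmax(p)) == g.label
    return correct / len(graphs) if graphs else float("nan")


def train_model(
    train_graphs: Sequence[SpatialGraph],
    val_graphs: Sequence[SpatialGraph],
    model_config: ModelConfig,
    train_config: TrainConfig,
    *,
    n_edge_types: int | None = None,
    patient_pools: Mapping[str, Sequence[SpatialGraph]] | None = None,
) -> tuple[CeographModel, pd.DataFrame]:
    """Train a model and return (best-validation checkpoint, history).

    When ``train_config.resample_per_epoch`` is set, the effective training
    set of each epoch is one freshly drawn patch per patient from
    ``patient_pools``; otherwise ``train_graphs`` is used as-is.
    """
    if not train_graphs and not patient_pools:
        raise ValueError("empty training set")
    if not val_graphs:
        raise ValueError("empty validation set")
    check_split_integrity({"train": list(train_graphs), "val": list(val_graphs)})
    if any(g.label is None for g in list(train_graphs) + list(val_graphs)):
        raise ValueError("all training/validation graphs need integer labels")

    some_graph = train_graphs[0] if train_graphs else next(iter(patient_pools.values()))[0]
    t_sq = n_edge_types or some_graph.scheme.n_types ** 2
    rng = np.random.default_rng(train_config.seed)
    model = CeographModel(model_config, n_edge_types=t_sq, f_in=some_graph.node_features.shape[1], rng=rng)
    optimizer = _make_optimizer(train_config, model.parameters())

    best_state = model.state_copy()
    best_acc, best_epoch = -1.0, -1
    rows = []
    for epoch in range(train_config.epochs):
        if train_config.resample_per_epoch:
            if patient_pools is None:
                raise ValueError("resample_per_epoch requires patient_pools")
            epoch_graphs = resample_epoch_patches(patient_pools, train_config.seed, epoch)
        else:
            epoch_graphs = list(train_graphs)
        order = rng.permutation(len(epoch_graphs))
        total_loss, correct = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [epoch_graphs[i] for i in order[start : start + train_config.batch_size]]
            model.zero_grad()
            for g in batch:
                logits, _ = model.forward_tensors(g, training=True, rng=rng)
                loss = cross_entropy_with_logits(logits, int(g.label))
                loss.backward(np.asarray(1.0 / len(batch)))
                total_loss += float(loss.data)
                correct += int(np.argmax(logits.data)) == g.label
            optimizer.step()
        val_acc = evaluate_accuracy(model, val_graphs)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": total_loss / max(len(epoch_graphs), 1),
                "train_acc": correct / max(len(epoch_graphs), 1),
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_copy()
    model.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_acc"] = best_acc
    return model, history


# ---------------------------------------------------------------------------
# Checkpoint container: model + normalization stats in one JSON document.

def save_checkpoint(
    path: str | Path,
    model: CeographModel,
    stats: NormalizationStats | None = None,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"format": "ceograph-checkpoint/1", "model": model.to_dict()}
    if stats is not None:
        payload["normalization"] = stats.to_dict()
    if extra:
        payload["extra"] = extra
    path.write_text(json.dumps(payload))
    return path


def load_checkpoint(path: str | Path) -> tuple[CeographModel, NormalizationStats | None, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ceograph-checkpoint/1":
        raise ValueError(f"{path}: not a ceograph checkpoint")
    model = CeographModel.from_dict(payload["model"])
    stats = NormalizationStats.from_dict(payload["normalization"]) if "normalization" in payload else None
    return model, stats, payload.get("extra", {})
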