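import numpy as np
import pandas as pd
import pytest

from ceograph.autodiff import cross_entropy_with_logits
from ceograph.graph_build import apply_normalization, fit_normalization
from ceograph.model import CeographModel, ModelConfig
from ceograph.synthetic import SyntheticSpec, generate_dataset
from ceograph.train import (
    OutcomeLabeler,
    TrainConfig,
    check_split_integrity,
    evaluate_accuracy,
    load_checkpoint,
    make_labels,
    resample_epoch_patches,
    save_checkpoint,
    train_model,
)

from conftest import random_graph


def tiny_splits(effects=None, seed=0, n=12):
    spec = SyntheticSpec(
        n_patches_per_class=n,
        cells_per_patch=(25, 40),
        effect_sizes=effects or {},
        patches_per_patient=2,
        seed=seed,
    )
    splits, _ = generate_dataset(spec)
    stats = fit_normalization(splits["train"])
    return {k: [apply_normalization(g, stats) for g in v] for k, v in splits.items()}


class TestMakeLabels:
    def _clinical(self, times):
        return pd.DataFrame({"time": times})

    def test_opmd_boundary_high_risk(self):
        out = make_labels(self._clinical([42.3]), OutcomeLabeler("opmd_risk"))
        assert out["label"].tolist() == [1]

    def test_opmd_gap_excluded(self):
        out = make_labels(self._clinical([50.0, 42.3, 70.0]), OutcomeLabeler("opmd_risk"))
        assert out["label"].tolist() == [1, 0]
        assert out.attrs["excluded"] == [0]

    def test_opmd_upper_boundary_excluded(self):
        # 68.5 sits inside the gap: "> 68.5" defines low-risk
        out = make_labels(self._clinical([68.5]), OutcomeLabeler("opmd_risk"))
        assert len(out) == 0

    def test_tki_boundary_non_benefitting(self):
        out = make_labels(self._clinical([31.0, 31.1]), OutcomeLabeler("tki_response"))
        assert out["label"].tolist() == [0, 1]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_labels(self._clinical([-1.0]), OutcomeLabeler("tki_response"))


class TestSplitIntegrity:
    def test_leak_detected(self, rng):
        a, b = random_graph(rng, 5), random_graph(rng, 5)
        a.slide_id = b.slide_id = "S1"
        a.patient_id, b.patient_id = "P1", "P2"
        with pytest.raises(ValueError, match="S1"):
            check_split_integrity({"train": [a], "val": [b]})

    def test_disjoint_ok(self, rng):
        a, b = random_graph(rng, 5), random_graph(rng, 5)
        a.slide_id, b.slide_id = "S1", "S2"
        a.patient_id, b.patient_id = "P1", "P2"
        check_split_integrity({"train": [a], "val": [b]})


class TestResample:
    def _pools(self, rng, sizes):
        pools = {}
        for i, size in enumerate(sizes):
            pools[f"pt{i}"] = [random_graph(rng, 5) for _ in range(size)]
        return pools

    def test_pool_of_one(self, rng):
        pools = self._pools(rng, [1])
        for epoch in range(5):
            assert resample_epoch_patches(pools, 7, epoch)[0] is pools["pt0"][0]

    def test_same_seed_epoch_identical(self, rng):
        pools = self._pools(rng, [10, 10, 10])
        a = resample_epoch_patches(pools, 3, 5)
        b = resample_epoch_patches(pools, 3, 5)
        assert all(x is y for x, y in zip(a, b))

    def test_epochs_differ(self, rng):
        pools = self._pools(rng, [100] * 20)
        a = resample_epoch_patches(pools, 3, 1)
        b = resample_epoch_patches(pools, 3, 2)
        assert any(x is not y for x, y in zip(a, b))

    def test_empty_pool_error(self):
        with pytest.raises(ValueError, match="pt0"):
            resample_epoch_patches({"pt0": []}, 0, 0)


class TestTrainModel:
    def test_tiny_lr_leaves_parameters_unchanged(self):
        splits = tiny_splits()
        cfg = TrainConfig(learning_rate=1e-300, epochs=1, seed=0)
        model, _ = train_model(splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg)
        reference = CeographModel(
            ModelConfig.preset("lung_subtype"), 36, 11, np.random.default_rng(0)
        )
        for got, want in zip(model.parameters(), reference.parameters()):
            assert np.allclose(got.data, want.data, atol=1e-250)

    def test_seeded_determinism(self):
        splits = tiny_splits()
        cfg = TrainConfig(learning_rate=0.01, epochs=3, seed=5)
        _, h1 = train_model(splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg)
        _, h2 = train_model(splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_learns_separable_synthetic_data(self):
        splits = tiny_splits(effects={"eccentricity_shift": 0.3, "alignment_strength": 0.95}, n=16)
        cfg = TrainConfig(learning_rate=0.05, epochs=15, batch_size=8, seed=1)
        model, history = train_model(
            splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg
        )
        assert history["train_acc"].iloc[-1] >= 0.95

    def test_loss_decreases_in_expectation(self):
        splits = tiny_splits(effects={"eccentricity_shift": 0.3}, n=8)
        first, last = [], []
        for seed in range(5):
            cfg = TrainConfig(learning_rate=0.02, epochs=6, seed=seed)
            _, h = train_model(splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg)
            first.append(h["train_loss"].iloc[0])
            last.append(h["train_loss"].iloc[-1])
        assert np.mean(last) < np.mean(first)

    def test_best_epoch_selection(self):
        splits = tiny_splits(effects={"eccentricity_shift": 0.3}, n=8)
        cfg = TrainConfig(learning_rate=0.05, epochs=8, seed=2)
        model, history = train_model(splits["train"], splits["val"], ModelConfig.preset("lung_subtype"), cfg)
        best = history.attrs["best_epoch"]
        assert history["val_acc"].iloc[best] == history.attrs["best_val_acc"]
        assert history["val_acc"].iloc[best] == history["val_acc"].max()
        # earliest epoch wins ties
        ties = history.index[history["val_acc"] == history["val_acc"].max()]
        assert best == ties[0]

    def test_leakage_raises(self, rng):
        a, b = random_graph(rng, 6), random_graph(rng, 6)
        a.slide_id = b.slide_id = "shared"
        with pytest.raises(ValueError, match="leakage"):
            train_model([a], [b], ModelConfig.preset("lung_subtype"), TrainConfig(learning_rate=0.1, epochs=1))

    def test_adadelta_runs_and_learns(self):
        splits = tiny_splits(effects={"eccentricity_shift": 0.3, "alignment_strength": 0.95}, n=12)
        cfg = TrainConfig(optimizer="adadelta", adadelta_scale=2.0, epochs=10, batch_size=8, seed=0)
        model, history = train_model(
            splits["train"], splits["val"], ModelConfig.preset("tki_response"), cfg
        )
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_resample_per_epoch_mode(self):
        splits = tiny_splits(effects={"eccentricity_shift": 0.3}, n=8)
        pools = {}
        for g in splits["train"]:
            pools.setdefault(g.patient_id, []).append(g)
        cfg = TrainConfig(learning_rate=0.02, epochs=3, seed=0, resample_per_epoch=True)
        model, history = train_model(
            [], splits["val"], ModelConfig.preset("opmd_risk"), cfg, patient_pools=pools
        )
        assert len(history) == 3

    def test_parameter_gradients_match_finite_differences(self, rng):
        g = random_graph(rng, 5, k=2)
        model = CeographModel(ModelConfig.preset("lung_subtype", hidden=4), 36, 11, rng)
        for layer in model.layers:
            layer.film_scale_weight.data = rng.normal(0, 0.3, layer.film_scale_weight.data.shape)

        def loss_value():
            logits, _ = model.forward_tensors(g)
            return float(cross_entropy_with_logits(logits, 0).data)

        model.zero_grad()
        logits, _ = model.forward_tensors(g)
        cross_entropy_with_logits(logits, 0).backward()

        eps = 1e-6
        checked = 0
        for tensor in model.parameters():
            flat = tensor.data.reshape(-1)
            grad = tensor.grad.reshape(-1) if tensor.grad is not None else np.zeros_like(flat)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                if abs(fd) > 1e-10:
                    assert abs(fd - grad[idx]) / abs(fd) < 1e-4
                    checked += 1
        assert checked > 10


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        g = random_graph(rng, 10)
        model = CeographModel(ModelConfig.preset("lung_subtype"), 36, 11, rng)
        stats = fit_normalization([g])
        path = save_checkpoint(tmp_path / "ck.json", model, stats, extra={"task": "lung_subtype"})
        model2, stats2, extra = load_checkpoint(path)
        p1, _ = model.forward(g)
        p2, _ = model2.forward(g)
        assert np.allclose(p1, p2)
        assert np.allclose(stats2.mean, stats.mean)
        assert extra["task"] == "lung_subtype"
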