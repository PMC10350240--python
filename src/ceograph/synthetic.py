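"""Synthetic labeled cell tables with controllable class-discriminative structure.

The generator plants documented effects between two classes so that every
pipeline stage (I/O, graph construction, training, aggregation,
interpretation) can be exercised and verified without external data:

``eccentricity_shift``
    adds a delta to the mean nuclear eccentricity of subgroup-type cells
    (e.g., tumor) in class 1, holding the beta concentration fixed so the
    planted mean difference equals the delta exactly.
``alignment_strength`` (s in (0, 1])
    class 1 patches draw orientations from a shared per-patch direction
    plus wrapped-normal noise with sd ``(1 - s) * 45`` degrees (s = 1 means
    every nucleus shares one orientation, so kNN-edge parallelism is 1);
    class 0 stays uniform.
``stroma_spacing_scale`` (r >= 0)
    cells of the second scheme type are drawn from spatial clusters whose
    spread is scaled by ``1 + r`` in class 1, lowering their mutual
    closeness.

All randomness flows from the spec seed through ``numpy`` SeedSequences,
so identical specs reproduce bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from ceograph.cell_io import (
    CellRecord,
    CellTable,
    CellTypeScheme,
    MORPHOLOGY_FEATURES,
    SCHEMES,
)
from ceograph.graph_build import SpatialGraph, build_graph

DEFAULT_MIXTURES: dict[str, dict[str, float]] = {
    "lung6": {
        "tumor": 0.50,
        "stroma": 0.20,
        "lymphocyte": 0.15,
        "red_blood_cell": 0.05,
        "macrophage": 0.05,
        "karyorrhexis": 0.05,
    },
    "oral4": {
        "stratum_corneum": 0.25,
        "stratum_basale": 0.25,
        "other_strata": 0.30,
        "non_epithelium": 0.20,
    },
}

EFFECT_FEATURES: dict[str, tuple[str, str]] = {
    # effect key -> (feature name it moves, direction in class 1)
    "eccentricity_shift": ("eccentricity", "up"),
    "alignment_strength": ("parallelism", "up"),
    "stroma_spacing_scale": ("closeness", "down"),
}


@dataclass
class SyntheticSpec:
    """Parameters of the generator; every planted effect lands in the manifest."""

    scheme_name: Literal["lung6", "oral4"] = "lung6"
    n_patches_per_class: int = 20
    cells_per_patch: tuple[int, int] = (60, 100)
    patch_size_px: int = 1024
    type_mixture: Mapping[str, float] | None = None
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    orientation_model: Literal["uniform", "locally_aligned"] = "uniform"
    orientation_noise_sd: float = 10.0  # degrees, for the base locally_aligned model
    density_model: Literal["uniform", "clustered"] = "uniform"
    base_eccentricity: float = 0.35
    eccentricity_concentration: float = 30.0
    log_area_mean: float = float(np.log(300.0))
    log_area_sd: float = 0.30
    measurement_noise_sd: float = 0.08  # log-scale jitter on derived geometry features
    patches_per_patient: int = 5
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    k: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_patch[0] < 1 or self.cells_per_patch[0] > self.cells_per_patch[1]:
            raise ValueError("cells_per_patch range infeasible")
        if self.n_patches_per_class < 1:
            raise ValueError("need at least one patch per class")
        unknown = set(self.effect_sizes) - set(EFFECT_FEATURES)
        if unknown:
            raise ValueError(f"unknown effect(s): {sorted(unknown)}")
        mix = self.mixture()
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("type mixture proportions must sum to 1")

    @property
    def scheme(self) -> CellTypeScheme:
        return SCHEMES[self.scheme_name]

    def mixture(self) -> dict[str, float]:
        return dict(self.type_mixture) if self.type_mixture else dict(DEFAULT_MIXTURES[self.scheme_name])


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    mean = float(np.clip(mean, 0.02, 0.98))
    return mean * concentration, (1.0 - mean) * concentration


def _sample_morphology(rng: np.random.Generator, n: int, spec: SyntheticSpec, ecc_mean: float) -> np.ndarray:
    """Draw a consistent ellipse-based morphology block (n x 10).

    Derived geometry features (axis lengths, perimeter, filled area) carry
    independent multiplicative measurement noise, mimicking segmentation
    jitter; eccentricity itself is the clean planted quantity.
    """
    area = np.exp(rng.normal(spec.log_area_mean, spec.log_area_sd, size=n))
    a_e, b_e = _beta_params(ecc_mean, spec.eccentricity_concentration)
    ecc = rng.beta(a_e, b_e, size=n)
    solidity = rng.beta(*_beta_params(0.94, 80.0), size=n)
    extent = rng.beta(*_beta_params(0.72, 40.0), size=n)
    axis_ratio = np.sqrt(np.maximum(1.0 - ecc**2, 1e-6))  # minor / major

    def noise(sd: float) -> np.ndarray:
        return np.exp(rng.normal(0.0, sd, size=n))

    major = np.sqrt(4.0 * area / (np.pi * axis_ratio)) * noise(spec.measurement_noise_sd)
    minor = np.minimum(major * axis_ratio * noise(spec.measurement_noise_sd), major)
    convex_area = area / solidity
    filled_area = area * noise(spec.measurement_noise_sd / 2.0)
    sa, sb = major / 2.0, minor / 2.0  # Ramanujan ellipse perimeter
    perimeter = np.pi * (3.0 * (sa + sb) - np.sqrt((3.0 * sa + sb) * (sa + 3.0 * sb))) * noise(
        spec.measurement_noise_sd
    )
    p2a = perimeter**2 / area
    block = np.column_stack([area, convex_area, ecc, extent, filled_area, major, minor, p2a, perimeter, solidity])
    assert block.shape[1] == len(MORPHOLOGY_FEATURES)
    return block


def _sample_positions(rng: np.random.Generator, n: int, spec: SyntheticSpec, spread_scale: float) -> np.ndarray:
    size = spec.patch_size_px
    if spec.density_model == "uniform" and spread_scale == 1.0:
        return rng.uniform(0.0, size, size=(n, 2))
    n_clusters = max(1, n // 20)
    centers = rng.uniform(0.0, size, size=(n_clusters, 2))
    assign = rng.integers(n_clusters, size=n)
    sd = (size / 15.0) * spread_scale
    xy = centers[assign] + rng.normal(0.0, sd, size=(n, 2))
    return np.clip(xy, 0.0, np.nextafter(size, 0.0))


def _sample_orientation(rng: np.random.Generator, n: int, aligned: bool, noise_sd: float) -> np.ndarray:
    if not aligned:
        return rng.uniform(0.0, 180.0, size=n)
    base = rng.uniform(0.0, 180.0)
    return np.mod(base + rng.normal(0.0, noise_sd, size=n), 180.0)


def generate_patch(
    spec: SyntheticSpec,
    class_label: int,
    seed: int | np.random.SeedSequence,
    *,
    patch_id: str = "patch",
    slide_id: str = "slide",
    patient_id: str = "patient",
) -> CellTable:
    """Generate one labeled patch table; deterministic given the seed."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    rng = np.random.default_rng(seed)
    scheme = spec.scheme
    mixture = spec.mixture()
    n = int(rng.integers(spec.cells_per_patch[0], spec.cells_per_patch[1] + 1))

    names = list(scheme.names)
    probs = np.array([mixture.get(t, 0.0) for t in names])
    types = rng.choice(len(names), size=n, p=probs / probs.sum())

    ecc_shift = float(spec.effect_sizes.get("eccentricity_shift", 0.0))
    align = float(spec.effect_sizes.get("alignment_strength", 0.0))
    spacing = float(spec.effect_sizes.get("stroma_spacing_scale", 0.0))
    subgroup_idx = set(int(i) for i in scheme.subgroup_indices())

    # positions: the second scheme type gets its own (possibly spread) clusters
    # whenever the spacing effect is declared, identically for both classes at r=0
    spread_type = 1 if "stroma_spacing_scale" in spec.effect_sizes else None
    xy = _sample_positions(rng, n, spec, 1.0)
    if spread_type is not None:
        mask = types == spread_type
        scale = 1.0 + (spacing if class_label == 1 else 0.0)
        xy[mask] = _sample_positions(rng, int(mask.sum()), spec, scale)

    aligned_base = spec.orientation_model == "locally_aligned"
    if class_label == 1 and align > 0.0:
        orient = _sample_orientation(rng, n, True, (1.0 - align) * 45.0)
    else:
        orient = _sample_orientation(rng, n, aligned_base, spec.orientation_noise_sd)

    morph = _sample_morphology(rng, n, spec, spec.base_eccentricity)
    if class_label == 1 and ecc_shift != 0.0:
        shifted = _sample_morphology(rng, n, spec, spec.base_eccentricity + ecc_shift)
        in_subgroup = np.isin(types, list(subgroup_idx))
        morph[in_subgroup] = shifted[in_subgroup]

    confidence = rng.beta(18.0, 2.0, size=n)

    records = [
        CellRecord(
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            cell_type=names[types[i]],
            confidence=float(confidence[i]),
            orientation=float(orient[i]),
            morphology=tuple(float(v) for v in morph[i]),
        )
        for i in range(n)
    ]
    return CellTable(
        records=records,
        patch_id=patch_id,
        slide_id=slide_id,
        patient_id=patient_id,
        patch_size_px=spec.patch_size_px,
    )


def generate_tables(spec: SyntheticSpec) -> tuple[list[CellTable], list[int]]:
    """All patch tables of both classes with patient/slide provenance."""
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(2 * spec.n_patches_per_class)
    tables, labels = [], []
    i = 0
    for cls in (0, 1):
        for p in range(spec.n_patches_per_class):
            patient = f"c{cls}_pt{p // spec.patches_per_patient:03d}"
            tables.append(
                generate_patch(
                    spec,
                    cls,
                    seeds[i],
                    patch_id=f"c{cls}_patch{p:04d}",
                    slide_id=f"{patient}_s0",
                    patient_id=patient,
                )
            )
            labels.append(cls)
            i += 1
    return tables, labels


def generate_dataset(spec: SyntheticSpec) -> tuple[dict[str, list[SpatialGraph]], dict]:
    """Patient-disjoint train/val/test graph corpora plus a manifest.

    The manifest records the planted effects, the seed, and the features a
    recovery test should find discriminative (direction refers to class 1).
    """
    tables, labels = generate_tables(spec)
    graphs = [build_graph(t, spec.scheme, k=spec.k, label=lbl) for t, lbl in zip(tables, labels)]

    patients = sorted({g.patient_id for g in graphs})
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    order = list(rng.permutation(patients))
    f_train, f_val, _ = spec.split_fractions
    n = len(order)
    n_train = max(1, round(f_train * n))
    n_val = max(1, round(f_val * n))
    assign: dict[str, str] = {}
    for idx, patient in enumerate(order):
        assign[patient] = "train" if idx < n_train else ("val" if idx < n_train + n_val else "test")
    if not any(v == "test" for v in assign.values()):
        assign[order[-1]] = "test"

    splits: dict[str, list[SpatialGraph]] = {"train": [], "val": [], "test": []}
    for g in graphs:
        splits[assign[g.patient_id]].append(g)

    manifest = {
        "seed": spec.seed,
        "scheme": spec.scheme_name,
        "n_patches_per_class": spec.n_patches_per_class,
        "effect_sizes": dict(spec.effect_sizes),
        "planted_features": [
            {"effect": k, "feature": EFFECT_FEATURES[k][0], "direction_in_class1": EFFECT_FEATURES[k][1]}
            for k, v in spec.effect_sizes.items()
            if v != 0.0
        ],
        "split_patients": {s: sorted({g.patient_id for g in gs}) for s, gs in splits.items()},
    }
    return splits, manifest
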