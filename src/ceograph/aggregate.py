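"""Patch-score aggregation to slide- and patient-level decisions.

Three rules: majority voting of patch classes per slide, arithmetic mean
of the positive-class probability per patient, and dichotomization of
patient scores either at a fixed 0.5 cutoff or at the cohort median.
Boundary conventions (documented, deterministic): a score exactly at the
fixed cutoff or at the median goes to the negative group; slide-vote ties
break by higher mean probability, then by lower class index.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PatchScore:
    patch_id: str
    slide_id: str
    patient_id: str
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        total = float(sum(self.probabilities))
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"patch {self.patch_id!r}: probabilities sum to {total}, not 1")

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probabilities))


def slide_majority_vote(scores: Sequence[PatchScore]) -> int:
    """Most frequent predicted class among a slide's patches."""
    if not scores:
        raise ValueError("majority vote needs at least one patch")
    votes = Counter(s.predicted_class for s in scores)
    top = max(votes.values())
    tied = sorted(k for k, v in votes.items() if v == top)
    if len(tied) == 1:
        return tied[0]
    mean_p = {k: float(np.mean([s.probabilities[k] for s in scores])) for k in tied}
    best = max(mean_p.values())
    return min(k for k in tied if mean_p[k] == best)


def patient_mean_score(scores: Sequence[PatchScore], positive_class: int) -> float:
    """Arithmetic mean of the positive-class probability over all patches."""
    if not scores:
        raise ValueError("patient mean score needs at least one patch")
    return float(np.mean([s.probabilities[positive_class] for s in scores]))


def dichotomize(
    patient_scores: Mapping[str, float],
    rule: Literal["fixed_cutoff", "cohort_median"] = "fixed_cutoff",
    cutoff: float = 0.5,
) -> dict[str, int]:
    """Assign each patient to the positive (1) or negative (0) group.

    ``fixed_cutoff``: score > cutoff is positive.  ``cohort_median``:
    score above the cohort median is positive, ties at the median negative.
    """
    if not patient_scores:
        raise ValueError("dichotomize needs at least one patient")
    values = np.array(list(patient_scores.values()), dtype=float)
    if rule == "fixed_cutoff":
        threshold = cutoff
    elif rule == "cohort_median":
        if len(values) < 2:
            raise ValueError("cohort_median rule needs at least two patients")
        threshold = float(np.median(values))
        if np.all(values == values[0]):
            warnings.warn("all patient scores identical; median rule assigns everyone negative", stacklevel=2)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return {pid: int(score > threshold) for pid, score in patient_scores.items()}


def score_table(scores: Iterable[PatchScore], class_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Delimited-text-ready table of patch scores for external tooling."""
    scores = list(scores)
    if not scores:
        return pd.DataFrame(columns=["patch_id", "slide_id", "patient_id", "predicted_class"])
    k = len(scores[0].probabilities)
    names = list(class_names) if class_names else [f"class_{i}" for i in range(k)]
    rows = []
    for s in scores:
        row = {"patch_id": s.patch_id, "slide_id": s.slide_id, "patient_id": s.patient_id,
               "predicted_class": s.predicted_class}
        row.update({f"p_{names[i]}": s.probabilities[i] for i in range(k)})
        rows.append(row)
    return pd.DataFrame(rows)


def group_by(scores: Iterable[PatchScore], key: str) -> dict[str, list[PatchScore]]:
    out: dict[str, list[PatchScore]] = {}
    for s in scores:
        out.setdefault(getattr(s, key), []).append(s)
    return out
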