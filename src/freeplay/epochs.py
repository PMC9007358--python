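"""Windowing: merge raw signal and annotation into labelled 15 s epochs.

Each epoch carries the per-sample vector magnitude, the majority activity
class, the duration-weighted CARS score, the intensity category derived
from that score, and a validity flag driven by out-of-view exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .labels import OUT_OF_VIEW, TIE_BREAK_ORDER, class_to_intensity
from .simulate import EventLog, RawSession

__all__ = [
    "EpochRecord",
    "vector_magnitude",
    "segment_epochs",
    "majority_class",
    "weighted_cars",
    "categorize_intensity",
    "class_to_intensity",
]


@dataclass
class EpochRecord:
    """One 15 s analysis window with ground truth and signal slices."""

    subject_id: str
    placement: str
    index: int
    start_s: float
    vm: np.ndarray            # per-sample vector magnitude, g
    axes: np.ndarray          # (n, 3) per-axis samples, g
    true_class: str | None    # None when the whole epoch is out of view
    cars_score: float         # duration-weighted CARS over in-view time; nan if none
    intensity: str | None
    valid: bool


def vector_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis vectors must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def majority_class(overlaps: dict[str, float]) -> str:
    """Class covering the most in-view time; ties go to the more intense
    class under SED < L_ACT_G < WALK < M_ACT_G < RUN."""
    if not overlaps:
        raise ValueError("empty overlap map")
    rank = {c: i for i, c in enumerate(TIE_BREAK_ORDER)}
    return max(overlaps, key=lambda c: (overlaps[c], rank[c]))


def weighted_cars(fractions: dict[int, float], tol: float = 1e-9) -> float:
    """Duration-weighted CARS score: sum of code x fraction-of-epoch.

    Fractions are proportions of in-view epoch time and must sum to 1."""
    total = sum(fractions.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"CARS fractions sum to {total!r}, expected 1")
    return float(sum(code * frac for code, frac in fractions.items()))


def categorize_intensity(score: float, sed_upper: float = 2.0, mvpa_lower: float = 3.0) -> str:
    """Band a weighted CARS score: < 2.0 SED, [2.0, 3.0) LPA, >= 3.0 MVPA."""
    if not (1.0 <= score <= 5.0):
        raise ValueError(f"CARS score {score} outside [1, 5]")
    if score < sed_upper:
        return "SED"
    if score < mvpa_lower:
        return "LPA"
    return "MVPA"


def segment_epochs(
    session: RawSession,
    log: EventLog,
    epoch_s: float = 15.0,
    max_out_of_view_s: float = 0.0,
) -> list[EpochRecord]:
    """Tile the session into epochs from its start, dropping any trailing
    partial window.

    An epoch is invalid when out-of-view time exceeds max_out_of_view_s
    (strict by default: any contamination excludes the window from
    evaluation).  Ground truth is computed over in-view time only.
    """
    log.validate()
    span = session.duration_s
    if log.duration_s + 1e-6 < span:
        raise ValueError(
            f"event log covers {log.duration_s:.3f} s but session spans "
            f"{span:.3f} s; uncovered interval ({log.duration_s:.3f}, {span:.3f})"
        )
    rate = session.rate_hz
    vm_all = vector_magnitude(
        session.samples[:, 0], session.samples[:, 1], session.samples[:, 2]
    )
    n_epochs = int(math.floor(span / epoch_s))
    samples_per = int(round(epoch_s * rate))
    records: list[EpochRecord] = []
    for k in range(n_epochs):
        t0, t1 = k * epoch_s, (k + 1) * epoch_s
        class_overlap: dict[str, float] = {}
        cars_overlap: dict[int, float] = {}
        oov_s = 0.0
        for ev in log.events:
            ov = min(ev.end_s, t1) - max(ev.start_s, t0)
            if ov <= 0:
                continue
            if ev.label == OUT_OF_VIEW:
                oov_s += ov
            else:
                class_overlap[ev.label] = class_overlap.get(ev.label, 0.0) + ov
                cars_overlap[ev.cars] = cars_overlap.get(ev.cars, 0.0) + ov
        in_view = sum(class_overlap.values())
        if in_view > 0:
            label = majority_class(class_overlap)
            fractions = {c: s / in_view for c, s in cars_overlap.items()}
            score = weighted_cars(fractions)
            intensity = categorize_intensity(score)
        else:
            label, score, intensity = None, float("nan"), None
        valid = oov_s <= max_out_of_view_s and label is not None
        i0 = k * samples_per
        records.append(
            EpochRecord(
                subject_id=session.subject_id,
                placement=session.placement,
                index=k,
                start_s=t0,
                vm=vm_all[i0 : i0 + samples_per],
                axes=session.samples[i0 : i0 + samples_per],
                true_class=label,
                cars_score=score,
                intensity=intensity,
                valid=valid,
            )
        )
    return records
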