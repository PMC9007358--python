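"""Epoch intensity metrics and published preschool cut-point sets.

Three metric families are supported per 15 s epoch:

* ENMO — Euclidean norm minus one, negatives truncated, epoch mean in mg;
* SVMg — epoch mean of |VM - 1| in mg (frequency-independent convention);
* activity counts — a documented surrogate for the proprietary ActiGraph
  count algorithm: per axis the signal is mean-centred, band-pass filtered
  (0.25-2.5 Hz, 4th-order Butterworth, causal), rectified, dead-band
  subtracted, clipped at a saturation ceiling, integrated per second and
  scaled to counts.  Vertical-axis counts use the Y axis; vector-magnitude
  counts are the rounded Euclidean norm of the three per-axis counts.

All count constants live in :class:`CountParams` so every run can log the
exact surrogate configuration.  Results based on counts are internally
consistent (the same surrogate generates and classifies) but are labelled
"surrogate counts" in reports because the true device algorithm is
unpublished.

The registry holds the eight published preschool cut-point sets (four hip,
four wrist), expressed per 15 s window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

VERTICAL_AXIS = 1  # Y column of the raw CSV by default


@dataclass(frozen=True)
class CountParams:
    """Constants of the surrogate activity-count algorithm."""

    passband_hz: tuple[float, float] = (0.25, 2.5)
    order: int = 4
    deadband_g: float = 0.018
    saturation_g: float = 2.13
    counts_per_g_s: float = 128.0

    def as_dict(self) -> dict[str, object]:
        return {
            "passband_hz": list(self.passband_hz),
            "order": self.order,
            "deadband_g": self.deadband_g,
            "saturation_g": self.saturation_g,
            "counts_per_g_s": self.counts_per_g_s,
        }


@dataclass(frozen=True)
class CutPointSet:
    """One published cut-point set: a metric plus two thresholds per 15 s.

    sed_inclusive=True means SED is value <= sed_upper (count-based sets);
    False means value < sed_upper (ENMO/SVMg sets).  LPA is the open
    interval between the two operative thresholds.
    """

    name: str
    placement: str
    metric: str  # vertical_counts | vm_counts | enmo_mg | svmg_mg
    sed_upper: float
    mvpa_lower: float
    units: str
    sed_inclusive: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.sed_upper >= self.mvpa_lower:
            raise ValueError("sed_upper must be below mvpa_lower")


def enmo(vm: np.ndarray) -> float:
    """Epoch mean of max(VM - 1, 0), in mg."""
    vm = np.asarray(vm, float)
    if vm.size == 0:
        raise ValueError("empty epoch")
    return float(np.clip(vm - 1.0, 0.0, None).mean() * 1000.0)


def svm_g(vm: np.ndarray) -> float:
    """Epoch mean of |VM - 1|, in mg."""
    vm = np.asarray(vm, float)
    if vm.size == 0:
        raise ValueError("empty epoch")
    return float(np.abs(vm - 1.0).mean() * 1000.0)


def axis_count_rate(
    samples: np.ndarray, rate_hz: float, params: CountParams | None = None
) -> np.ndarray:
    """Per-second surrogate counts for one axis over an arbitrary stretch.

    Returns an array of one value per whole second of input (a trailing
    partial second is dropped).
    """
    params = params or CountParams()
    lo, hi = params.passband_hz
    if rate_hz < 2.0 * hi:
        raise ValueError(
            f"sample rate {rate_hz} Hz below twice the passband top {hi} Hz"
        )
    x = np.asarray(samples, float)
    x = x - x.mean()  # removes the gravity step the causal filter would ring on
    sos = sps.butter(params.order, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    y = sps.sosfilt(sos, x)
    y = np.abs(y)
    y = np.clip(y - params.deadband_g, 0.0, params.saturation_g)
    n_sec = int(x.size // rate_hz)
    per_sample = y[: int(n_sec * rate_hz)].reshape(n_sec, int(rate_hz))
    g_seconds = per_sample.sum(axis=1) / rate_hz
    return g_seconds * params.counts_per_g_s


def surrogate_counts(
    samples: np.ndarray,
    rate_hz: float,
    params: CountParams | None = None,
    epoch_s: float = 15.0,
) -> np.ndarray:
    """Integer surrogate counts per epoch.

    samples may be 1-D (a single axis: vertical counts) or (n, 3) (all
    axes: vector-magnitude counts, the rounded Euclidean norm of per-axis
    epoch counts).
    """
    x = np.asarray(samples, float)
    sec_per_epoch = int(round(epoch_s))
    if x.ndim == 1:
        rate = axis_count_rate(x, rate_hz, params)
        n_ep = rate.size // sec_per_epoch
        per_epoch = rate[: n_ep * sec_per_epoch].reshape(n_ep, sec_per_epoch).sum(1)
        return np.rint(per_epoch).astype(int)
    if x.ndim == 2 and x.shape[1] == 3:
        per_axis = []
        for a in range(3):
            rate = axis_count_rate(x[:, a], rate_hz, params)
            n_ep = rate.size // sec_per_epoch
            per_axis.append(
                rate[: n_ep * sec_per_epoch].reshape(n_ep, sec_per_epoch).sum(1)
            )
        stacked = np.vstack(per_axis)
        return np.rint(np.sqrt((stacked**2).sum(axis=0))).astype(int)
    raise ValueError("samples must be a single axis or an (n, 3) array")


@dataclass
class EpochMetrics:
    """The four cut-point metrics for one 15 s epoch."""

    vertical_counts: int
    vm_counts: int
    enmo_mg: float
    svmg_mg: float

    def value(self, metric: str) -> float:
        try:
            return getattr(self, metric)
        except AttributeError:
            raise ValueError(f"metric {metric!r} missing from EpochMetrics") from None


def session_metrics(
    samples: np.ndarray,
    rate_hz: float,
    epoch_s: float = 15.0,
    params: CountParams | None = None,
    vertical_axis: int = VERTICAL_AXIS,
) -> list[EpochMetrics]:
    """Compute all four metrics for every complete epoch of a session.

    The count filter runs over the whole session once (as a device would),
    so epoch boundaries do not reset the filter state.
    """
    x = np.asarray(samples, float)
    vm = np.sqrt((x**2).sum(axis=1))
    vert = surrogate_counts(x[:, vertical_axis], rate_hz, params, epoch_s)
    vmc = surrogate_counts(x, rate_hz, params, epoch_s)
    n_ep = min(vert.size, vmc.size, int(x.shape[0] / rate_hz / epoch_s))
    per = int(round(epoch_s * rate_hz))
    out = []
    for k in range(n_ep):
        seg = vm[k * per : (k + 1) * per]
        out.append(
            EpochMetrics(
                vertical_counts=int(vert[k]),
                vm_counts=int(vmc[k]),
                enmo_mg=enmo(seg),
                svmg_mg=svm_g(seg),
            )
        )
    return out


def classify_cutpoint(metrics: EpochMetrics, cps: CutPointSet) -> str:
    """SED/LPA/MVPA decision for one epoch under one cut-point set."""
    v = metrics.value(cps.metric)
    if (v <= cps.sed_upper) if cps.sed_inclusive else (v < cps.sed_upper):
        return "SED"
    if v >= cps.mvpa_lower:
        return "MVPA"
    return "LPA"


def registry() -> tuple[CutPointSet, ...]:
    """The eight published preschool cut-point sets, per 15 s window."""
    return (
        CutPointSet("Pate", "hip", "vertical_counts", 200, 420,
                    "counts/15s", sed_inclusive=True,
                    note="vertical-axis surrogate counts"),
        CutPointSet("Evenson", "hip", "vertical_counts", 25, 574,
                    "counts/15s", sed_inclusive=True,
                    note="vertical-axis surrogate counts"),
        CutPointSet("Butte", "hip", "vm_counts", 205, 977,
                    "counts/15s", sed_inclusive=True,
                    note="vector-magnitude surrogate counts"),
        CutPointSet("Crotti", "hip", "enmo_mg", 20.0, 95.0,
                    "mg", sed_inclusive=False),
        CutPointSet("Johansson", "wrist", "vertical_counts", 267, 1320,
                    "counts/15s", sed_inclusive=True,
                    note="vertical-axis surrogate counts"),
        CutPointSet("Li", "wrist", "vm_counts", 639, 1765.75,
                    "counts/15s", sed_inclusive=True,
                    note="vector-magnitude surrogate counts"),
        CutPointSet("Roscoe", "wrist", "svmg_mg", 60.6, 98.3,
                    "mg", sed_inclusive=False,
                    note="scaled to frequency-independent mg per sample"),
        CutPointSet("Crotti", "wrist", "enmo_mg", 36.0, 189.0,
                    "mg", sed_inclusive=False),
    )


def registry_for(placement: str) -> tuple[CutPointSet, ...]:
    sets = tuple(c for c in registry() if c.placement == placement)
    if not sets:
        raise ValueError(f"unknown placement {placement!r}")
    return sets
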