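"""Per-epoch time- and frequency-domain features for activity classification.

Twenty-five features per 15 s window: twenty-two computed on the vector
magnitude and three zero-lag Pearson correlations between axis pairs.
Conventions (fixed here and oracle-tested):

* sd uses the sample (n-1) denominator; cv = sd/mean with cv = 0 when the
  mean is zero; skewness is adjusted Fisher-Pearson; kurtosis is excess.
* mad is the mean absolute deviation about the mean; signal_power the mean
  squared VM; log_energy the sum of log(VM^2 + 1e-10).
* median_crossings counts sign changes of VM minus its median, zeros
  attached to the previous sign.
* lag1_autocorr is the Pearson correlation of the series with itself
  shifted by one sample.
* percentiles use linear interpolation.
* the dominant frequency is searched in [0.25, 5.0] Hz on the mean-removed,
  un-tapered (rectangular) DFT; its magnitude is the normalised amplitude
  2|X(f)|/N.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .epochs import EpochRecord

log = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "sd",
    "cv",
    "p10",
    "p25",
    "p50",
    "p75",
    "p90",
    "skewness",
    "kurtosis",
    "max",
    "min",
    "peak_to_peak",
    "median_crossings",
    "sum",
    "mad",
    "signal_power",
    "lag1_autocorr",
    "log_energy",
    "iqr",
    "dom_freq",
    "dom_freq_magnitude",
    "corr_xy",
    "corr_xz",
    "corr_yz",
)

LOG_ENERGY_EPS = 1e-10
DOM_FREQ_BAND = (0.25, 5.0)


def dominant_frequency(
    vm: np.ndarray, rate_hz: float, band: tuple[float, float] = DOM_FREQ_BAND
) -> tuple[float, float]:
    """Frequency of maximal spectral amplitude inside *band* and that
    amplitude, normalised as 2|X(f)|/N."""
    lo, hi = band
    if not (0.0 < lo < hi < rate_hz / 2.0):
        raise ValueError(f"band {band} outside (0, {rate_hz / 2.0}) Hz")
    vm = np.asarray(vm, float)
    n = vm.size
    if n < 2 * rate_hz:
        raise ValueError("window must contain at least 2 s of samples")
    spectrum = np.fft.rfft(vm - vm.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    mask = (freqs >= lo) & (freqs <= hi)
    mags = np.abs(spectrum[mask])
    k = int(np.argmax(mags))
    return float(freqs[mask][k]), float(2.0 * mags[k] / n)


def axis_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation; 0 for a zero-variance axis."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("axis vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        log.debug("degenerate axis pair (zero variance); correlation set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _median_crossings(vm: np.ndarray) -> int:
    d = vm - np.median(vm)
    signs = np.sign(d)
    # zeros take the previous sign; leading zeros are dropped
    nz = signs != 0
    if not nz.any():
        return 0
    idx = np.where(nz, np.arange(signs.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, signs[np.maximum(idx, 0)], 0)
    filled = filled[filled != 0]
    return int(np.count_nonzero(np.diff(filled)))


def _lag1_autocorr(vm: np.ndarray) -> float:
    a, b = vm[:-1], vm[1:]
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compute_features(
    vm: np.ndarray, axes: np.ndarray, rate_hz: float
) -> dict[str, float]:
    """All 25 features for one epoch given its VM and (n, 3) axis samples."""
    vm = np.asarray(vm, float)
    axes = np.asarray(axes, float)
    n = vm.size
    mean = float(vm.mean())
    sd = float(vm.std(ddof=1))
    if mean == 0.0:
        if sd == 0.0:
            log.debug("degenerate epoch: constant-zero VM; cv emitted as 0")
        cv = 0.0
    else:
        cv = sd / mean
    p10, p25, p50, p75, p90 = np.percentile(vm, [10, 25, 50, 75, 90])
    vmax, vmin = float(vm.max()), float(vm.min())
    feats = {
        "mean": mean,
        "sd": sd,
        "cv": float(cv),
        "p10": float(p10),
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "p90": float(p90),
        "skewness": float(stats.skew(vm, bias=False)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(vm, fisher=True, bias=False)) if sd > 0 else 0.0,
        "max": vmax,
        "min": vmin,
        "peak_to_peak": vmax - vmin,
        "median_crossings": float(_median_crossings(vm)),
        "sum": float(vm.sum()),
        "mad": float(np.abs(vm - mean).mean()),
        "signal_power": float((vm * vm).mean()),
        "lag1_autocorr": _lag1_autocorr(vm),
        "log_energy": float(np.log(vm * vm + LOG_ENERGY_EPS).sum()),
        "iqr": float(p75 - p25),
    }
    freq, mag = dominant_frequency(vm, rate_hz)
    feats["dom_freq"] = freq
    feats["dom_freq_magnitude"] = mag
    feats["corr_xy"] = axis_correlation(axes[:, 0], axes[:, 1])
    feats["corr_xz"] = axis_correlation(axes[:, 0], axes[:, 2])
    feats["corr_yz"] = axis_correlation(axes[:, 1], axes[:, 2])
    assert set(feats) == set(FEATURE_NAMES) and len(feats) == 25
    return {name: feats[name] for name in FEATURE_NAMES}


def extract_features(epoch: EpochRecord, rate_hz: float) -> dict[str, float]:
    """Feature vector for one EpochRecord (column order = FEATURE_NAMES)."""
    if epoch.vm.size == 0 or epoch.axes.shape[0] != epoch.vm.size:
        raise ValueError("epoch must carry matching VM and axis samples")
    return compute_features(epoch.vm, epoch.axes, rate_hz)
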