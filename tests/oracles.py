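"""Independent brute-force reference implementations used only by tests.

Every formula here is written as a literal summation in plain Python (no
numpy shortcuts beyond array access) so it cannot share a code path with
the package implementation it checks.
"""

from __future__ import annotations

import cmath
import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    n = len(xs)
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def percentile_linear(xs, q):
    """q in [0, 100], linear interpolation between order statistics."""
    s = sorted(xs)
    n = len(s)
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return s[int(h)]
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def skewness_adjusted(xs):
    n = len(xs)
    m = mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / n
    m3 = sum((x - m) ** 3 for x in xs) / n
    g1 = m3 / m2**1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def kurtosis_excess_adjusted(xs):
    n = len(xs)
    m = mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / n
    m4 = sum((x - m) ** 4 for x in xs) / n
    g2 = m4 / m2**2 - 3.0
    return ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))


def median_crossings(xs):
    med = percentile_linear(xs, 50)
    signs = []
    for x in xs:
        d = x - med
        if d > 0:
            signs.append(1)
        elif d < 0:
            signs.append(-1)
        elif signs:
            signs.append(signs[-1])  # zero takes the previous sign
        # leading zeros dropped
    crossings = 0
    for a, b in zip(signs, signs[1:]):
        if a != b:
            crossings += 1
    return crossings


def pearson(a, b):
    n = len(a)
    ma, mb = mean(a), mean(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    if da == 0 or db == 0:
        return 0.0
    return num / (da * db)


def dominant_frequency(xs, rate, lo=0.25, hi=5.0):
    """Direct DFT summation over rfft bins inside [lo, hi]."""
    n = len(xs)
    m = mean(xs)
    centred = [x - m for x in xs]
    best = None
    for k in range(n // 2 + 1):
        f = k * rate / n
        if f < lo or f > hi:
            continue
        xk = sum(
            c * cmath.exp(-2j * math.pi * k * j / n) for j, c in enumerate(centred)
        )
        mag = abs(xk)
        if best is None or mag > best[1]:
            best = (f, mag)
    return best[0], 2.0 * best[1] / n


def all_features(vm, x, y, z, rate):
    """The full 25-feature vector by literal formulas (dict by name)."""
    n = len(vm)
    m = mean(vm)
    sd = sample_sd(vm)
    p10 = percentile_linear(vm, 10)
    p25 = percentile_linear(vm, 25)
    p50 = percentile_linear(vm, 50)
    p75 = percentile_linear(vm, 75)
    p90 = percentile_linear(vm, 90)
    vmax, vmin = max(vm), min(vm)
    freq, mag = dominant_frequency(vm, rate)
    return {
        "mean": m,
        "sd": sd,
        "cv": 0.0 if m == 0 else sd / m,
        "p10": p10,
        "p25": p25,
        "p50": p50,
        "p75": p75,
        "p90": p90,
        "skewness": skewness_adjusted(vm) if sd > 0 else 0.0,
        "kurtosis": kurtosis_excess_adjusted(vm) if sd > 0 else 0.0,
        "max": vmax,
        "min": vmin,
        "peak_to_peak": vmax - vmin,
        "median_crossings": float(median_crossings(vm)),
        "sum": sum(vm),
        "mad": mean([abs(v - m) for v in vm]),
        "signal_power": mean([v * v for v in vm]),
        "lag1_autocorr": pearson(vm[:-1], vm[1:]),
        "log_energy": sum(math.log(v * v + 1e-10) for v in vm),
        "iqr": p75 - p25,
        "dom_freq": freq,
        "dom_freq_magnitude": mag,
        "corr_xy": pearson(x, y),
        "corr_xz": pearson(x, z),
        "corr_yz": pearson(y, z),
    }


def confusion_counts(truth, pred, labels):
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = [[0] * k for _ in range(k)]
    for t, p in zip(truth, pred):
        counts[idx[t]][idx[p]] += 1
    return counts


def weighted_kappa(truth, pred, labels, weights="linear"):
    """kappa = 1 - sum(w o) / sum(w e) with explicit o/e summation."""
    k = len(labels)
    counts = confusion_counts(truth, pred, labels)
    n = len(truth)
    o = [[counts[i][j] / n for j in range(k)] for i in range(k)]
    row = [sum(counts[i]) / n for i in range(k)]
    col = [sum(counts[i][j] for i in range(k)) / n for j in range(k)]
    e = [[row[i] * col[j] for j in range(k)] for i in range(k)]
    if weights == "linear":
        w = [[abs(i - j) / (k - 1) for j in range(k)] for i in range(k)]
    else:
        w = [[((i - j) / (k - 1)) ** 2 for j in range(k)] for i in range(k)]
    num = sum(w[i][j] * o[i][j] for i in range(k) for j in range(k))
    den = sum(w[i][j] * e[i][j] for i in range(k) for j in range(k))
    return 1.0 - num / den


def tost_decision_from_ci(diffs, bound, alpha=0.05):
    """Equivalence via strict 90% CI containment, from scratch."""
    from scipy.stats import t as tdist

    n = len(diffs)
    m = mean(diffs)
    sd = sample_sd(diffs)
    se = sd / math.sqrt(n)
    tc = tdist.ppf(1 - alpha, n - 1)
    lo, hi = m - tc * se, m + tc * se
    return -bound < lo and hi < bound
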