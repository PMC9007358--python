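"""Agreement and equivalence statistics for the method comparison.

Confusion matrices (rows = ground truth, columns = prediction), overall
accuracy with a Wilson score interval, linearly weighted Cohen's kappa with
its asymptotic 95% CI and Landis-Koch interpretation, per-session time in
intensity, and paired TOST equivalence testing with half-SD bounds.

The weighted kappa is

    kappa = 1 - sum(w_ij o_ij) / sum(w_ij e_ij)

with disagreement weights w_ij = |i - j| / (k - 1) on the ordinal
SED < LPA < MVPA scale, observed cell proportions o and chance-expected
proportions e from the marginals.  The computation and its Fleiss-type
large-sample standard error are delegated to statsmodels.

Equivalence of predicted and directly observed minutes uses two one-sided
paired t-tests at alpha = 0.05 against +/- the bound; the decision is
identical to requiring the 90% CI of the mean difference to lie strictly
inside the bounds.  Bounds default to 0.5 sample standard deviations of
the directly observed minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa
from statsmodels.stats.proportion import proportion_confint

from .labels import INTENSITIES

LANDIS_KOCH_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (np.inf, "almost perfect"),
)


@dataclass
class AgreementReport:
    labels: tuple[str, ...]
    counts: pd.DataFrame           # rows = ground truth, columns = prediction
    row_percent: pd.DataFrame      # each row sums to 100
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None
    kappa_rating: str | None = None

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.to_numpy().tolist(),
            "row_percent": np.round(self.row_percent.to_numpy(), 4).tolist(),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci) if self.kappa_ci else None,
            "kappa_rating": self.kappa_rating,
        }


@dataclass
class EquivalenceResult:
    band: str
    n: int
    mean_diff: float           # predicted - observed, minutes
    sd_diff: float
    ci90: tuple[float, float]
    bound: float
    t_lower: float             # H0: mean <= -bound
    t_upper: float             # H0: mean >= +bound
    p_lower: float
    p_upper: float
    equivalent: bool

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def p(self) -> float:
        """The TOST p-value: the larger of the two one-sided p-values."""
        return max(self.p_lower, self.p_upper)

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "n": self.n,
            "df": self.df,
            "mean_diff_min": self.mean_diff,
            "sd_diff_min": self.sd_diff,
            "ci90_min": list(self.ci90),
            "bound_min": self.bound,
            "t_lower": self.t_lower,
            "t_upper": self.t_upper,
            "p": self.p,
            "equivalent": self.equivalent,
        }


def confusion(
    truth, pred, labels: tuple[str, ...]
) -> AgreementReport:
    """Count matrix, row percentages and accuracy with a Wilson 95% CI."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    for seq, name in ((truth, "truth"), (pred, "prediction")):
        bad = set(seq) - set(labels)
        if bad:
            raise ValueError(f"{name} contains labels outside the label set: {bad}")
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        counts[idx[t], idx[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    n = counts.sum()
    correct = int(np.trace(counts))
    acc = correct / n if n else float("nan")
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="wilson")
    cdf = pd.DataFrame(counts, index=list(labels), columns=list(labels))
    pdf = pd.DataFrame(pct, index=list(labels), columns=list(labels))
    return AgreementReport(
        labels=tuple(labels),
        counts=cdf,
        row_percent=pdf,
        accuracy=float(acc),
        accuracy_ci=(float(lo), float(hi)),
    )


def weighted_kappa(
    truth,
    pred,
    labels: tuple[str, ...] = INTENSITIES,
    weights: str = "linear",
) -> tuple[float, tuple[float, float]]:
    """Weighted Cohen's kappa with its asymptotic 95% CI.

    weights is 'linear' (default) or 'quadratic' on the ordinal label
    order.  Degenerate input (one label in both sequences) yields
    (nan, (nan, nan)): kappa is undefined without variation.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    rep = confusion(truth, pred, labels)
    table = rep.counts.to_numpy()
    observed = set(np.asarray(truth)) | set(np.asarray(pred))
    if len(observed) < 2:
        warnings.warn("kappa undefined: a single label observed")
        return float("nan"), (float("nan"), float("nan"))
    res = cohens_kappa(table, wt=weights)
    return float(res.kappa), (float(res.kappa_low), float(res.kappa_upp))


def landis_koch(kappa: float) -> str:
    """Interpretation bands; boundaries belong to the upper band and any
    negative kappa reads 'poor'."""
    if not (-1.0 - 1e-12 <= kappa <= 1.0 + 1e-12):
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    for upper, name in LANDIS_KOCH_BANDS:
        if kappa < upper:
            return name
    return "almost perfect"


def agreement_report(
    truth, pred, labels: tuple[str, ...], weights: str = "linear"
) -> AgreementReport:
    """Confusion + accuracy + weighted kappa in one report."""
    rep = confusion(truth, pred, labels)
    kap, ci = weighted_kappa(truth, pred, labels, weights)
    rep.kappa, rep.kappa_ci = kap, ci
    rep.kappa_rating = landis_koch(kap) if np.isfinite(kap) else None
    return rep


def time_in_intensity(
    intensities, epoch_s: float = 15.0, bands: tuple[str, ...] = INTENSITIES
) -> dict[str, float]:
    """Minutes per intensity band for one session's epoch stream."""
    seq = list(intensities)
    per_epoch_min = epoch_s / 60.0
    return {b: per_epoch_min * sum(1 for s in seq if s == b) for b in bands}


def equivalence_bound(observed_minutes, multiplier: float = 0.5) -> float:
    """Half the sample SD of the directly observed minutes (default)."""
    x = np.asarray(observed_minutes, float)
    if x.size < 2:
        raise ValueError("need at least 2 sessions")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance in observed minutes; equivalence bound is 0")
    return multiplier * sd


def tost(
    differences, bound: float, band: str = "", alpha: float = 0.05
) -> EquivalenceResult:
    """Paired TOST of predicted-minus-observed minutes against +/- bound.

    Equivalence is declared when the (1 - 2*alpha) CI of the mean
    difference lies strictly inside (-bound, +bound), which coincides with
    both one-sided t-tests rejecting at alpha.
    """
    d = np.asarray(differences, float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    if bound <= 0:
        raise ValueError("equivalence bound must be positive")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        warnings.warn("zero-variance differences; degenerate equivalence decision")
        inside = abs(mean) < bound
        p = 0.0 if inside else 1.0
        return EquivalenceResult(
            band=band, n=n, mean_diff=mean, sd_diff=0.0, ci90=(mean, mean),
            bound=bound, t_lower=float("inf") if inside else float("-inf"),
            t_upper=float("-inf") if inside else float("inf"),
            p_lower=p, p_upper=p, equivalent=inside,
        )
    se = sd / np.sqrt(n)
    t_lower = (mean + bound) / se           # reject H0 mean <= -bound when large
    t_upper = (mean - bound) / se           # reject H0 mean >= +bound when small
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    ci90 = (mean - tcrit * se, mean + tcrit * se)
    equivalent = (-bound < ci90[0]) and (ci90[1] < bound)
    return EquivalenceResult(
        band=band, n=n, mean_diff=mean, sd_diff=sd,
        ci90=(float(ci90[0]), float(ci90[1])), bound=float(bound),
        t_lower=float(t_lower), t_upper=float(t_upper),
        p_lower=p_lower, p_upper=p_upper, equivalent=bool(equivalent),
    )
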