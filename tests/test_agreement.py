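"""Confusion, weighted kappa, Landis-Koch, minutes, and TOST equivalence."""

import numpy as np
import pytest
from statsmodels.stats.weightstats import ttost_paired

from freeplay.agreement import (
    agreement_report,
    confusion,
    equivalence_bound,
    landis_koch,
    time_in_intensity,
    tost,
    weighted_kappa,
)
from freeplay.labels import INTENSITIES

import oracles


def test_perfect_predictions_identity_matrix():
    truth = ["SED", "LPA", "MVPA"] * 10
    rep = confusion(truth, truth, INTENSITIES)
    np.testing.assert_array_equal(
        np.diag(rep.row_percent.to_numpy()), [100.0] * 3
    )
    assert rep.accuracy == 1.0


def test_confusion_hand_count():
    rep = confusion(
        ["SED", "SED", "LPA"], ["SED", "LPA", "LPA"], INTENSITIES
    )
    assert rep.row_percent.loc["SED"].tolist() == [50.0, 50.0, 0.0]
    assert rep.counts.loc["SED", "LPA"] == 1


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError, match="outside"):
        confusion(["SED"], ["NAP"], INTENSITIES)


def test_confusion_matches_tally_oracle(rng):
    truth = rng.choice(INTENSITIES, 500)
    pred = rng.choice(INTENSITIES, 500)
    rep = confusion(truth, pred, INTENSITIES)
    want = oracles.confusion_counts(truth.tolist(), pred.tolist(), INTENSITIES)
    np.testing.assert_array_equal(rep.counts.to_numpy(), np.array(want))
    rows = rep.row_percent.to_numpy().sum(axis=1)
    np.testing.assert_allclose(rows[rows > 0], 100.0, atol=0.1)


def test_weighted_kappa_perfect_agreement():
    truth = ["SED", "LPA", "MVPA"] * 20
    k, (lo, hi) = weighted_kappa(truth, truth)
    assert k == pytest.approx(1.0)
    assert lo <= 1.0 <= hi + 1e-12


def test_weighted_kappa_matches_first_principles(rng):
    """Implementation agrees with explicit o/e summation to 1e-12 on 100
    random three-class fixtures, for both weighting schemes."""
    for _ in range(100):
        n = int(rng.integers(30, 200))
        truth = rng.choice(INTENSITIES, n, p=[0.3, 0.5, 0.2])
        noise = rng.choice(INTENSITIES, n)
        keep = rng.random(n) < 0.6
        pred = np.where(keep, truth, noise)
        if len(set(truth) | set(pred)) < 2:
            continue
        for scheme in ("linear", "quadratic"):
            k, _ = weighted_kappa(truth, pred, INTENSITIES, scheme)
            want = oracles.weighted_kappa(
                truth.tolist(), pred.tolist(), INTENSITIES, scheme
            )
            assert k == pytest.approx(want, abs=1e-12)


def test_two_category_weighted_equals_unweighted(rng):
    """With 2 categories the linear disagreement weights degenerate to 0/1,
    so weighted and plain kappa coincide."""
    from statsmodels.stats.inter_rater import cohens_kappa

    truth = rng.choice(["SED", "LPA"], 300, p=[0.4, 0.6])
    pred = np.where(rng.random(300) < 0.7, truth, rng.choice(["SED", "LPA"], 300))
    k, _ = weighted_kappa(truth, pred, ("SED", "LPA"))
    table = np.array(oracles.confusion_counts(truth.tolist(), pred.tolist(), ["SED", "LPA"]))
    plain = cohens_kappa(table, wt=None).kappa
    assert k == pytest.approx(plain, abs=1e-12)


def test_degenerate_kappa_reported_undefined():
    with pytest.warns(UserWarning, match="undefined"):
        k, ci = weighted_kappa(["SED"] * 10, ["SED"] * 10)
    assert np.isnan(k) and np.isnan(ci[0])


@pytest.mark.parametrize(
    "kappa, rating",
    [(0.1, "poor"), (-0.2, "poor"), (0.2, "fair"), (0.31, "fair"),
     (0.4, "moderate"), (0.44, "moderate"), (0.6, "substantial"),
     (0.76, "substantial"), (0.8, "almost perfect"), (0.95, "almost perfect"),
     (1.0, "almost perfect")],
)
def test_landis_koch_bands(kappa, rating):
    assert landis_koch(kappa) == rating


def test_agreement_report_combines_everything(rng):
    truth = rng.choice(INTENSITIES, 200, p=[0.3, 0.5, 0.2])
    pred = np.where(rng.random(200) < 0.8, truth, rng.choice(INTENSITIES, 200))
    rep = agreement_report(truth, pred, INTENSITIES)
    assert rep.kappa_rating == landis_koch(rep.kappa)
    assert rep.kappa_ci[0] < rep.kappa < rep.kappa_ci[1]
    d = rep.to_dict()
    assert d["labels"] == list(INTENSITIES)


@pytest.mark.parametrize(
    "counts, expected",
    [({"LPA": 80}, (0.0, 20.0, 0.0)),
     ({"SED": 24, "LPA": 52, "MVPA": 4}, (6.0, 13.0, 1.0))],
)
def test_time_in_intensity(counts, expected):
    seq = [band for band, n in counts.items() for _ in range(n)]
    minutes = time_in_intensity(seq)
    assert tuple(minutes[b] for b in INTENSITIES) == expected


@pytest.mark.parametrize("sd, bound", [(2.8, 1.4), (3.9, 1.95)])
def test_equivalence_bound_half_sd(rng, sd, bound):
    x = rng.normal(10.0, 1.0, 10)
    x = (x - x.mean()) / x.std(ddof=1) * sd + 10.0  # exact sample SD
    assert equivalence_bound(x) == pytest.approx(bound, abs=1e-12)


def test_equivalence_bound_degenerate():
    with pytest.warns(UserWarning, match="zero variance"):
        assert equivalence_bound([5.0] * 10) == 0.0


def test_tost_tight_differences_equivalent(rng):
    d = rng.normal(0.1, 0.3, 10)
    res = tost(d, bound=1.4)
    assert res.equivalent is True
    assert res.df == 9
    assert res.p < 0.05


def test_tost_large_bias_not_equivalent(rng):
    d = rng.normal(2.8, 0.3, 10)  # mean = 2x bound
    res = tost(d, bound=1.4)
    assert res.equivalent is False
    assert res.p > 0.05


def test_tost_ci_touching_bound_not_equivalent():
    # symmetric differences: 90% CI is centred; scale it to end on the bound
    d = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
    res = tost(d, bound=1.4)
    scale = 1.4 / res.ci90[1]
    touching = tost(d * scale, bound=1.4)
    assert abs(touching.ci90[1] - 1.4) < 1e-9
    assert touching.equivalent is False  # strict containment required


def test_tost_matches_statsmodels(rng):
    for _ in range(50):
        n = int(rng.integers(4, 20))
        d = rng.normal(rng.normal(0, 1), rng.uniform(0.2, 2.0), n)
        bound = float(rng.uniform(0.5, 2.5))
        res = tost(d, bound)
        p_sm, _, _ = ttost_paired(d, np.zeros(n), -bound, bound)
        assert res.p == pytest.approx(float(p_sm), abs=1e-12)


def test_tost_decision_equals_ci_containment(rng):
    """The t-test decision and strict 90% CI containment agree on 1,000
    random difference vectors."""
    mismatches = 0
    for _ in range(1000):
        n = int(rng.integers(3, 25))
        d = rng.normal(rng.normal(0, 1.0), rng.uniform(0.1, 2.0), n)
        bound = float(rng.uniform(0.3, 2.0))
        res = tost(d, bound)
        by_p = res.p_lower < 0.05 and res.p_upper < 0.05
        by_ci = oracles.tost_decision_from_ci(d.tolist(), bound)
        assert res.equivalent == by_ci
        if by_p != res.equivalent:
            mismatches += 1
    assert mismatches == 0


def test_tost_zero_variance_degenerate():
    with pytest.warns(UserWarning, match="zero-variance"):
        res = tost([0.3] * 8, bound=1.0)
    assert res.equivalent is True and res.p == 0.0
    with pytest.warns(UserWarning):
        res2 = tost([2.0] * 8, bound=1.0)
    assert res2.equivalent is False and res2.p == 1.0


def test_tost_input_validation():
    with pytest.raises(ValueError):
        tost([1.0], bound=1.0)
    with pytest.raises(ValueError):
        tost([1.0, 2.0], bound=0.0)
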