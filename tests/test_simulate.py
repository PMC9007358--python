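"""Generator: annotation coverage, determinism, dwell times, placement effects."""

import math

import numpy as np
import pytest

from freeplay.epochs import segment_epochs
from freeplay.labels import ACTIVITY_CLASSES, OUT_OF_VIEW
from freeplay.simulate import (
    _draw_events,
    default_profile,
    generate_cohort,
    generate_session,
    scaled_profile,
)


def test_session_has_expected_sample_count(profile):
    session, _ = generate_session("S01", "hip", 20.0, profile, seed=1)
    assert session.samples.shape == (120_000, 3)
    assert session.duration_s == pytest.approx(1200.0)


def test_event_log_covers_session_without_gaps(profile):
    for seed in (0, 1, 2):
        session, log = generate_session("S01", "hip", 10.0, profile, seed=seed)
        log.validate()  # contiguity, coverage, positive durations
        assert log.events[0].start_s == 0.0
        assert log.events[-1].end_s == pytest.approx(session.duration_s)


def test_seeded_determinism_bit_identical(profile):
    a_sess, a_log = generate_session("S01", "wrist", 3.0, profile, seed=42)
    b_sess, b_log = generate_session("S01", "wrist", 3.0, profile, seed=42)
    np.testing.assert_array_equal(a_sess.samples, b_sess.samples)
    assert [(e.start_s, e.end_s, e.label, e.cars) for e in a_log.events] == [
        (e.start_s, e.end_s, e.label, e.cars) for e in b_log.events
    ]


def test_different_seeds_differ(profile):
    _, a = generate_session("S01", "hip", 3.0, profile, seed=1)
    _, b = generate_session("S01", "hip", 3.0, profile, seed=2)
    assert [e.end_s for e in a.events] != [e.end_s for e in b.events]


def test_samples_within_device_range(profile):
    session, _ = generate_session("S01", "wrist", 5.0, profile, seed=5)
    assert np.abs(session.samples).max() <= 6.0


def test_invalid_profile_rejected():
    bad = default_profile()  # fresh instance: safe to corrupt
    bad.classes["RUN"].transitions["SED"] += 0.1  # break row sum
    with pytest.raises(ValueError, match="sums to"):
        generate_session("S01", "hip", 1.0, bad, seed=0)


def test_cars_codes_respect_class_support(profile):
    _, log = generate_session("S01", "hip", 20.0, profile, seed=9)
    support = {"SED": {1, 2}, "L_ACT_G": {2, 3}, "M_ACT_G": {3, 4, 5},
               "WALK": {3, 4}, "RUN": {4, 5}}
    for ev in log.events:
        assert ev.cars in support[ev.label]


def test_dwell_time_medians_match_profile(profile):
    """Empirical dwell medians within 25% of the profile medians (n >= 500)."""
    rng = np.random.default_rng(77)
    events = []
    while len(events) < 4000:
        events.extend(_draw_events(profile, 3600.0, rng))
    by_class = {c: [] for c in ACTIVITY_CLASSES}
    for ev in events:
        if ev.end_s - ev.start_s > 1e-6:
            by_class[ev.label].append(ev.end_s - ev.start_s)
    for c, durations in by_class.items():
        assert len(durations) >= 500 or c in ("RUN", "M_ACT_G")
        # truncation at the hour mark biases long bouts slightly downward
        med = np.median(durations)
        target = profile.classes[c].dwell_median_s
        assert abs(med - target) / target < 0.25, (c, med, target)


def _class_epoch_vm_sd(session, log, label):
    recs = segment_epochs(session, log)
    sds = [r.vm.std(ddof=1) for r in recs if r.true_class == label and r.valid]
    return float(np.mean(sds)) if sds else math.nan


def test_run_epochs_swing_harder_than_sed(profile):
    """Mean epoch VM-SD is far larger for RUN than SED under the defaults."""
    sed_sds, run_sds = [], []
    for seed in range(6):
        session, log = generate_session("S01", "hip", 20.0, profile, seed=seed)
        recs = segment_epochs(session, log)
        for r in recs:
            if r.true_class == "SED":
                sed_sds.append(r.vm.std(ddof=1))
            elif r.true_class == "RUN":
                run_sds.append(r.vm.std(ddof=1))
    assert len(run_sds) > 5 and len(sed_sds) > 5
    assert np.mean(run_sds) > np.mean(sed_sds)


def test_amplitude_monotonicity(profile):
    """Scaling a class's amplitude range scales its mean epoch VM-SD up."""
    louder = scaled_profile(profile, "L_ACT_G", 2.5)
    base_vals, loud_vals = [], []
    for seed in range(4):
        s1, l1 = generate_session("S01", "hip", 15.0, profile, seed=seed)
        s2, l2 = generate_session("S01", "hip", 15.0, louder, seed=seed)
        base_vals.append(_class_epoch_vm_sd(s1, l1, "L_ACT_G"))
        loud_vals.append(_class_epoch_vm_sd(s2, l2, "L_ACT_G"))
    assert np.nanmean(loud_vals) > np.nanmean(base_vals)


def test_wrist_sed_busier_than_hip_sed(profile):
    """Wrist SED epochs show strictly higher mean VM-SD than hip SED epochs
    (extraneous limb movement during sedentary behaviour)."""
    hip_sds, wrist_sds = [], []
    for seed in range(5):
        cohort = generate_cohort(2, 0.5, 10.0, profile, seed=seed)
        for sid in cohort.sessions:
            log = cohort.logs[sid]
            hip_sds.append(_class_epoch_vm_sd(cohort.sessions[sid]["hip"], log, "SED"))
            wrist_sds.append(
                _class_epoch_vm_sd(cohort.sessions[sid]["wrist"], log, "SED")
            )
    assert np.nanmean(wrist_sds) > np.nanmean(hip_sds)


def test_cohort_split_and_shared_log():
    cohort = generate_cohort(31, 21 / 31, duration_min=1.0, seed=3)
    assert len(cohort.train_subjects) == 21
    assert len(cohort.holdout_subjects) == 10
    assert not set(cohort.train_subjects) & set(cohort.holdout_subjects)
    for sid in cohort.sessions:
        assert set(cohort.sessions[sid]) == {"hip", "wrist"}
        # shared behaviour, different rendering
        assert not np.array_equal(
            cohort.sessions[sid]["hip"].samples,
            cohort.sessions[sid]["wrist"].samples,
        )


def test_cohort_rejects_empty_split():
    with pytest.raises(ValueError, match="empty"):
        generate_cohort(3, 0.99, duration_min=1.0, seed=0)
    with pytest.raises(ValueError):
        generate_cohort(1, 0.5, duration_min=1.0, seed=0)


def test_out_of_view_gaps_appear_in_log(profile):
    from dataclasses import replace

    oov = replace(profile, out_of_view_rate_per_min=2.0)
    _, log = generate_session("S01", "hip", 10.0, oov, seed=4)
    log.validate()
    labels = {e.label for e in log.events}
    assert OUT_OF_VIEW in labels
    for ev in log.events:
        if ev.label == OUT_OF_VIEW:
            assert ev.cars is None
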