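"""Windowing: VM, epoch tiling, majority class, weighted CARS, banding."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from freeplay.epochs import (
    categorize_intensity,
    majority_class,
    segment_epochs,
    vector_magnitude,
    weighted_cars,
)
from freeplay.labels import class_to_intensity
from freeplay.simulate import Event, EventLog, RawSession, generate_session


@pytest.mark.parametrize(
    "xyz, expected",
    [((0.0, 0.0, 1.0), 1.0), ((1.0, 2.0, 2.0), 3.0), ((0.0, 0.0, 0.0), 0.0)],
)
def test_vector_magnitude_values(xyz, expected):
    x, y, z = (np.array([v]) for v in xyz)
    assert vector_magnitude(x, y, z)[0] == pytest.approx(expected)


def test_vector_magnitude_rejects_mismatch():
    with pytest.raises(ValueError):
        vector_magnitude(np.zeros(3), np.zeros(3), np.zeros(4))


@pytest.mark.parametrize(
    "overlaps, expected",
    [
        ({"WALK": 9.0, "RUN": 6.0}, "WALK"),
        ({"SED": 15.0}, "SED"),
        ({"WALK": 7.5, "RUN": 7.5}, "RUN"),          # tie -> more intense
        ({"WALK": 7.5, "M_ACT_G": 7.5}, "M_ACT_G"),  # WALK below M_ACT_G
    ],
)
def test_majority_class(overlaps, expected):
    assert majority_class(overlaps) == expected


def test_majority_class_rejects_empty():
    with pytest.raises(ValueError):
        majority_class({})


@pytest.mark.parametrize(
    "fractions, expected",
    [
        ({2: 1.0}, 2.0),
        ({2: 10 / 15, 4: 5 / 15}, 8 / 3),
        ({1: 0.5, 5: 0.5}, 3.0),
    ],
)
def test_weighted_cars(fractions, expected):
    assert weighted_cars(fractions) == pytest.approx(expected)


def test_weighted_cars_rejects_bad_fractions():
    with pytest.raises(ValueError):
        weighted_cars({2: 0.5, 3: 0.4})


@given(
    st.lists(
        st.tuples(st.integers(1, 5), st.floats(0.01, 1.0)), min_size=1, max_size=5
    )
)
def test_weighted_cars_stays_in_range(pairs):
    total = sum(w for _, w in pairs)
    fractions = {}
    for code, w in pairs:
        fractions[code] = fractions.get(code, 0.0) + w / total
    score = weighted_cars(fractions, tol=1e-6)
    assert 1.0 - 1e-9 <= score <= 5.0 + 1e-9


@pytest.mark.parametrize(
    "score, expected",
    [(1.0, "SED"), (1.9, "SED"), (2.0, "LPA"), (2.5, "LPA"), (2.99, "LPA"),
     (3.0, "MVPA"), (5.0, "MVPA")],
)
def test_categorize_intensity_banding(score, expected):
    assert categorize_intensity(score) == expected


def test_categorize_intensity_monotone_and_bounded():
    order = {"SED": 0, "LPA": 1, "MVPA": 2}
    scores = np.linspace(1.0, 5.0, 101)
    cats = [order[categorize_intensity(s)] for s in scores]
    assert all(a <= b for a, b in zip(cats, cats[1:]))
    with pytest.raises(ValueError):
        categorize_intensity(0.5)


@pytest.mark.parametrize(
    "label, expected",
    [("SED", "SED"), ("L_ACT_G", "LPA"), ("M_ACT_G", "MVPA"),
     ("WALK", "MVPA"), ("RUN", "MVPA")],
)
def test_class_to_intensity(label, expected):
    assert class_to_intensity(label) == expected


def test_class_to_intensity_rejects_unknown():
    with pytest.raises(ValueError):
        class_to_intensity("JUMP")


def _toy_session(duration_s, events, rate=10.0):
    n = int(duration_s * rate)
    samples = np.tile([0.0, 1.0, 0.0], (n, 1))
    session = RawSession("T", "hip", rate, datetime(2022, 1, 1), samples)
    log = EventLog(datetime(2022, 1, 1), duration_s, [Event(*e) for e in events])
    return session, log


def test_epoch_counts_and_truncation(profile):
    session, log = generate_session("S01", "hip", 20.0, profile, seed=0)
    assert len(segment_epochs(session, log)) == 80
    s2, l2 = _toy_session(100.0, [(0.0, 100.0, "SED", 1)])
    assert len(segment_epochs(s2, l2)) == 6  # 90 s used, trailing 10 s dropped


def test_epoch_fully_inside_event_inherits_its_annotation():
    session, log = _toy_session(
        60.0, [(0.0, 30.0, "WALK", 4), (30.0, 60.0, "SED", 1)]
    )
    recs = segment_epochs(session, log)
    assert [r.true_class for r in recs] == ["WALK", "WALK", "SED", "SED"]
    assert [r.cars_score for r in recs] == [4.0, 4.0, 1.0, 1.0]
    assert [r.intensity for r in recs] == ["MVPA", "MVPA", "SED", "SED"]


def test_epoch_mixing_events_weights_by_duration():
    session, log = _toy_session(
        15.0, [(0.0, 10.0, "L_ACT_G", 2), (10.0, 15.0, "M_ACT_G", 4)]
    )
    (rec,) = segment_epochs(session, log)
    assert rec.true_class == "L_ACT_G"  # 10 s majority
    assert rec.cars_score == pytest.approx(8 / 3)
    assert rec.intensity == "LPA"


def test_out_of_view_epoch_marked_invalid():
    session, log = _toy_session(
        30.0,
        [(0.0, 12.0, "SED", 1), (12.0, 14.0, "OUT_OF_VIEW", None),
         (14.0, 30.0, "WALK", 3)],
    )
    recs = segment_epochs(session, log)
    assert recs[0].valid is False        # contaminated by 2 s out of view
    assert recs[0].true_class == "SED"   # in-view majority still reported
    assert recs[1].valid is True
    # relaxed threshold re-admits the epoch
    relaxed = segment_epochs(session, log, max_out_of_view_s=3.0)
    assert relaxed[0].valid is True


def test_uncovered_session_rejected():
    session, log = _toy_session(30.0, [(0.0, 20.0, "SED", 1)])
    log.duration_s = 20.0
    with pytest.raises(ValueError, match="uncovered"):
        segment_epochs(session, log)


def test_intensity_minutes_conservation(profile):
    session, log = generate_session("S02", "wrist", 12.0, profile, seed=8)
    recs = segment_epochs(session, log)
    valid = [r for r in recs if r.valid]
    from freeplay.agreement import time_in_intensity

    minutes = time_in_intensity([r.intensity for r in valid])
    assert sum(minutes.values()) == pytest.approx(0.25 * len(valid))
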