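"""Synthetic free-play sessions with direct-observation style annotation.

Generates tri-axial accelerometer signal (100 Hz, ±6 g, hip and wrist
placements) together with a contiguous event log of the five observed
activity classes and per-event CARS intensity codes.  The behaviour stream
is a semi-Markov chain: class transitions follow a Markov matrix and
within-class dwell times are log-normal (short, right-skewed play bouts).
Each event renders as a slowly drifting unit-gravity orientation vector
plus a class-specific sinusoid (frequency and amplitude drawn per event)
and broadband Gaussian noise.  Amplitude ranges of adjacent classes
deliberately overlap so that a single magnitude threshold cannot separate
intensities cleanly, while frequency content and axis structure still carry
class information a feature-based classifier can exploit.

One behaviour stream per subject drives both placements: the children wore
hip and wrist devices simultaneously, so the annotation is shared and only
the signal rendering differs (the wrist adds fidget bursts during sedentary
events to emulate extraneous limb movement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np

from .labels import ACTIVITY_CLASSES, CARS_SUPPORT, OUT_OF_VIEW

PLACEMENTS = ("hip", "wrist")
DEVICE_RANGE_G = 6.0


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one activity class.

    dwell_median_s / dwell_sigma parameterise the log-normal bout duration
    (median in seconds, sigma on the log scale).  freq_range (Hz) and
    amp_range (g) bound the per-event oscillation draw; noise_sd (g) is the
    per-axis broadband noise.  cars_probs is the distribution of CARS codes
    for events of this class; transitions the Markov row over next classes.
    vertical_bias in [0, 1] shifts oscillation energy toward the vertical
    axis (locomotion is vertically dominant).
    """

    dwell_median_s: float
    dwell_sigma: float
    freq_range: tuple[float, float]
    amp_range: tuple[float, float]
    noise_sd: float
    cars_probs: dict[int, float]
    transitions: dict[str, float]
    vertical_bias: float = 0.3


@dataclass(frozen=True)
class ActivityProfile:
    """Full generative profile: per-class parameters plus placement and
    out-of-view behaviour."""

    classes: dict[str, ClassProfile]
    # wrist rendering of SED events: short limb-movement bursts frequent and
    # strong enough that wrist sedentary epochs are visibly "busier" than hip
    wrist_sed_burst_rate_per_min: float = 12.0
    wrist_sed_burst_amp_g: tuple[float, float] = (0.08, 0.30)
    wrist_sed_burst_dur_s: tuple[float, float] = (0.5, 2.0)
    # out-of-view gaps; default disabled (used by exclusion-logic tests)
    out_of_view_rate_per_min: float = 0.0
    out_of_view_dur_s: tuple[float, float] = (2.0, 8.0)

    def validate(self) -> None:
        if set(self.classes) != set(ACTIVITY_CLASSES):
            raise ValueError(
                f"profile must define exactly the classes {ACTIVITY_CLASSES}"
            )
        for name, cp in self.classes.items():
            row = sum(cp.transitions.values())
            if abs(row - 1.0) > 1e-9:
                raise ValueError(
                    f"transition row for {name} sums to {row:.6f}, expected 1"
                )
            if any(k not in ACTIVITY_CLASSES for k in cp.transitions):
                raise ValueError(f"transition row for {name} names unknown classes")
            csum = sum(cp.cars_probs.values())
            if abs(csum - 1.0) > 1e-9:
                raise ValueError(
                    f"CARS distribution for {name} sums to {csum:.6f}, expected 1"
                )
            if any(code not in CARS_SUPPORT[name] for code in cp.cars_probs):
                raise ValueError(
                    f"CARS codes for {name} must lie in {CARS_SUPPORT[name]}"
                )
            lo, hi = cp.amp_range
            if lo < 0 or hi < lo:
                raise ValueError(f"amplitude range for {name} must be 0 <= lo <= hi")
            flo, fhi = cp.freq_range
            if not (0 < flo <= fhi < 50.0):
                raise ValueError(
                    f"frequency range for {name} must lie inside (0, 50) Hz"
                )


def default_profile() -> ActivityProfile:
    """The default study profile.

    Dwell medians and transition weights put roughly 30% of session time in
    the SED class, ~45% in L_ACT_G and the remainder in the locomotor /
    vigorous-play classes.  Amplitude ranges overlap across the class
    boundaries (e.g. an energetic L_ACT_G bout can out-swing a gentle WALK)
    so intensity is not a simple function of signal magnitude.
    """

    def row(**kw: float) -> dict[str, float]:
        total = sum(kw.values())
        return {k: v / total for k, v in kw.items()}

    classes = {
        "SED": ClassProfile(
            dwell_median_s=35.0,
            dwell_sigma=0.5,
            freq_range=(0.3, 1.2),
            amp_range=(0.0, 0.06),
            noise_sd=0.010,
            cars_probs={1: 0.8, 2: 0.2},
            transitions=row(L_ACT_G=0.55, WALK=0.25, M_ACT_G=0.15, RUN=0.05),
        ),
        "L_ACT_G": ClassProfile(
            dwell_median_s=30.0,
            dwell_sigma=0.5,
            freq_range=(0.5, 2.0),
            amp_range=(0.05, 0.30),
            noise_sd=0.020,
            cars_probs={2: 0.7, 3: 0.3},
            transitions=row(SED=0.35, WALK=0.30, M_ACT_G=0.25, RUN=0.10),
        ),
        "M_ACT_G": ClassProfile(
            dwell_median_s=15.0,
            dwell_sigma=0.5,
            freq_range=(1.0, 3.5),
            amp_range=(0.20, 0.80),
            noise_sd=0.050,
            cars_probs={3: 0.3, 4: 0.5, 5: 0.2},
            transitions=row(SED=0.15, L_ACT_G=0.50, WALK=0.25, RUN=0.10),
        ),
        "WALK": ClassProfile(
            dwell_median_s=12.0,
            dwell_sigma=0.5,
            freq_range=(1.5, 2.5),
            amp_range=(0.15, 0.50),
            noise_sd=0.030,
            cars_probs={3: 0.5, 4: 0.5},
            transitions=row(SED=0.25, L_ACT_G=0.45, M_ACT_G=0.20, RUN=0.10),
            vertical_bias=0.7,
        ),
        "RUN": ClassProfile(
            dwell_median_s=8.0,
            dwell_sigma=0.5,
            freq_range=(2.0, 3.5),
            amp_range=(0.60, 1.50),
            noise_sd=0.080,
            cars_probs={4: 0.5, 5: 0.5},
            transitions=row(SED=0.10, L_ACT_G=0.40, WALK=0.35, M_ACT_G=0.15),
            vertical_bias=0.7,
        ),
    }
    return ActivityProfile(classes=classes)


@dataclass
class Event:
    """One annotated movement event; times are seconds from session start.

    cars is None only for OUT_OF_VIEW segments."""

    start_s: float
    end_s: float
    label: str
    cars: int | None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventLog:
    """Contiguous, non-overlapping annotation covering a whole session."""

    session_start: datetime
    duration_s: float
    events: list[Event]

    def validate(self, tol: float = 1e-6) -> None:
        if not self.events:
            raise ValueError("empty event log")
        if abs(self.events[0].start_s) > tol:
            raise ValueError("event log does not start at session start")
        for a, b in zip(self.events, self.events[1:]):
            if abs(a.end_s - b.start_s) > tol:
                raise ValueError(
                    f"event log gap/overlap between {a.end_s:.6f} and {b.start_s:.6f}"
                )
        for ev in self.events:
            if ev.end_s <= ev.start_s:
                raise ValueError(f"event with non-positive duration at {ev.start_s}")
        if abs(self.events[-1].end_s - self.duration_s) > tol:
            raise ValueError("event log does not cover the session span")


@dataclass
class RawSession:
    """Tri-axial raw acceleration at a fixed sample rate.

    samples is an (n, 3) float array in g, axis order X, Y, Z; the vertical
    axis is Y by convention (device worn upright)."""

    subject_id: str
    placement: str
    rate_hz: float
    start: datetime
    samples: np.ndarray
    serial: str = ""

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate_hz


def _draw_events(
    profile: ActivityProfile, duration_s: float, rng: np.random.Generator
) -> list[Event]:
    """Semi-Markov behaviour stream truncated to the session length."""
    weights = np.array(
        [
            sum(cp.transitions.get(c, 0.0) for cp in profile.classes.values())
            for c in ACTIVITY_CLASSES
        ]
    )
    weights = weights / weights.sum()
    label = str(rng.choice(ACTIVITY_CLASSES, p=weights))
    events: list[Event] = []
    t = 0.0
    while t < duration_s:
        cp = profile.classes[label]
        dwell = float(
            rng.lognormal(mean=math.log(cp.dwell_median_s), sigma=cp.dwell_sigma)
        )
        end = min(t + dwell, duration_s)
        codes = sorted(cp.cars_probs)
        probs = np.array([cp.cars_probs[c] for c in codes])
        cars = int(rng.choice(codes, p=probs))
        events.append(Event(t, end, label, cars))
        t = end
        nxt = list(cp.transitions)
        label = str(rng.choice(nxt, p=np.array([cp.transitions[k] for k in nxt])))
    return events


def _carve_out_of_view(
    events: list[Event],
    profile: ActivityProfile,
    duration_s: float,
    rng: np.random.Generator,
) -> list[Event]:
    """Overlay out-of-view gaps on the annotation (signal is unaffected)."""
    rate = profile.out_of_view_rate_per_min / 60.0
    if rate <= 0:
        return events
    gaps: list[tuple[float, float]] = []
    t = float(rng.exponential(1.0 / rate))
    lo, hi = profile.out_of_view_dur_s
    while t < duration_s:
        dur = float(rng.uniform(lo, hi))
        gaps.append((t, min(t + dur, duration_s)))
        t += dur + float(rng.exponential(1.0 / rate))
    out: list[Event] = []
    for ev in events:
        pieces = [(ev.start_s, ev.end_s, ev.label, ev.cars)]
        for g0, g1 in gaps:
            nxt = []
            for s, e, lab, cars in pieces:
                if g1 <= s or g0 >= e:
                    nxt.append((s, e, lab, cars))
                    continue
                if s < g0:
                    nxt.append((s, g0, lab, cars))
                nxt.append((max(s, g0), min(e, g1), OUT_OF_VIEW, None))
                if e > g1:
                    nxt.append((g1, e, lab, cars))
            pieces = nxt
        out.extend(Event(s, e, lab, cars) for s, e, lab, cars in pieces if e > s)
    # merge adjacent OUT_OF_VIEW fragments produced by overlapping carves
    merged: list[Event] = []
    for ev in out:
        if merged and merged[-1].label == OUT_OF_VIEW and ev.label == OUT_OF_VIEW:
            merged[-1].end_s = ev.end_s
        else:
            merged.append(ev)
    return merged


def _gravity_track(
    n: int, rate_hz: float, placement: str, rng: np.random.Generator
) -> np.ndarray:
    """Unit gravity orientation random-walking with small angular steps."""
    if placement == "hip":
        theta0, phi0 = math.pi, 0.0  # gravity along -Y (device upright)
        step = 0.002
    else:
        theta0, phi0 = 2.2, 0.6  # tilted resting forearm posture
        step = 0.004
    # low-rate random walk on spherical angles, linearly upsampled
    n_ctrl = max(2, int(n / rate_hz) + 1)  # one control point per second
    theta = theta0 + np.cumsum(rng.normal(0.0, step, n_ctrl))
    phi = phi0 + np.cumsum(rng.normal(0.0, step, n_ctrl))
    tq = np.interp(np.arange(n) / rate_hz, np.arange(n_ctrl), theta)
    pq = np.interp(np.arange(n) / rate_hz, np.arange(n_ctrl), phi)
    g = np.empty((n, 3))
    g[:, 0] = np.sin(tq) * np.cos(pq)
    g[:, 1] = np.cos(tq)
    g[:, 2] = np.sin(tq) * np.sin(pq)
    return g


def _render_signal(
    events: list[Event],
    placement: str,
    duration_s: float,
    rate_hz: float,
    profile: ActivityProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the behaviour stream as a tri-axial acceleration signal in g."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    sig = _gravity_track(n, rate_hz, placement, rng)
    for ev in events:
        cp = profile.classes[ev.label]
        i0 = int(round(ev.start_s * rate_hz))
        i1 = min(int(round(ev.end_s * rate_hz)), n)
        if i1 <= i0:
            continue
        freq = rng.uniform(*cp.freq_range)
        amp = rng.uniform(*cp.amp_range)
        # CARS code nudges amplitude within the class range so the observed
        # intensity code is partially recoverable from the signal
        code = ev.cars if ev.cars is not None else 3
        amp *= 0.70 + 0.15 * (code - 1)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        direction = rng.normal(0.0, 1.0, 3)
        direction[1] = (1.0 - cp.vertical_bias) * direction[1] + cp.vertical_bias * 3.0
        direction /= np.linalg.norm(direction)
        wave = amp * np.sin(2.0 * math.pi * freq * t[i0:i1] + phase)
        sig[i0:i1] += wave[:, None] * direction[None, :]
        sig[i0:i1] += rng.normal(0.0, cp.noise_sd, (i1 - i0, 3))
        if placement == "wrist" and ev.label == "SED":
            sig[i0:i1] += _sed_fidget(
                i1 - i0, rate_hz, profile, rng
            )
    np.clip(sig, -DEVICE_RANGE_G, DEVICE_RANGE_G, out=sig)
    return sig


def _sed_fidget(
    n: int, rate_hz: float, profile: ActivityProfile, rng: np.random.Generator
) -> np.ndarray:
    """Short limb-movement bursts during wrist-worn sedentary events."""
    out = np.zeros((n, 3))
    rate = profile.wrist_sed_burst_rate_per_min / 60.0
    if rate <= 0:
        return out
    t = float(rng.exponential(1.0 / rate))
    dur_lo, dur_hi = profile.wrist_sed_burst_dur_s
    amp_lo, amp_hi = profile.wrist_sed_burst_amp_g
    while t * rate_hz < n:
        dur = rng.uniform(dur_lo, dur_hi)
        i0 = int(t * rate_hz)
        i1 = min(int((t + dur) * rate_hz), n)
        if i1 > i0:
            amp = rng.uniform(amp_lo, amp_hi)
            freq = rng.uniform(1.0, 3.0)
            direction = rng.normal(0.0, 1.0, 3)
            direction /= np.linalg.norm(direction)
            tt = np.arange(i1 - i0) / rate_hz
            env = np.sin(math.pi * np.arange(i1 - i0) / (i1 - i0))  # smooth on/off
            wave = amp * env * np.sin(2.0 * math.pi * freq * tt)
            out[i0:i1] += wave[:, None] * direction[None, :]
        t += dur + float(rng.exponential(1.0 / rate))
    return out


def generate_session(
    subject_id: str,
    placement: str,
    duration_min: float,
    profile: ActivityProfile | None = None,
    seed: int | np.random.SeedSequence = 0,
    rate_hz: float = 100.0,
    start: datetime | None = None,
) -> tuple[RawSession, EventLog]:
    """Generate one annotated session for a single placement.

    The same (profile, seed) always reproduces the identical session and
    event log bit for bit.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    if placement not in PLACEMENTS:
        raise ValueError(f"placement must be one of {PLACEMENTS}")
    profile = profile or default_profile()
    profile.validate()
    start = start or datetime(2022, 1, 1, 9, 0, 0)
    duration_s = duration_min * 60.0
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    ev_seed, sig_seed = ss.spawn(2)
    behaviour = _draw_events(profile, duration_s, np.random.default_rng(ev_seed))
    rng_sig = np.random.default_rng(sig_seed)
    samples = _render_signal(
        behaviour, placement, duration_s, rate_hz, profile, rng_sig
    )
    annotated = _carve_out_of_view(
        behaviour, profile, duration_s, np.random.default_rng(ev_seed.spawn(1)[0])
    )
    log = EventLog(session_start=start, duration_s=duration_s, events=annotated)
    log.validate()
    session = RawSession(
        subject_id=subject_id,
        placement=placement,
        rate_hz=rate_hz,
        start=start,
        samples=samples,
        serial=f"SYN-{subject_id}-{placement.upper()}",
    )
    return session, log


@dataclass
class Cohort:
    """A simulated study cohort: per subject one shared event log rendered
    at both placements, plus a random train/holdout split by subject."""

    sessions: dict[str, dict[str, RawSession]]  # subject -> placement -> session
    logs: dict[str, EventLog]
    train_subjects: list[str]
    holdout_subjects: list[str]


def generate_cohort(
    n_subjects: int,
    train_fraction: float,
    duration_min: float = 20.0,
    profile: ActivityProfile | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
) -> Cohort:
    """Generate a cohort; one behaviour stream per subject drives both the
    hip and wrist renderings, and subjects are randomly partitioned into
    training and hold-out groups."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    n_train = int(round(n_subjects * train_fraction))
    if n_train < 1 or n_train >= n_subjects:
        raise ValueError(
            f"train_fraction {train_fraction} yields an empty train or holdout split"
        )
    profile = profile or default_profile()
    profile.validate()
    root = np.random.SeedSequence(seed)
    split_seed, *subject_seeds = root.spawn(n_subjects + 1)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    sessions: dict[str, dict[str, RawSession]] = {}
    logs: dict[str, EventLog] = {}
    duration_s = duration_min * 60.0
    start = datetime(2022, 1, 1, 9, 0, 0)
    for sid, sseed in zip(subjects, subject_seeds):
        ev_seed, hip_seed, wrist_seed, oov_seed = sseed.spawn(4)
        behaviour = _draw_events(
            profile, duration_s, np.random.default_rng(ev_seed)
        )
        annotated = _carve_out_of_view(
            behaviour, profile, duration_s, np.random.default_rng(oov_seed)
        )
        log = EventLog(session_start=start, duration_s=duration_s, events=annotated)
        log.validate()
        logs[sid] = log
        sessions[sid] = {}
        for placement, pseed in (("hip", hip_seed), ("wrist", wrist_seed)):
            samples = _render_signal(
                behaviour,
                placement,
                duration_s,
                rate_hz,
                profile,
                np.random.default_rng(pseed),
            )
            sessions[sid][placement] = RawSession(
                subject_id=sid,
                placement=placement,
                rate_hz=rate_hz,
                start=start,
                samples=samples,
                serial=f"SYN-{sid}-{placement.upper()}",
            )
    order = np.random.default_rng(split_seed).permutation(subjects)
    return Cohort(
        sessions=sessions,
        logs=logs,
        train_subjects=sorted(order[:n_train]),
        holdout_subjects=sorted(order[n_train:]),
    )


def scaled_profile(base: ActivityProfile, label: str, amp_scale: float) -> ActivityProfile:
    """Return a copy of *base* with one class's amplitude range scaled
    (used for monotonicity checks)."""
    cp = base.classes[label]
    lo, hi = cp.amp_range
    new = replace(cp, amp_range=(lo * amp_scale, hi * amp_scale))
    classes = dict(base.classes)
    classes[label] = new
    return replace(base, classes=classes)
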