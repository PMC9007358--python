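# Methods

## The measurement problem

Accelerometer studies of preschool-aged children conventionally reduce the
raw tri-axial signal to a single per-epoch magnitude (activity counts, ENMO
or SVMg) and threshold it into sedentary (SED), light (LPA) and
moderate-to-vigorous (MVPA) intensity. Because the magnitude–intensity
relationship varies across activities and children, any single threshold
trades sensitivity against specificity and misclassifies heavily near the
band boundaries. Feature-based classifiers avoid the single-parameter
bottleneck: they predict the *type* of activity from the distributional and
spectral shape of the signal and map types to intensity afterwards.
`freeplay` implements both routes over a common simulated cohort and
quantifies the difference with chance-corrected agreement and equivalence
testing.

## Synthetic cohort

The generator emulates the design of a free-living validation study:
31 children, each completing one 20-minute free-play session at 100 Hz with
devices on the right hip and the non-dominant wrist, 21 children for model
development and 10 held out for the method comparison. These defaults are
all configurable (`RunConfig`).

**Behaviour stream.** Activity is a semi-Markov chain over five
direct-observation classes — SED, light activities and games (L_ACT_G),
moderate-to-vigorous activities and games (M_ACT_G), brisk walking (WALK),
running (RUN). Bout durations are log-normal (positive, right-skewed, as
short play bouts are): medians 35, 30, 15, 12 and 8 s respectively, sigma
0.5 on the log scale. Transition weights favour L_ACT_G as the hub class,
putting roughly 30% of session time in SED, ~45% in L_ACT_G and the rest in
the locomotor/vigorous classes — event-level base rates are assumptions of
the generator, not measurements. Each event receives a CARS code
(1 stationary … 5 fast translocation) from a class-conditional distribution
restricted to plausible codes (SED→{1,2}, L_ACT_G→{2,3}, M_ACT_G→{3,4,5},
WALK→{3,4}, RUN→{4,5}). The class→code draw is the source of label noise
between the class channel and the intensity channel: e.g. a SED event coded
CARS 2 contributes LPA ground truth, exactly the ambiguity that caps
attainable agreement for any classifier trained on classes.

**Signal model.** Gravity is a unit vector random-walking with small
angular steps (so stationary epochs still read VM ≈ 1 g); the hip starts
upright (gravity ≈ −Y), the wrist tilted and with a faster drift. Each
event adds one sinusoid with frequency and amplitude drawn from
class-specific ranges, distributed over the axes by a per-event random
direction that is vertically biased for locomotion, plus per-axis Gaussian
noise. Amplitude is additionally scaled by the event's CARS code
(factor 0.70 + 0.15·(code−1)), so observed intensity is partially — not
fully — recoverable from signal magnitude. Amplitude ranges of adjacent
classes deliberately overlap (SED 0–0.06 g, L_ACT_G 0.05–0.30 g,
WALK 0.15–0.50 g, M_ACT_G 0.20–0.80 g, RUN 0.60–1.50 g): a single
magnitude threshold cannot separate the intensity bands cleanly, while the
joint feature distribution still carries class information. During wrist
SED events, short fidget bursts (12/min, 0.08–0.30 g, 0.5–2 s, smoothly
enveloped) emulate extraneous limb movement, making wrist sedentary epochs
measurably busier than hip ones. Signals are clipped at the ±6 g device
range; RUN frequencies (2–3.5 Hz) partly exceed the count surrogate's
2.5 Hz passband, reproducing the well-known attenuation of vigorous
locomotion in count space.

One behaviour stream per child drives both placements (the devices are worn
simultaneously); only the rendering differs. Out-of-view gaps can be
overlaid on the annotation (signal unaffected, ground truth withheld) but
default to a rate of 0; they exist to exercise the exclusion logic.

**What the generator does not emulate.** No biomechanical gait structure,
no between-child heterogeneity in activity level or signal style, no
device artefacts (quantisation, temperature drift, idle sleep). Passing
tests therefore demonstrate the pipeline's correctness and the qualitative
classifier-versus-threshold ordering, not field validity on real children.

## Windowing and ground truth

Epochs tile each session from its start in 15 s windows; a trailing partial
window is dropped. Per epoch: majority class by in-view overlap seconds
(ties to the more intense class under SED < L_ACT_G < WALK < M_ACT_G < RUN
— stated explicitly because a tie rule is otherwise unspecified); weighted
CARS score Σ code·fraction with fractions renormalised over in-view time;
intensity SED/LPA/MVPA at the 2.0 and 3.0 score boundaries with half-open
bands ([2.0, 3.0) is LPA, so no score is stranded between 2.99 and 3.0).
An epoch is invalid if out-of-view time exceeds a threshold (default 0 s:
strict exclusion guarantees uncontaminated ground truth; configurable).

## Features

The 25 features and the conventions chosen where several definitions are
current: sample SD (n−1); CV = SD/mean, 0 at zero mean; adjusted
Fisher–Pearson skewness; excess kurtosis; MAD = mean absolute deviation
about the mean; signal power = mean squared VM; log energy =
Σ log(VM² + 1e−10); median crossings = sign changes of VM − median with
zeros attached to the previous sign; lag-1 autocorrelation = Pearson r of
the one-sample-shifted series; percentiles by linear interpolation;
dominant frequency = argmax of the rectangular-window DFT amplitude of the
mean-removed VM within 0.25–5.0 Hz, magnitude normalised 2|X|/N; zero-lag
Pearson correlations for the xy/xz/yz axis pairs, 0 for a zero-variance
axis. Every definition is pinned by a brute-force oracle test, so changing
a convention is a one-line edit with an immediate, visible diff.

## Count surrogate

The device-native count algorithm is unpublished, so counts are produced by
a documented surrogate: per axis, subtract the axis mean (removes the
gravity step a causal filter would ring on), 4th-order Butterworth
band-pass 0.25–2.5 Hz, rectify, subtract a 0.018 g dead-band, clip at
2.13 g, integrate per second, scale at 128 counts per g·s, sum 15
one-second values per epoch. Vertical-axis counts use Y; vector-magnitude
counts are the rounded Euclidean norm of the three per-axis epoch counts.
All constants live in `CountParams` and are logged with every run. The
synthetic study is internally consistent because the same surrogate
generates and classifies; count-based cut-point rows in reports are
labelled as surrogate counts, and no claim is made that the surrogate
matches real device output — published count thresholds are applied
verbatim to the surrogate scale, which suffices for pipeline verification
but not for field equivalence.

ENMO is the epoch mean of max(VM − 1, 0) in mg; SVMg the epoch mean of
|VM − 1| in mg (frequency-independent convention), so ENMO ≤ SVMg always.
Cut-point boundary directions follow each published set (count-based sets
use SED ≤ threshold, ENMO/SVMg sets SED < threshold; MVPA is ≥ its
threshold; LPA is the open interval between).

## Classifier and evaluation

Random forest: 500 trees, 3 features sampled per split, Gini criterion,
bootstrap samples of training-set size, trees grown to full depth,
deterministic under a fixed seed (scikit-learn backend). One model per
placement, never pooled. Evaluation is subject-aware throughout:
leave-one-subject-out cross-validation on the 21 training children (each
child is the test fold exactly once; folds with zero valid epochs are
skipped with a warning), and a single train-once pass onto the 10 hold-out
children for the method comparison. Five-class predictions collapse to
intensity via SED→SED, L_ACT_G→LPA, M_ACT_G/WALK/RUN→MVPA.

## Statistics

* Confusion matrices: rows = ground truth, columns = prediction; row
  percentages sum to 100.
* Accuracy CI: Wilson score interval (the CI method behind printed
  accuracy intervals is rarely stated; Wilson is well-behaved at the
  sample sizes involved).
* Weighted κ: linear disagreement weights |i−j|/(k−1) on the ordinal
  SED < LPA < MVPA scale — the conservative default where the weighting
  scheme is unstated — with quadratic available as a config switch; CI from
  the Fleiss-type asymptotic standard error (statsmodels). κ is reported
  as undefined when only one label occurs. Landis–Koch bands label κ as
  poor/fair/moderate/substantial/almost-perfect with boundaries assigned
  upward (0.4 → moderate) and negative κ read as poor.
* Minutes in intensity: 0.25 min per valid 15 s epoch, so band minutes sum
  to 0.25 × valid epochs per session by construction.
* Equivalence: per band, bound = 0.5 × sample SD (n−1, matching the
  half-of-2.8 = 1.4 arithmetic of printed bounds) of the directly observed
  hold-out minutes; paired TOST at α = 0.05 with df = n−1; the reported p
  is the larger one-sided p; the decision (both tests reject) coincides
  with strict containment of the 90% CI in (−bound, +bound), and the
  containment form is what the code decides on. Zero-variance differences
  short-circuit to |mean| < bound with a warning.

## Problem sizes and determinism

The default study (31 subjects × 2 placements × 20 min at 100 Hz,
42 LOSO folds of a 500-tree forest on ~1,680 × 25 feature matrices)
completes in about 1–2 minutes on one CPU; the test suite uses the same
default study once plus reduced cohorts (6 subjects, 5-minute sessions)
for orchestration tests. All randomness flows from a single integer seed
through `numpy.random.SeedSequence` spawning, so reruns are bit-identical,
including the JSON reports.

## Known limitations

* Synthetic signal realism is deliberately limited (see above); reported
  accuracies and κ values characterise the simulation, not children.
* Between-subject behavioural heterogeneity is absent, so the dispersion
  of observed minutes across hold-out sessions is small and the half-SD
  equivalence bounds correspondingly tight; combined with the CARS-code
  label noise (a five-class model cannot recover code-level intensity
  within a class), the forest's minute estimates typically do *not* meet
  the strict TOST criterion here even though its κ dominates every
  cut-point set. The equivalence machinery is exercised and tested in both
  directions regardless.
* The count surrogate is a stand-in by design; only internally consistent
  conclusions should be drawn from count-based rows.
* The annotation consumer assumes finished event logs; inter-observer
  reliability of human coding is out of scope.
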