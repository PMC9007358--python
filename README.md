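# freeplay

Machine-learning activity classifiers clearly outperform fixed intensity
cut-points when estimating young children's physical activity from
accelerometers — but demonstrating that comparison requires a full pipeline:
annotated free-living sessions, epoch-level ground truth, feature extraction,
model training with subject-aware cross-validation, and a battery of
agreement and equivalence statistics. `freeplay` implements that pipeline
end to end for the preschool free-play setting, with a synthetic-data
generator in place of human participants so every stage is testable and
reproducible on a laptop.

The package is aimed at physical-activity measurement researchers and
methodologists who want a transparent, fully seeded re-implementation of the
machine-learning-versus-cut-points study design.

## What it does

1. **Simulate** annotated 20-minute free-play sessions: tri-axial
   acceleration at 100 Hz (±6 g) for hip and wrist placements, driven by a
   semi-Markov behaviour stream over five observed activity classes
   (SED, L_ACT_G, M_ACT_G, WALK, RUN) with log-normal bout durations and a
   per-event CARS intensity code (Children's Activity Rating Scale, 1–5).
   One behaviour stream per child renders at both placements.
2. **Window** sessions into 15 s epochs. Ground-truth class is the majority
   class in the window; ground-truth intensity comes from the
   duration-weighted CARS score s = Σ codeᵢ·fracᵢ, banded as
   SED (s < 2.0), LPA (2.0 ≤ s < 3.0), MVPA (s ≥ 3.0).
3. **Extract** 25 time- and frequency-domain features per epoch from the
   vector magnitude VM = √(x²+y²+z²) and the axis pairs (mean, SD, CV,
   5 percentiles, skewness, kurtosis, extremes, median crossings, MAD,
   signal power, lag-1 autocorrelation, log energy, IQR, dominant frequency
   in 0.25–5 Hz with its magnitude, and the three inter-axis correlations).
4. **Classify** epochs two ways:
   * a random forest (500 trees, 3 features per split, grown to full depth)
     trained per placement on the five classes and evaluated with
     leave-one-subject-out cross-validation, its predictions collapsed to
     SED/LPA/MVPA (M_ACT_G, WALK, RUN → MVPA);
   * eight published preschool cut-point sets (Pate, Evenson, Butte and
     Crotti for the hip; Johansson, Li, Roscoe and Crotti for the wrist)
     applied to per-epoch activity counts, ENMO or SVMg. Activity counts
     use a documented surrogate algorithm (band-pass 0.25–2.5 Hz, rectify,
     dead-band, saturate, integrate, 128 counts per g·s) because the
     device-native count algorithm is proprietary; all constants are
     configurable and echoed into every report.
5. **Compare** methods on a hold-out group of children: confusion matrices,
   accuracy with Wilson 95% CI, linearly weighted Cohen's κ with asymptotic
   95% CI and Landis–Koch interpretation, per-session minutes in each
   intensity band, and TOST equivalence testing of predicted versus
   observed minutes with bounds of ±0.5 SD of the observed values
   (equivalent ⇔ the 90% CI of the mean difference lies inside the bounds).

## Worked example

```python
from freeplay import generate_session, default_profile
from freeplay.epochs import segment_epochs
from freeplay.features import extract_features
from freeplay.cutpoints import session_metrics, registry_for, classify_cutpoint
from freeplay.agreement import agreement_report
from freeplay.labels import INTENSITIES

session, log = generate_session("S01", "hip", 20.0, default_profile(), seed=7)
epochs = segment_epochs(session, log)
f = extract_features(epochs[0], session.rate_hz)
print(len(epochs), epochs[0].true_class, epochs[0].cars_score, epochs[0].intensity)
print("mean=%.3f g  sd=%.3f g  dom_freq=%.2f Hz" % (f["mean"], f["sd"], f["dom_freq"]))

mets = session_metrics(session.samples, session.rate_hz)
crotti = [c for c in registry_for("hip") if c.name == "Crotti"][0]
pred = [classify_cutpoint(m, crotti) for m in mets]
rep = agreement_report([e.intensity for e in epochs], pred, INTENSITIES)
print("Crotti hip kappa = %.2f (95%% CI %.2f-%.2f), %s" % (rep.kappa, *rep.kappa_ci, rep.kappa_rating))
```

prints

```
80 WALK 4.0 MVPA
mean=1.014 g  sd=0.300 g  dom_freq=1.67 Hz
Crotti hip kappa = 0.47 (95% CI 0.33-0.61), moderate
```

The 20-minute session yields 120,000 samples and 80 epochs; the first epoch
is a walking bout coded CARS 4 (moderate-speed translocation), hence MVPA.
Its VM hovers around 1 g (gravity) with an 0.3 g swing at the 1.7 Hz step
frequency. Applying one ENMO cut-point set to the same session gives only
"moderate" chance-corrected agreement (κ = 0.47) with the observation-based
intensity — the misclassification pattern the study design is built to
expose; the forest does substantially better (see the full study below).

## Full study and CLI

```sh
freeplay study --seed 1 --out results/       # 31 children, 21 train / 10 hold-out
freeplay simulate --subject S01 --placement wrist --out sess
freeplay epochs sess_raw.csv sess_events.csv
freeplay cutpoints                            # list the eight threshold sets
```

`study` writes `study_report.json` (confusion matrices, κ with CIs,
equivalence tests, the full configuration and its hash), per-epoch tables,
and heat-map/forest/equivalence figures. Sessions round-trip through an
ActiGraph-style raw CSV dialect (10-line header, then
`Accelerometer X,Accelerometer Y,Accelerometer Z` rows in g at 4 decimal
places); event logs through `start_iso8601,end_iso8601,class,cars` CSV.

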