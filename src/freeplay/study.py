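"""End-to-end study orchestration.

Simulate an annotated cohort, window and featurise every session, run
leave-one-subject-out cross-validation of the five-class random forest on
the training split, then evaluate the forest and all eight published
cut-point sets on the hold-out subjects: weighted kappa with 95% CI,
heat-map-ready confusion matrices, per-session time in intensity, and TOST
equivalence against directly observed minutes with half-SD bounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from .config import RunConfig
from .cutpoints import registry, registry_for, session_metrics
from .epochs import segment_epochs
from .features import FEATURE_NAMES, extract_features
from .forest import ForestConfig, loso_cv, pooled_accuracy, predict, train_forest
from .io import feature_table, metrics_table
from .labels import ACTIVITY_CLASSES, INTENSITIES, class_to_intensity
from .simulate import ActivityProfile, Cohort, default_profile, generate_cohort

log = logging.getLogger(__name__)

PLACEMENTS = ("hip", "wrist")


@dataclass
class StudyResult:
    """Everything run_study computes, plus the epoch-level tables."""

    config: RunConfig
    epochs: pd.DataFrame                     # features + metrics per valid epoch
    loso: dict[str, dict]                    # placement -> report
    holdout: dict[str, dict]                 # placement -> {method -> report}
    equivalence: dict[str, dict]             # placement -> {method -> {band -> result}}
    observed_minutes: pd.DataFrame           # per holdout session, direct observation
    predicted_minutes: pd.DataFrame          # per session x method

    def report(self) -> dict:
        """JSON-serializable study report (embeds config hash and seed)."""
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "count_surrogate_note": (
                "activity counts are produced by the documented surrogate "
                "algorithm, not the proprietary device firmware"
            ),
            "loso": self.loso,
            "holdout": self.holdout,
            "equivalence": {
                p: {
                    m: {b: r.to_dict() for b, r in bands.items()}
                    for m, bands in methods.items()
                }
                for p, methods in self.equivalence.items()
            },
        }


def build_epoch_table(cohort: Cohort, cfg: RunConfig) -> pd.DataFrame:
    """Window, featurise and metricise every session in the cohort.

    Returns one row per valid epoch with ground truth, the 25 features and
    the four cut-point metrics.
    """
    frames = []
    for sid in sorted(cohort.sessions):
        logb = cohort.logs[sid]
        for placement in PLACEMENTS:
            session = cohort.sessions[sid][placement]
            records = segment_epochs(
                session, logb, cfg.epoch_s, cfg.max_out_of_view_s
            )
            feats = [extract_features(r, cfg.rate_hz) for r in records]
            mets = session_metrics(
                session.samples, cfg.rate_hz, cfg.epoch_s, cfg.counts
            )
            ft = feature_table(records, feats)
            mt = metrics_table(records, mets)
            merged = pd.concat(
                [ft, mt[["vertical_counts", "vm_counts", "enmo_mg", "svmg_mg"]]],
                axis=1,
            )
            frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    return table[table["valid"]].reset_index(drop=True)


def _cutpoint_predictions(df: pd.DataFrame, placement: str, cfg: RunConfig):
    """Per-epoch SED/LPA/MVPA predictions for each selected cut-point set."""
    sets = registry_for(placement)
    if cfg.cutpoint_names:
        known = {c.name for c in registry()}
        unknown = set(cfg.cutpoint_names) - known
        if unknown:
            raise ValueError(
                f"unknown cut-point name(s) {sorted(unknown)}; valid names: "
                f"{sorted(known)}"
            )
        sets = tuple(c for c in sets if c.name in cfg.cutpoint_names)
    out = {}
    for cps in sets:
        vals = df[cps.metric].to_numpy()
        if cps.sed_inclusive:
            pred = np.where(vals <= cps.sed_upper, "SED",
                            np.where(vals >= cps.mvpa_lower, "MVPA", "LPA"))
        else:
            pred = np.where(vals < cps.sed_upper, "SED",
                            np.where(vals >= cps.mvpa_lower, "MVPA", "LPA"))
        out[f"{cps.name} ({cps.placement})"] = pred
    return out


def run_study(
    cfg: RunConfig | None = None,
    profile: ActivityProfile | None = None,
    out_dir: str | Path | None = None,
    make_figures: bool = False,
) -> StudyResult:
    """Execute the full study; deterministic given (config, profile)."""
    cfg = cfg or RunConfig()
    profile = profile or default_profile()
    log.info("surrogate count constants: %s", cfg.counts.as_dict())

    cohort = generate_cohort(
        cfg.n_subjects, cfg.train_fraction, cfg.duration_min, profile,
        seed=cfg.seed, rate_hz=cfg.rate_hz,
    )
    table = build_epoch_table(cohort, cfg)
    feature_names = list(FEATURE_NAMES)

    loso_reports: dict[str, dict] = {}
    holdout_reports: dict[str, dict] = {}
    equivalence: dict[str, dict] = {}
    obs_rows, pred_rows = [], []

    for placement in PLACEMENTS:
        sub = table[table["placement"] == placement]
        train = sub[sub["subject_id"].isin(cohort.train_subjects)]
        hold = sub[sub["subject_id"].isin(cohort.holdout_subjects)]

        fcfg = ForestConfig(
            n_trees=cfg.forest.n_trees,
            features_per_split=cfg.forest.features_per_split,
            seed=cfg.forest.seed + (0 if placement == "hip" else 1),
            labels=cfg.forest.labels,
        )

        # --- LOSO cross-validation on the training split (5 classes) ---
        preds, fold_acc = loso_cv(train, feature_names, fcfg)
        rep = agr.confusion(
            preds["true_class"], preds["predicted_class"], ACTIVITY_CLASSES
        )
        loso_reports[placement] = {
            "n_folds": len(fold_acc),
            "fold_accuracy": fold_acc,
            "pooled_accuracy": pooled_accuracy(preds),
            "confusion": rep.to_dict(),
        }

        # --- hold-out evaluation: forest vs cut-points (3 intensities) ---
        model = train_forest(train[feature_names], train["true_class"], fcfg)
        rf_class = predict(model, hold[feature_names])
        rf_intensity = np.array([class_to_intensity(c) for c in rf_class])
        truth = hold["intensity"].to_numpy()

        methods: dict[str, np.ndarray] = {f"Random Forest ({placement})": rf_intensity}
        methods.update(_cutpoint_predictions(hold, placement, cfg))

        holdout_reports[placement] = {}
        for name, pred in methods.items():
            rep = agr.agreement_report(truth, pred, INTENSITIES, cfg.kappa_weights)
            holdout_reports[placement][name] = rep.to_dict()

        # --- per-session minutes and TOST equivalence ---
        sessions = sorted(hold["subject_id"].unique())
        observed = {
            b: np.array(
                [
                    agr.time_in_intensity(
                        hold.loc[hold["subject_id"] == s, "intensity"], cfg.epoch_s
                    )[b]
                    for s in sessions
                ]
            )
            for b in INTENSITIES
        }
        for s, row in zip(sessions, zip(*[observed[b] for b in INTENSITIES])):
            obs_rows.append(
                {"placement": placement, "subject_id": s,
                 **dict(zip(INTENSITIES, row))}
            )
        equivalence[placement] = {}
        for name, pred in methods.items():
            hold_pred = hold.assign(pred=pred)
            minutes = {
                b: np.array(
                    [
                        agr.time_in_intensity(
                            hold_pred.loc[hold_pred["subject_id"] == s, "pred"],
                            cfg.epoch_s,
                        )[b]
                        for s in sessions
                    ]
                )
                for b in INTENSITIES
            }
            for s_i, s in enumerate(sessions):
                pred_rows.append(
                    {"placement": placement, "method": name, "subject_id": s,
                     **{b: minutes[b][s_i] for b in INTENSITIES}}
                )
            equivalence[placement][name] = {}
            for b in INTENSITIES:
                bound = agr.equivalence_bound(
                    observed[b], cfg.bound_sd_multiplier
                )
                diffs = minutes[b] - observed[b]
                equivalence[placement][name][b] = agr.tost(
                    diffs, bound, band=b, alpha=cfg.equivalence_alpha
                )

    result = StudyResult(
        config=cfg,
        epochs=table,
        loso=loso_reports,
        holdout=holdout_reports,
        equivalence=equivalence,
        observed_minutes=pd.DataFrame(obs_rows),
        predicted_minutes=pd.DataFrame(pred_rows),
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir), make_figures=make_figures)
    return result


def write_outputs(
    result: StudyResult, out_dir: Path, make_figures: bool = False
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "study_report.json", "w") as fh:
        json.dump(result.report(), fh, indent=2, sort_keys=True)
    cols = [c for c in result.epochs.columns]
    result.epochs.to_csv(out_dir / "epochs.csv", index=False, columns=cols)
    result.observed_minutes.to_csv(out_dir / "observed_minutes.csv", index=False)
    result.predicted_minutes.to_csv(out_dir / "predicted_minutes.csv", index=False)
    if make_figures:
        from . import plots

        plots.study_figures(result, out_dir)
    log.info("study outputs written to %s (config %s)", out_dir, result.config.hash())
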