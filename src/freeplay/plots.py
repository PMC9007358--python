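"""Figures: heat-map confusion matrices, kappa forest plots, equivalence plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns


def confusion_heatmap(report: dict, title: str, path: Path) -> None:
    pct = np.asarray(report["row_percent"])
    labels = report["labels"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    sns.heatmap(
        pct, annot=True, fmt=".1f", cmap="Blues", vmin=0, vmax=100,
        xticklabels=labels, yticklabels=labels, cbar_kws={"label": "% of row"},
        ax=ax,
    )
    ax.set_xlabel("Prediction")
    ax.set_ylabel("Ground truth")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def kappa_forest(holdout: dict[str, dict], path: Path) -> None:
    """Kappa with 95% CI for every method, grouped by placement."""
    names, kappas, lows, highs = [], [], [], []
    for placement, methods in holdout.items():
        for name, rep in methods.items():
            if rep["kappa"] is None:
                continue
            names.append(name)
            kappas.append(rep["kappa"])
            lows.append(rep["kappa_ci"][0])
            highs.append(rep["kappa_ci"][1])
    y = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(names) + 1.5))
    ax.errorbar(
        kappas, y,
        xerr=[np.array(kappas) - np.array(lows), np.array(highs) - np.array(kappas)],
        fmt="o", capsize=3,
    )
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel("Weighted kappa (95% CI)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def equivalence_plot(
    results: dict[str, dict], band: str, path: Path
) -> None:
    """Mean difference with 90% CI against the +/- half-SD bounds."""
    names, means, lo, hi, bounds = [], [], [], [], []
    for placement, methods in results.items():
        for name, bands in methods.items():
            r = bands[band]
            d = r.to_dict() if hasattr(r, "to_dict") else r
            names.append(name)
            means.append(d["mean_diff_min"])
            lo.append(d["ci90_min"][0])
            hi.append(d["ci90_min"][1])
            bounds.append(d["bound_min"])
    y = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(names) + 1.5))
    ax.errorbar(
        means, y,
        xerr=[np.array(means) - np.array(lo), np.array(hi) - np.array(means)],
        fmt="o", capsize=3,
    )
    if bounds:
        ax.axvline(-bounds[0], color="red", ls="--", lw=1)
        ax.axvline(bounds[0], color="red", ls="--", lw=1)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel(f"Predicted - observed {band} (min), 90% CI")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def study_figures(result, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    for placement, rep in result.loso.items():
        confusion_heatmap(
            rep["confusion"],
            f"LOSO confusion ({placement})",
            out_dir / f"confusion_loso_{placement}.png",
        )
    for placement, methods in result.holdout.items():
        for name, rep in methods.items():
            safe = name.replace(" ", "_").replace("(", "").replace(")", "")
            confusion_heatmap(
                rep, f"{name} hold-out", out_dir / f"confusion_{safe}.png"
            )
    kappa_forest(result.holdout, out_dir / "kappa_forest.png")
    for band in ("SED", "LPA", "MVPA"):
        equivalence_plot(
            result.equivalence, band, out_dir / f"equivalence_{band.lower()}.png"
        )
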