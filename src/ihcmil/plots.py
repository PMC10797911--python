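"""Matplotlib figures: score scatter with clinical threshold guides,
Bland-Altman, Kaplan-Meier curves and the threshold-grid heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import CLINICAL_THRESHOLDS, bland_altman


def scatter_plot(reference, model, marker: str, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(reference, model, s=18, alpha=0.7)
    ax.plot([0, 100], [0, 100], "k--", lw=1, label="identity")
    t = CLINICAL_THRESHOLDS.get(marker)
    if t is not None:
        ax.axvline(t, color="r", lw=1, ls=":", label=f"clinical threshold {t:g}%")
        ax.axhline(t, color="r", lw=1, ls=":")
    ax.set_xlabel("reference score (%)")
    ax.set_ylabel("model score (%)")
    ax.set_title(f"{marker} agreement")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(reference, model, path: str | Path) -> None:
    reference = np.asarray(reference, dtype=float)
    model = np.asarray(model, dtype=float)
    md, lo, hi = bland_altman(reference, model)
    means = (reference + model) / 2.0
    diffs = reference - model
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7)
    for yv, style, lbl in ((md, "-", "mean diff"), (lo, "--", "-1.96 sd"),
                           (hi, "--", "+1.96 sd")):
        ax.axhline(yv, color="r", ls=style, lw=1,
                   label=f"{lbl} = {yv:.2f}")
    ax.set_xlabel("mean of reference and model (%)")
    ax.set_ylabel("reference - model (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(curves: dict, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for label, kmf in curves.items():
        kmf.plot_survival_function(ax=ax, show_censors=True)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def grid_plot(grid, path: str | Path) -> None:
    """Heatmap of -log10(p); masked (empty-group) cells hatched gray."""
    fig, ax = plt.subplots(figsize=(6, 5))
    data = np.ma.masked_invalid(grid.neg_log10_p)
    im = ax.imshow(data, origin="lower", cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(grid.bcl2_thresholds)),
                  [f"{t:g}" for t in grid.bcl2_thresholds])
    ax.set_yticks(range(len(grid.myc_thresholds)),
                  [f"{t:g}" for t in grid.myc_thresholds])
    ax.set_xlabel("BCL2 threshold (%)")
    ax.set_ylabel("c-MYC threshold (%)")
    fig.colorbar(im, ax=ax, label="-log10 log-rank p (>1.3 significant)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
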