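"""Figures: feature-correlation heat map and actual-vs-predicted scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .modeling import ModelReport

__all__ = ["correlation_heatmap", "prediction_scatter"]


def correlation_heatmap(selection_report: pd.DataFrame, path: str | Path) -> None:
    """Feature x group map of Pearson r; selected cells are outlined."""
    pivot_r = selection_report.pivot(index="feature", columns="group", values="r")
    pivot_sel = selection_report.pivot(
        index="feature", columns="group", values="selected"
    ).fillna(False)

    fig, ax = plt.subplots(figsize=(4.5, 0.22 * len(pivot_r) + 1.5))
    im = ax.imshow(pivot_r.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(pivot_r.shape[1]), pivot_r.columns)
    ax.set_yticks(range(pivot_r.shape[0]), pivot_r.index, fontsize=5)
    for i in range(pivot_r.shape[0]):
        for j in range(pivot_r.shape[1]):
            if bool(pivot_sel.iloc[i, j]):
                ax.add_patch(plt.Rectangle(
                    (j - 0.5, i - 0.5), 1, 1, fill=False, lw=0.6, ec="black"
                ))
    fig.colorbar(im, ax=ax, label="Pearson r with FDI")
    ax.set_title("Feature-FDI correlation by group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def prediction_scatter(reports: list[ModelReport], out_dir: str | Path) -> None:
    """One actual-vs-predicted panel pair (train/test) per model cell."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in reports:
        fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharex=True, sharey=True)
        for ax, role, metrics in (
            (axes[0], "train", rep.train),
            (axes[1], "test", rep.test),
        ):
            sub = rep.predictions[rep.predictions["role"] == role]
            ax.scatter(sub["fdi"], sub["fdi_pred"], s=12, alpha=0.7)
            lim = (0.0, 1.05)
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_xlim(lim)
            ax.set_ylim(lim)
            ax.set_xlabel("actual FDI")
            ax.set_title(
                f"{role}: R²={metrics.r2:.3f} RMSE={metrics.rmse:.3f}", fontsize=9
            )
        axes[0].set_ylabel("predicted FDI")
        fig.suptitle(f"{rep.source}-{rep.group}-{rep.algorithm}", fontsize=10)
        fig.tight_layout()
        fig.savefig(out / f"{rep.source}_{rep.group}_{rep.algorithm}.png", dpi=120)
        plt.close(fig)
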