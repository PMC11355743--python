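"""Figures: group-wise occurrence-frequency curves and the method rank heatmap.

Every figure's numeric content is also written as CSV next to the image so
plots are testable without image comparison.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import occurrence_frequency
from .datatypes import EventTensor, OutcomeVector


def plot_frequency(
    X: EventTensor,
    Y: OutcomeVector,
    features: list[str],
    out_path: str | Path,
) -> pd.DataFrame:
    """One panel per feature: mortality vs recovery occurrence-% by day.

    Writes ``<out_path>`` (image) and ``<out_path stem>.csv`` (long-format
    curve data) and returns the curve data frame.
    """
    if not features:
        raise ValueError("no features to plot")
    out_path = Path(out_path)
    rows = []
    ncols = min(len(features), 5)
    nrows = int(np.ceil(len(features) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax in axes.ravel()[len(features):]:
        ax.set_visible(False)
    for ax, fid in zip(axes.ravel(), features):
        mort, recov = occurrence_frequency(X, Y, fid)
        ax.plot(X.day_labels, mort, color="tab:blue", marker="o", ms=3, label="mortality")
        ax.plot(X.day_labels, recov, color="tab:orange", marker="o", ms=3, label="recovery")
        ax.set_title(fid, fontsize=8)
        ax.set_ylim(0, 100)
        ax.tick_params(labelsize=6)
        for day, m, r in zip(X.day_labels, mort, recov):
            rows.append({"feature_id": fid, "day": day, "mortality_pct": m, "recovery_pct": r})
    axes[0, 0].legend(fontsize=6)
    fig.supxlabel("days before discharge/death", fontsize=8)
    fig.supylabel("occurrence frequency (%)", fontsize=8)
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    curves = pd.DataFrame(rows)
    curves.to_csv(out_path.with_suffix(".csv"), index=False)
    return curves


def plot_rank_heatmap(rank_df: pd.DataFrame, out_path: str | Path) -> None:
    """Method x feature heatmap of importance ranks (red = high rank)."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * rank_df.shape[1], 1.0 + 0.25 * rank_df.shape[0])
    )
    im = ax.imshow(rank_df.to_numpy(), aspect="auto", cmap="RdBu")
    ax.set_xticks(range(rank_df.shape[1]), rank_df.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(rank_df.shape[0]), rank_df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="rank")
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    rank_df.to_csv(out_path.with_suffix(".csv"))
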