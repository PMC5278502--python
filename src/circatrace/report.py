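"""Figure rendering: heatmaps and significance-annotated time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .prep import HeatmapMatrix


def plot_heatmap(heatmap: HeatmapMatrix, path) -> None:
    """Render the row-ordered heatmap; values above the ceiling saturate."""
    vals = heatmap.values.to_numpy()
    vmax = heatmap.ceiling if heatmap.ceiling is not None else None
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * vals.shape[0])))
    im = ax.imshow(vals, aspect="auto", cmap="inferno", vmin=0, vmax=vmax,
                   extent=[heatmap.values.columns[0], heatmap.values.columns[-1],
                           vals.shape[0], 0])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cells (ordered by 24-h max)")
    fig.colorbar(im, ax=ax, label="relative intensity (fold t=0)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_response(normalized: pd.DataFrame, results: pd.DataFrame, path,
                  reference_group: str = "Vehicle", alpha: float = 0.05) -> None:
    """Mean +/- SEM fold-change per group over time, one panel per class.

    Timepoints where a group differs from the reference (Sidak-adjusted
    p < alpha) are marked with that group's star tier.
    """
    classes = sorted(normalized["neuron_class"].unique())
    groups = sorted(normalized["group"].unique())
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 3.2),
                             sharey=True, squeeze=False)
    for ax, ncls in zip(axes[0], classes):
        sub = normalized[normalized["neuron_class"] == ncls]
        for g in groups:
            gg = sub[sub["group"] == g]
            agg = gg.groupby("time_hr")["intensity"].agg(["mean", "sem"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=g,
                        marker="o", markersize=3, capsize=2)
        res = results[(results["neuron_class"] == ncls)
                      & (results["p_sidak"] < alpha)]
        for _, row in res.iterrows():
            ax.annotate(row["significance_tier"], (row["time_hr"], 0.98),
                        xycoords=("data", "axes fraction"), ha="center",
                        fontsize=7)
        ax.set_title(ncls)
        ax.set_xlabel("time (h)")
    axes[0][0].set_ylabel("relative intensity (fold t=0)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
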