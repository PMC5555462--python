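"""Manhattan plots and strain bar charts (native matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scan import ThresholdSet

_CHROM_COLORS = ("#33568c", "#8c9cc0")


def _cumulative_positions(scan: pd.DataFrame):
    """Offset each chromosome along a single genome axis."""
    offsets = {}
    ticks = {}
    cursor = 0.0
    for chrom, sub in scan.groupby("chrom", sort=False):
        offsets[chrom] = cursor
        span = sub["pos_mbp"].max()
        ticks[chrom] = cursor + span / 2.0
        cursor += span + 10.0  # 10 Mbp inter-chromosome gap
    x = scan["pos_mbp"].to_numpy() + scan["chrom"].map(offsets).to_numpy()
    return x, ticks


def manhattan_plot(
    scan: pd.DataFrame,
    threshold: ThresholdSet | None = None,
    ax=None,
    out_path=None,
    title: str | None = None,
):
    """Per-marker -log10(p) against cumulative genome position.

    Chromosomes alternate between two shades; a horizontal line marks the
    permutation threshold. Skipped markers are omitted. Layout is
    deterministic given the inputs.
    """
    plotted = scan[~scan["skipped"]]
    if plotted.empty:
        raise ValueError("nothing to plot: all markers skipped")
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(10, 3))
    else:
        fig = ax.figure

    x, ticks = _cumulative_positions(scan)
    x = x[~scan["skipped"].to_numpy()]
    y = plotted["neg_log10_p"].to_numpy()
    chrom_order = list(dict.fromkeys(scan["chrom"]))
    color_of = {c: _CHROM_COLORS[i % 2] for i, c in enumerate(chrom_order)}
    colors = plotted["chrom"].map(color_of).to_numpy()
    ax.scatter(x, y, s=6, c=colors, linewidths=0)

    if threshold is not None:
        ax.axhline(
            threshold.threshold_neg_log10, color="#c23b22", ls="--", lw=1,
            label=f"α = {threshold.alpha} ({threshold.n_perm} permutations)",
        )
        ax.legend(loc="upper right", fontsize=8, frameon=False)
    ax.set_xticks([ticks[c] for c in chrom_order])
    ax.set_xticklabels(chrom_order, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title, fontsize=10)

    if out_path is not None:
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def manhattan_grid(
    scans: dict[str, pd.DataFrame],
    thresholds: dict[str, ThresholdSet],
    out_path=None,
):
    """One Manhattan panel per condition, stacked vertically (the usual
    baseline / sensitized / challenged layout)."""
    n = len(scans)
    fig, axes = plt.subplots(n, 1, figsize=(10, 3 * n), squeeze=False)
    for ax, (cond, scan) in zip(axes[:, 0], scans.items()):
        manhattan_plot(scan, thresholds.get(cond), ax=ax, title=cond)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def strain_barplot(
    summaries: pd.DataFrame,
    condition: str,
    parental_strains: tuple[str, str] = ("A/J", "C57BL/6J"),
    ax=None,
    out_path=None,
):
    """Mean +/- SEM of log2 IgE per strain with parental reference lines."""
    sub = summaries[summaries["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no summaries for condition {condition!r}")
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(sub)), 3.5))
    else:
        fig = ax.figure
    order = sub.sort_values("strain")
    xs = np.arange(len(order))
    ax.bar(
        xs, order["mean_log2"], yerr=order["sem_log2"].fillna(0),
        color="#8c9cc0", edgecolor="#33568c", capsize=2,
    )
    for strain, style in zip(parental_strains, ("-", "--")):
        row = order[order["strain"] == strain]
        if not row.empty:
            ax.axhline(
                float(row["mean_log2"].iloc[0]), color="#c23b22",
                ls=style, lw=1, label=strain,
            )
    ax.set_xticks(xs)
    ax.set_xticklabels(order["strain"], rotation=90, fontsize=6)
    ax.set_ylabel(r"mean $\log_2$(IgE) ± SEM")
    ax.set_title(condition, fontsize=10)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=7, frameon=False)
    if out_path is not None:
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
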