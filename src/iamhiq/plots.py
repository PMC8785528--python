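"""Diagnostic figures: dual Manhattan-like track plot and the bubble plot.

Both functions write a figure to disk and return the matplotlib ``Figure``
so callers (and tests) can inspect the drawn artists.  These plots are
diagnostic summaries, not numeric outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse
from scipy.stats import chi2

__all__ = ["manhattan_dual_plot", "bubble_plot"]

DEFAULT_BUBBLE_GRID = 0.01


def _genome_x(metrics: pd.DataFrame):
    """Cumulative x-coordinate across chromosomes plus tick positions."""
    x = np.empty(len(metrics), dtype=float)
    offset = 0.0
    ticks, labels = [], []
    order = metrics["chrom"].drop_duplicates().tolist()
    for chrom in order:
        sel = (metrics["chrom"] == chrom).to_numpy()
        pos = metrics.loc[sel, "position"].to_numpy(dtype=float)
        x[sel] = offset + pos
        ticks.append(offset + (pos.min() + pos.max()) / 2.0)
        labels.append(str(chrom))
        offset += pos.max() + 1.0
    return x, ticks, labels


def manhattan_dual_plot(
    metrics: pd.DataFrame,
    iam_threshold: float,
    hiq_threshold: float,
    regions=None,
    path=None,
):
    """Two stacked genome tracks: hiQ on top (red), Iam_hwe below (blue).

    Horizontal lines mark the thresholds; hot / very-hot regions, when
    supplied, are shaded orange / red spans on the matching panel.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    metrics = metrics.sort_values(["chrom", "position"], kind="stable")
    x, ticks, labels = _genome_x(metrics)

    fig, (ax_hiq, ax_iam) = plt.subplots(
        2, 1, sharex=True, figsize=(10, 5), constrained_layout=True
    )
    ax_hiq.scatter(x, metrics["hiq"], s=2, color="tab:red", rasterized=True)
    ax_hiq.axhline(hiq_threshold, color="black", linestyle="--", linewidth=0.8)
    ax_hiq.set_ylabel("hiQ")
    ax_iam.scatter(x, metrics["iam_hwe"], s=2, color="tab:blue", rasterized=True)
    ax_iam.axhline(iam_threshold, color="black", linestyle="--", linewidth=0.8)
    ax_iam.set_ylabel("Iam_hwe")
    ax_iam.set_xticks(ticks, labels)
    ax_iam.set_xlabel("chromosome")

    if regions:
        offsets = {}
        off = 0.0
        for chrom in metrics["chrom"].drop_duplicates():
            pos = metrics.loc[metrics["chrom"] == chrom, "position"]
            offsets[str(chrom)] = off
            off += float(pos.max()) + 1.0
        for r in regions:
            ax = ax_hiq if r.metric == "hiq" else ax_iam
            o = offsets.get(str(r.chrom))
            if o is None:
                continue
            color = "red" if r.severity == "very_hot" else "orange"
            ax.axvspan(
                o + r.start_bp,
                o + r.end_bp,
                color=color,
                alpha=0.3,
                label=f"{r.metric}_{r.severity}",
            )
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def bubble_plot(
    metrics: pd.DataFrame,
    fit=None,
    path=None,
    grid: float = DEFAULT_BUBBLE_GRID,
):
    """Iam_hwe vs hiQ scatter with grid-aggregated, size-scaled bubbles.

    Markers are snapped to a ``grid`` x ``grid`` lattice and each occupied
    cell drawn as one bubble whose area scales with its marker count.  When
    a robust fit is supplied its coverage ellipse is overlaid (dotted); the
    ellipse's coordinate-wise extremes equal the fit's lower bounds.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    pts = metrics.loc[:, ["iam_hwe", "hiq"]].dropna()
    gx = np.round(pts["iam_hwe"] / grid) * grid
    gy = np.round(pts["hiq"] / grid) * grid
    counts = pd.DataFrame({"x": gx, "y": gy}).value_counts().reset_index(name="n")

    fig, ax = plt.subplots(figsize=(6, 6), constrained_layout=True)
    sizes = 8.0 + 120.0 * counts["n"] / counts["n"].max()
    ax.scatter(counts["x"], counts["y"], s=sizes, alpha=0.5, color="grey")
    ax.set_xlabel("Iam_hwe")
    ax.set_ylabel("hiQ")

    if fit is not None:
        # coverage ellipse: axes along Sigma's eigenvectors, half-widths
        # sqrt(chi2_2(coverage) * eigenvalue)
        evals, evecs = np.linalg.eigh(fit.sigma)
        c = chi2.ppf(fit.coverage, df=2)
        angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
        ax.add_patch(
            Ellipse(
                xy=tuple(fit.mu),
                width=2.0 * np.sqrt(c * evals[1]),
                height=2.0 * np.sqrt(c * evals[0]),
                angle=angle,
                fill=False,
                linestyle=":",
                edgecolor="black",
            )
        )
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
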