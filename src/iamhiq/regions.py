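"""EWMA smoothing along chromosomes and calling of low-accuracy regions.

Single poorly imputed markers are easy to filter; *runs* of them point at
genomic regions that imputation handled badly (typically near centromeres
and telomeres).  To find such runs, each per-marker index (Iam_hwe or hiQ)
is smoothed along the chromosome with a one-sided exponentially weighted
moving average, ``s_1 = x_1`` and ``s_t = a*x_t + (1-a)*s_{t-1}`` with
smoothing factor ``a = 0.1`` by default, restarted on every chromosome.
Maximal runs of consecutive markers whose smoothed value falls strictly
below the filtering threshold form a "hot region"; runs below half the
threshold form a "very hot region" (reported independently, typically
nested inside hot regions).  Region bounds are 1-based closed intervals at
the positions of the first and last member markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SmoothedTrack",
    "AccuracyRegion",
    "ewma_smooth",
    "smooth_tracks",
    "call_regions",
    "summarize_regions",
    "write_regions",
]

DEFAULT_SMOOTHING_FACTOR = 0.1
DEFAULT_VERY_HOT_FACTOR = 0.5


@dataclass
class SmoothedTrack:
    """One chromosome's raw and EWMA-smoothed index values, position-ordered."""

    chrom: str
    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    smoothing_factor: float
    metric: str = "iam"


@dataclass(frozen=True)
class AccuracyRegion:
    """A maximal run of markers with smoothed index below a cutoff.

    Coordinates are 1-based closed; singleton regions (start == end) occur
    whenever an isolated marker dips below the cutoff.
    """

    chrom: str
    start_bp: int
    end_bp: int
    n_variants: int
    metric: str
    severity: str  # "hot" or "very_hot"
    min_smoothed: float


def ewma_smooth(values, smoothing_factor: float = DEFAULT_SMOOTHING_FACTOR):
    """One-sided EWMA of a series; NaN entries carry state and stay NaN.

    The recursion is ``s_1 = x_1``, ``s_t = a*x_t + (1-a)*s_{t-1}``.  An
    undefined (NaN) input neither updates nor resets the state: the next
    defined value is smoothed against the last defined state, and the
    output at the NaN position is NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not 0.0 < smoothing_factor <= 1.0:
        raise ValueError(f"smoothing factor must lie in (0, 1], got {smoothing_factor}")
    s = (
        pd.Series(x)
        .ewm(alpha=smoothing_factor, adjust=False, ignore_na=True)
        .mean()
        .to_numpy()
    )
    s[~np.isfinite(x)] = np.nan
    return s


def smooth_tracks(
    metrics: pd.DataFrame,
    metric: str = "iam_hwe",
    smoothing_factor: float = DEFAULT_SMOOTHING_FACTOR,
    reverse: bool = False,
) -> list:
    """Build one :class:`SmoothedTrack` per chromosome from a metrics table.

    Markers are sorted by position within each chromosome; the EWMA restarts
    on every chromosome.  ``reverse=True`` runs the pass in descending
    position order (sensitivity analysis for the one-sided smoother).
    """
    short = {"iam_hwe": "iam", "iam_chance": "iam", "hiq": "hiq"}.get(metric, metric)
    tracks = []
    for chrom, grp in metrics.groupby("chrom", sort=True):
        grp = grp.sort_values("position", kind="stable")
        pos = grp["position"].to_numpy(dtype=int)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {chrom}: positions not strictly increasing")
        raw = grp[metric].to_numpy(dtype=float)
        smoothed = (
            ewma_smooth(raw[::-1], smoothing_factor)[::-1]
            if reverse
            else ewma_smooth(raw, smoothing_factor)
        )
        tracks.append(
            SmoothedTrack(
                chrom=str(chrom),
                positions=pos,
                raw=raw,
                smoothed=smoothed,
                smoothing_factor=smoothing_factor,
                metric=short,
            )
        )
    return tracks


def _runs(mask: np.ndarray):
    """Yield (start_idx, end_idx) inclusive for maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def call_regions(
    track: SmoothedTrack,
    threshold: float,
    very_hot_factor: float = DEFAULT_VERY_HOT_FACTOR,
) -> list:
    """Call hot and very-hot regions from a smoothed track.

    Hot regions are maximal runs with ``smoothed < threshold``; very-hot
    regions are maximal runs with ``smoothed < threshold * very_hot_factor``,
    reported independently (they may nest inside hot regions).  NaN smoothed
    values are never region members.  Comparison is strict (<).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    regions = []
    for severity, cutoff in (
        ("hot", threshold),
        ("very_hot", threshold * very_hot_factor),
    ):
        with np.errstate(invalid="ignore"):
            below = track.smoothed < cutoff  # NaN compares False
        for s, e in _runs(below):
            regions.append(
                AccuracyRegion(
                    chrom=track.chrom,
                    start_bp=int(track.positions[s]),
                    end_bp=int(track.positions[e]),
                    n_variants=e - s + 1,
                    metric=track.metric,
                    severity=severity,
                    min_smoothed=float(np.nanmin(track.smoothed[s : e + 1])),
                )
            )
    return regions


def summarize_regions(regions) -> pd.DataFrame:
    """Tally regions by metric and severity.

    Returns one row per (metric, severity) with region/variant counts, the
    singleton fraction and size quantiles; empty input gives an empty frame
    with the same columns.
    """
    cols = [
        "metric",
        "severity",
        "n_regions",
        "n_variants",
        "fraction_singleton",
        "size_min",
        "size_median",
        "size_max",
    ]
    if not regions:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "metric": [r.metric for r in regions],
            "severity": [r.severity for r in regions],
            "size": [r.n_variants for r in regions],
        }
    )
    rows = []
    for (metric, severity), grp in df.groupby(["metric", "severity"], sort=True):
        sizes = grp["size"].to_numpy()
        rows.append(
            {
                "metric": metric,
                "severity": severity,
                "n_regions": sizes.size,
                "n_variants": int(sizes.sum()),
                "fraction_singleton": float((sizes == 1).mean()),
                "size_min": int(sizes.min()),
                "size_median": float(np.median(sizes)),
                "size_max": int(sizes.max()),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def write_regions(regions, path, bed: bool = False) -> None:
    """Write regions as TSV; 1-based closed by default, BED-style if ``bed``.

    The default dialect keeps a commented header noting the coordinate
    convention; the BED export shifts to 0-based half-open intervals.
    """
    with open(path, "wt") as fh:
        if bed:
            for i, r in enumerate(sorted(regions, key=lambda r: (r.chrom, r.start_bp))):
                name = f"{r.metric}_{r.severity}_{i + 1}"
                fh.write(
                    f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\t0\t.\n"
                )
            return
        fh.write("# coordinates: 1-based, closed intervals\n")
        fh.write(
            "chrom\tstart_bp\tend_bp\tname\tmin_smoothed\tn_variants\tseverity\n"
        )
        for i, r in enumerate(sorted(regions, key=lambda r: (r.chrom, r.start_bp))):
            name = f"{r.metric}_{r.severity}_{i + 1}"
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{name}"
                f"\t{r.min_smoothed:.6g}\t{r.n_variants}\t{r.severity}\n"
            )
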