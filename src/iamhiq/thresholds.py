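"""Data-driven filtering thresholds from a robust bivariate-normal fit.

Most markers in a well-imputed dataset cluster tightly near (1, 1) in the
(Iam_hwe, hiQ) plane, with a thin tail of poorly imputed markers.  Treating
the bulk as a hidden two-dimensional normal distribution (ignoring the
indices' upper bounds), a robust location/scatter estimate yields a
*random region* — the coverage ellipse at probability 1 - 1e-9 by default —
whose coordinate-wise lower extremes serve as conservative, data-driven
lower bounds for marker filtering.  Robustness comes from iterative hard
trimming: points whose squared Mahalanobis distance exceeds the chi-square
(2 df) quantile at 1 - outlier_alpha are discarded and the moments
re-estimated until the retained set stabilizes.

When no fit is wanted, the suggested general-use operating thresholds are
0.5 for Iam_hwe and 0.9 for hiQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "DEFAULT_IAM_THRESHOLD",
    "DEFAULT_HIQ_THRESHOLD",
    "RobustBivariateFit",
    "ClassificationTable",
    "fit_robust_bivariate",
    "classify_markers",
]

DEFAULT_IAM_THRESHOLD = 0.5
DEFAULT_HIQ_THRESHOLD = 0.9
DEFAULT_COVERAGE = 1.0 - 1e-9
DEFAULT_OUTLIER_ALPHA = 1e-6

_COORDS = ("iam_hwe", "hiq")


@dataclass(frozen=True)
class RobustBivariateFit:
    """Robust location/scatter of (Iam_hwe, hiQ) and derived lower bounds.

    ``iam_lower`` / ``hiq_lower`` are the coordinate-wise extremes of the
    coverage ellipse: ``mu_j - sqrt(chi2_2(coverage) * sigma_jj)``.
    """

    mu: np.ndarray
    sigma: np.ndarray
    coverage: float
    iam_lower: float
    hiq_lower: float
    n_markers_used: int
    n_flagged_outliers: int


def fit_robust_bivariate(
    metrics: pd.DataFrame,
    coverage: float = DEFAULT_COVERAGE,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    max_iter: int = 50,
) -> RobustBivariateFit:
    """Fit a robust bivariate normal to the (iam_hwe, hiq) columns.

    Initialization uses coordinate-wise medians with a MAD-based diagonal
    scatter; each iteration recomputes squared Mahalanobis distances, drops
    points above the chi-square(2) quantile at ``1 - outlier_alpha``, and
    re-estimates mean and covariance from the retained points, until the
    retained set is unchanged or ``max_iter`` passes.

    Markers with undefined (NaN) ``iam_hwe`` or ``hiq`` are excluded from
    the fit.  Raises ``ValueError`` with fewer than 10 usable markers or
    when a coordinate has zero spread (degenerate scatter).
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage}")
    if not 0.0 < outlier_alpha < 1.0:
        raise ValueError(f"outlier_alpha must lie in (0, 1), got {outlier_alpha}")

    x = metrics.loc[:, list(_COORDS)].to_numpy(dtype=float)
    x = x[np.isfinite(x).all(axis=1)]
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"robust fit needs >= 10 markers with defined indices, got {n}")

    mu = np.median(x, axis=0)
    mad = np.median(np.abs(x - mu), axis=0)
    scale = 1.4826 * mad  # normal-consistent MAD
    fallback = x.std(axis=0, ddof=1)
    scale = np.where(scale > 0.0, scale, fallback)
    for j, s in enumerate(scale):
        if s == 0.0:
            raise ValueError(f"degenerate scatter: zero spread in coordinate {_COORDS[j]!r}")
    sigma = np.diag(scale**2)

    cut = chi2.ppf(1.0 - outlier_alpha, df=2)
    retained = None
    for _ in range(max_iter):
        diff = x - mu
        d2 = np.einsum("ij,ij->i", diff @ np.linalg.inv(sigma), diff)
        new_retained = d2 <= cut
        if new_retained.sum() < 10:
            raise ValueError("robust fit trimmed below 10 markers; data too dispersed")
        converged = retained is not None and np.array_equal(new_retained, retained)
        retained = new_retained
        kept = x[retained]
        mu = kept.mean(axis=0)
        sigma = np.cov(kept, rowvar=False)
        for j in range(2):
            if sigma[j, j] <= 0.0:
                raise ValueError(
                    f"degenerate scatter: zero spread in coordinate {_COORDS[j]!r}"
                )
        if converged:
            break

    half = np.sqrt(chi2.ppf(coverage, df=2) * np.diag(sigma))
    return RobustBivariateFit(
        mu=mu,
        sigma=sigma,
        coverage=coverage,
        iam_lower=float(mu[0] - half[0]),
        hiq_lower=float(mu[1] - half[1]),
        n_markers_used=int(retained.sum()),
        n_flagged_outliers=int(n - retained.sum()),
    )


@dataclass(frozen=True)
class ClassificationTable:
    """Per-stratum 2x2 marker counts against the (Iam_hwe, hiQ) thresholds.

    ``table`` holds one row per stratum and cell with columns
    ``stratum, iam_below, hiq_below, n, proportion``; proportions sum to 1
    within each stratum.  Markers with undefined ``iam_hwe`` count as
    below-threshold (conservative) and are also tallied separately in
    ``n_undefined_iam``.
    """

    table: pd.DataFrame
    iam_threshold: float
    hiq_threshold: float
    n_total: int
    n_undefined_iam: int

    def pass_proportion(self, stratum: str = "all") -> float:
        """Fraction of a stratum's markers at or above both thresholds."""
        t = self.table
        row = t[(t["stratum"] == stratum) & ~t["iam_below"] & ~t["hiq_below"]]
        return float(row["proportion"].iloc[0]) if len(row) else 0.0


def _cells(iam_below: np.ndarray, hiq_below: np.ndarray, stratum: str) -> list:
    n = iam_below.size
    rows = []
    for ib in (True, False):
        for hb in (True, False):
            count = int(np.sum((iam_below == ib) & (hiq_below == hb)))
            rows.append(
                {
                    "stratum": stratum,
                    "iam_below": ib,
                    "hiq_below": hb,
                    "n": count,
                    "proportion": count / n if n else 0.0,
                }
            )
    return rows


def classify_markers(
    metrics: pd.DataFrame,
    iam_threshold: float = DEFAULT_IAM_THRESHOLD,
    hiq_threshold: float = DEFAULT_HIQ_THRESHOLD,
    maf_bins=None,
    quality_col: str | None = None,
) -> ClassificationTable:
    """Cross-classify markers by (iam_hwe, hiq) against two thresholds.

    ``maf_bins`` (a monotone sequence of bin edges applied to ``maf_hat``)
    and ``quality_col`` (a column of external quality labels) each add
    per-stratum breakdowns alongside the overall "all" stratum.  Strict
    comparison: a marker is *below* when its index ``< threshold``; an
    undefined ``iam_hwe`` is conservatively below.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    if not np.isfinite(iam_threshold) or not np.isfinite(hiq_threshold):
        raise ValueError("thresholds must be finite")

    iam = metrics["iam_hwe"].to_numpy(dtype=float)
    hq = metrics["hiq"].to_numpy(dtype=float)
    undef = ~np.isfinite(iam)
    iam_below = np.where(undef, True, iam < iam_threshold)
    hiq_below = np.where(np.isfinite(hq), hq < hiq_threshold, True)

    rows = _cells(iam_below, hiq_below, "all")
    if maf_bins is not None:
        maf = metrics["maf_hat"].to_numpy(dtype=float)
        binned = pd.cut(maf, bins=list(maf_bins), include_lowest=True)
        for interval in binned.categories:
            sel = np.asarray(binned == interval)
            if sel.any():
                rows.extend(
                    _cells(iam_below[sel], hiq_below[sel], f"maf:{interval}")
                )
    if quality_col is not None:
        labels = metrics[quality_col]
        for label in pd.unique(labels):
            sel = (labels == label).to_numpy()
            rows.extend(_cells(iam_below[sel], hiq_below[sel], f"{quality_col}:{label}"))

    return ClassificationTable(
        table=pd.DataFrame(rows),
        iam_threshold=iam_threshold,
        hiq_threshold=hiq_threshold,
        n_total=len(metrics),
        n_undefined_iam=int(undef.sum()),
    )
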