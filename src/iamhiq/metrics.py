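"""Per-marker imputation accuracy indices computed from dosage triplets.

Imputation software reports, for every untyped marker and every individual,
a triplet of a-posteriori genotype probabilities ``(p0, p1, p2)`` (the
*dosages*), one probability per allele dose ``g in {0, 1, 2}``.  Two
complementary indices are computed from these triplets:

``Iam`` (imputation accuracy measure)
    Quantifies how much *individual-specific* genotype information the
    dosages carry, as opposed to chance-level or purely population-level
    (Hardy-Weinberg) information.  It is built on the anti-concentration
    statistic ``Q = sum_g p_g (1 - p_g)``, the complement of the
    Herfindahl-Hirschman concentration index of the triplet: ``Q = 0`` for a
    one-hot triplet (the genotype is known), ``Q = 2/3`` for the uniform
    triplet (the imputation failed completely).  The marker mean ``Q̄`` is
    rescaled in two ways:

    * ``Iam_chance = 1 - Q̄ / (2/3)`` — 1 when every triplet is one-hot,
      0 when every triplet is uniform;
    * ``Iam_hwe = 1 - Q̄ / Q_HWE(f̂)`` — 1 when every triplet is one-hot,
      0 when the triplets carry exactly the information of the population
      allele frequency under Hardy-Weinberg equilibrium.  ``Iam_hwe`` may be
      negative (triplets flatter than the HWE anchor) and is undefined when
      ``Q_HWE(f̂) = 0``, i.e. for a monomorphic dosage-implied frequency.

``hiQ`` (heterogeneity in quantities of dosages)
    One minus the Hellinger distance between the marker's *average dosage*
    distribution ``f_ad`` (component-wise mean of the triplets) and its
    *average best-guess* distribution ``f_bg`` (mean of the one-hot
    best-guess vectors).  ``hiQ = 1`` when the two distributions coincide —
    the dosages are as heterogeneous across individuals as their best
    guesses — and decreases towards 0 as inter-individual heterogeneity is
    lost to shared, blurred dosages.

All quantities need nothing beyond the dosage file itself; the allele
frequency is estimated from the same triplets as ``f̂ = Σ d_i / (2N)`` with
allele dose ``d_i = p1 + 2 p2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerAccuracy",
    "FLAG_IAM_HWE_UNDEFINED",
    "FLAG_RENORMALIZED",
    "FLAG_MISSING_EXCLUDED",
    "estimate_allele_freq",
    "anti_concentration",
    "q_hwe",
    "iam_chance",
    "iam_hwe",
    "average_dosage_dist",
    "best_guess_dist",
    "hiq",
    "compute_marker",
]

#: the mean anti-concentration of the uniform triplet — upper bound of Q
Q_CHANCE = 2.0 / 3.0

FLAG_IAM_HWE_UNDEFINED = "IAM_HWE_UNDEFINED"
FLAG_RENORMALIZED = "RENORMALIZED"
FLAG_MISSING_EXCLUDED = "MISSING_EXCLUDED"

_RANGE_TOL = 1e-9
_NORM_TOL = 1e-6


@dataclass(frozen=True)
class MarkerAccuracy:
    """Derived accuracy quantities for one marker.

    ``iam_hwe`` is ``nan`` when the HWE anchor vanishes (``maf_hat`` of
    exactly 0 or 1); the ``IAM_HWE_UNDEFINED`` flag records that case.
    ``n_used`` counts the individuals contributing after missing-dosage
    exclusion (all-zero triplets).
    """

    maf_hat: float
    q_bar: float
    iam_chance: float
    iam_hwe: float
    hiq: float
    n_used: int
    flags: frozenset = field(default_factory=frozenset)


def _probs_2d(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"expected an N x 3 probability matrix, got shape {p.shape}")
    return p


def _usable_mask(p: np.ndarray) -> np.ndarray:
    # all-zero triplet = missing individual (IMPUTE2 convention)
    return p.sum(axis=1) > 0.0


def estimate_allele_freq(probs) -> float:
    """Dosage-based allele frequency f̂ = Σ d_i / (2 n), d_i = p1 + 2 p2.

    All-zero (missing) triplets are excluded from both the sum and the
    denominator.  Raises ``ValueError`` when no usable individual remains.
    """
    p = _probs_2d(probs)
    mask = _usable_mask(p)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("no usable (non-missing) individuals")
    d = p[mask, 1] + 2.0 * p[mask, 2]
    return float(d.sum() / (2.0 * n_used))


def anti_concentration(triplet) -> float:
    """Q = Σ_g p_g (1 − p_g) for one normalized triplet.

    Equals ``1 − Σ p_g²``; 0 for a one-hot triplet, 2/3 for the uniform one.
    """
    p = np.asarray(triplet, dtype=float)
    return float(np.sum(p * (1.0 - p)))


def q_hwe(f):
    """Anti-concentration of the Hardy-Weinberg triplet at allele frequency f.

    Closed form ``(−2f)(f − 1)(3f² − 3f + 2)``.  Symmetric under
    ``f ↔ 1 − f``, zero at the boundaries and maximal (0.625) at f = 0.5.
    Accepts scalars or arrays.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    out = (-2.0 * f) * (f - 1.0) * (3.0 * f * f - 3.0 * f + 2.0)
    return float(out) if out.ndim == 0 else out


def iam_chance(q_bar: float) -> float:
    """Rescale mean anti-concentration against the chance anchor 2/3."""
    if q_bar < -_RANGE_TOL or q_bar > Q_CHANCE + _RANGE_TOL:
        raise ValueError(f"q_bar {q_bar} outside [0, 2/3]")
    q_bar = min(max(q_bar, 0.0), Q_CHANCE)
    return 1.0 - q_bar / Q_CHANCE


def iam_hwe(q_bar: float, f: float) -> float:
    """Rescale mean anti-concentration against the HWE anchor Q_HWE(f).

    Returns ``nan`` when ``Q_HWE(f) = 0`` (f exactly 0 or 1): the anchor
    degenerates and the index is undefined rather than infinite.  Negative
    values (triplets flatter than the HWE triplet) are returned as-is.
    """
    if q_bar < -_RANGE_TOL or q_bar > Q_CHANCE + _RANGE_TOL:
        raise ValueError(f"q_bar {q_bar} outside [0, 2/3]")
    anchor = q_hwe(f)
    if anchor == 0.0:
        return float("nan")
    return 1.0 - max(q_bar, 0.0) / anchor


def average_dosage_dist(probs) -> np.ndarray:
    """Component-wise mean of the usable triplets; a probability 3-vector."""
    p = _probs_2d(probs)
    mask = _usable_mask(p)
    if not mask.any():
        raise ValueError("no usable (non-missing) individuals")
    return p[mask].mean(axis=0)


def best_guess_dist(probs) -> np.ndarray:
    """Mean of one-hot best-guess vectors; ties share mass equally.

    Each individual contributes a one-hot vector at the genotype of maximal
    probability.  When k genotypes tie for the maximum, the individual
    contributes 1/k to each, keeping the result a deterministic probability
    vector with no directional bias.
    """
    p = _probs_2d(probs)
    mask = _usable_mask(p)
    if not mask.any():
        raise ValueError("no usable (non-missing) individuals")
    p = p[mask]
    is_max = p == p.max(axis=1, keepdims=True)
    onehot = is_max / is_max.sum(axis=1, keepdims=True)
    return onehot.mean(axis=0)


def hiq(f_ad, f_bg) -> float:
    """1 minus the Hellinger distance between two trinomial distributions.

    ``hiq = 1 − sqrt(1 − Σ_g sqrt(f_ad(g) f_bg(g)))``.  Equals 1 iff the two
    distributions coincide and 0 when their supports are disjoint.  The
    squared Hellinger distance is evaluated in the algebraically equivalent
    form ``½ Σ (√f_ad − √f_bg)²`` (exact for normalized vectors), which is
    exactly zero at coincidence instead of accumulating 1e-15-level rounding
    from the Bhattacharyya sum.
    """
    a = np.asarray(f_ad, dtype=float)
    b = np.asarray(f_bg, dtype=float)
    for name, v in (("f_ad", a), ("f_bg", b)):
        if v.shape != (3,):
            raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
        if np.any(v < 0.0) or abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} is not a probability vector: {v}")
    h2 = 0.5 * float(np.sum((np.sqrt(a) - np.sqrt(b)) ** 2))
    return 1.0 - float(np.sqrt(min(max(h2, 0.0), 1.0)))


def compute_marker(record, founder_mask=None) -> MarkerAccuracy:
    """All per-marker accuracy quantities for one dosage matrix.

    ``record`` is either an N x 3 probability matrix or any object with a
    ``.probs`` attribute holding one (e.g. a
    :class:`~iamhiq.io.MarkerRecord`).  All-zero triplets are treated as
    missing individuals and excluded; if every individual is missing the
    row is fully flagged and every metric is ``nan``.

    ``founder_mask`` optionally restricts the allele-frequency estimate to a
    boolean subset of individuals (unrelated founders in family data); all
    other quantities always use every usable individual.
    """
    flags = set()
    probs = getattr(record, "probs", record)
    if getattr(record, "n_renormalized", 0):
        flags.add(FLAG_RENORMALIZED)
    if getattr(record, "n_skipped", 0):
        flags.add(FLAG_MISSING_EXCLUDED)

    p = _probs_2d(probs)
    mask = _usable_mask(p)
    n_used = int(mask.sum())
    if n_used < p.shape[0]:
        flags.add(FLAG_MISSING_EXCLUDED)
    if n_used == 0:
        nan = float("nan")
        return MarkerAccuracy(nan, nan, nan, nan, nan, 0, frozenset(flags))

    usable = p[mask]
    if founder_mask is not None:
        fmask = np.asarray(founder_mask, dtype=bool) & mask
        if not fmask.any():
            raise ValueError("founder mask excludes every usable individual")
        f_hat = estimate_allele_freq(p[fmask])
    else:
        f_hat = estimate_allele_freq(usable)

    # mean over individuals of the per-row anti-concentration sums
    q_bar = float((usable * (1.0 - usable)).sum(axis=1).mean())
    q_bar = min(max(q_bar, 0.0), Q_CHANCE)

    i_hwe = iam_hwe(q_bar, f_hat)
    if np.isnan(i_hwe):
        flags.add(FLAG_IAM_HWE_UNDEFINED)

    return MarkerAccuracy(
        maf_hat=f_hat,
        q_bar=q_bar,
        iam_chance=iam_chance(q_bar),
        iam_hwe=i_hwe,
        hiq=hiq(average_dosage_dist(usable), best_guess_dist(usable)),
        n_used=n_used,
        flags=frozenset(flags),
    )
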