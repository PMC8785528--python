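"""Synthetic dosage datasets with controllable accuracy structure.

The generator emulates the output of genotype imputation without running an
imputation engine.  For each marker with allele frequency ``f`` a true
genotype ``G`` is drawn per individual from Hardy-Weinberg proportions
``((1-f)^2, 2f(1-f), f^2)``; the emitted dosage triplet is the mixture

    lam * onehot(G) + (1 - lam) * B

where ``lam`` in [0, 1] is the per-marker imputation accuracy and ``B`` is
a blur distribution:

* ``"hwe"`` — the HWE triplet at ``f`` (population-level information only);
* ``"uniform"`` — ``(1/3, 1/3, 1/3)`` (no information, pure chance);
* ``"homogeneous"`` — one arbitrary triplet shared by all individuals of
  the marker (inter-individual homogeneity with a non-trivial shape).

The endpoints reproduce the canonical limiting situations exactly:
``lam = 1`` gives one-hot triplets (Iam = hiQ = 1); ``lam = 0`` with
uniform blur gives Iam_chance = 0; ``lam = 0`` with HWE blur gives
Iam_hwe = 0 up to the sampling noise of the dosage-implied frequency.
Expected Iam rises monotonically in ``lam``.

Markers are laid on one chromosome at strictly increasing positions; spans
of markers can be assigned a lower accuracy (``HotRegionSpec``) to plant
detectable low-accuracy regions.  All randomness flows through one
explicitly seeded generator, so a fixed seed reproduces the dataset
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MarkerRecord, write_gen, write_sample_file

__all__ = [
    "BLUR_MODES",
    "HotRegionSpec",
    "SimulationConfig",
    "hwe_triplet",
    "simulate_marker",
    "simulate_dataset",
    "write_dataset",
]

BLUR_MODES = ("hwe", "uniform", "homogeneous")
_UNIFORM = np.full(3, 1.0 / 3.0)


@dataclass(frozen=True)
class HotRegionSpec:
    """A span of consecutive markers simulated with reduced accuracy."""

    start_index: int  # 0-based index of the first affected marker
    n_markers: int
    lambda_low: float

    def __post_init__(self):
        if self.start_index < 0 or self.n_markers < 1:
            raise ValueError("hot region span must be non-empty and start at >= 0")
        if not 0.0 <= self.lambda_low <= 1.0:
            raise ValueError("lambda_low must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dosage generator.

    ``maf_law`` is a fixed frequency, a ``(low, high)`` uniform range, or
    ``"low_enriched"`` — an equal mixture of uniform(0.0005, 0.05) and
    uniform(0.05, 0.5), mimicking arrays enriched with rare variants.
    ``accuracy_lambda`` is a global value, a ``(low, high)`` uniform range
    sampled per marker, or an explicit per-marker array.
    """

    n_individuals: int = 100
    n_markers: int = 50
    maf_law: object = (0.05, 0.5)
    accuracy_lambda: object = 1.0
    blur_mode: str = "hwe"
    hot_regions: tuple = field(default_factory=tuple)
    seed: int = 0
    chrom: str = "1"
    position_start: int = 10_001
    position_step: int = 1_000

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("n_individuals and n_markers must be >= 1")
        if self.blur_mode not in BLUR_MODES:
            raise ValueError(f"blur_mode must be one of {BLUR_MODES}")
        spans = []
        for spec in self.hot_regions:
            if spec.start_index + spec.n_markers > self.n_markers:
                raise ValueError("hot region extends past the last marker")
            spans.append((spec.start_index, spec.start_index + spec.n_markers))
        spans.sort()
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("hot region spans overlap")


def hwe_triplet(f: float) -> np.ndarray:
    """Hardy-Weinberg genotype distribution ((1-f)^2, 2f(1-f), f^2)."""
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])


def simulate_marker(f, n, lam, blur_mode="hwe", rng=None, blur_triplet=None):
    """Simulate one marker's N x 3 dosage matrix.

    Draws true genotypes from HWE at ``f`` and blends their one-hot vectors
    with the blur distribution at weight ``1 - lam``.  For
    ``blur_mode="homogeneous"`` the shared triplet is ``blur_triplet`` or,
    when omitted, a single Dirichlet(1,1,1) draw shared by all individuals.
    Rows sum to 1 by construction.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {f}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"accuracy lambda must lie in [0, 1], got {lam}")
    if blur_mode not in BLUR_MODES:
        raise ValueError(f"blur_mode must be one of {BLUR_MODES}")
    rng = np.random.default_rng() if rng is None else rng

    g = rng.choice(3, size=n, p=hwe_triplet(f))
    onehot = np.zeros((n, 3))
    onehot[np.arange(n), g] = 1.0

    if blur_mode == "hwe":
        blur = hwe_triplet(f)
    elif blur_mode == "uniform":
        blur = _UNIFORM
    else:
        blur = (
            np.asarray(blur_triplet, dtype=float)
            if blur_triplet is not None
            else rng.dirichlet(np.ones(3))
        )
        if blur.shape != (3,) or abs(blur.sum() - 1.0) > 1e-9 or np.any(blur < 0):
            raise ValueError(f"blur_triplet is not a probability 3-vector: {blur}")
    return lam * onehot + (1.0 - lam) * blur


def _draw_mafs(law, m, rng):
    if isinstance(law, str):
        if law != "low_enriched":
            raise ValueError(f"unknown maf law {law!r}")
        rare = rng.uniform(0.0005, 0.05, size=m)
        common = rng.uniform(0.05, 0.5, size=m)
        return np.where(rng.random(m) < 0.5, rare, common)
    if np.isscalar(law):
        return np.full(m, float(law))
    lo, hi = law
    return rng.uniform(lo, hi, size=m)


def _draw_lambdas(spec, m, rng):
    # tuple -> uniform range; array/list -> explicit per-marker values
    if np.isscalar(spec):
        return np.full(m, float(spec))
    if isinstance(spec, tuple):
        lo, hi = spec
        return rng.uniform(lo, hi, size=m)
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (m,):
        raise ValueError(f"accuracy_lambda must be scalar, (low, high) or length {m}")
    return arr.copy()


def simulate_dataset(config: SimulationConfig):
    """Generate a full synthetic dataset.

    Returns ``(records, sample_ids, lambdas)``: the marker records (strictly
    increasing positions on ``config.chrom``), the individual identifiers,
    and the per-marker accuracy actually used (after applying hot-region
    spans).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.n_markers, config.n_individuals
    mafs = _draw_mafs(config.maf_law, m, rng)
    lambdas = _draw_lambdas(config.accuracy_lambda, m, rng)
    for spec in config.hot_regions:
        lambdas[spec.start_index : spec.start_index + spec.n_markers] = spec.lambda_low

    records = []
    for j in range(m):
        probs = simulate_marker(mafs[j], n, lambdas[j], config.blur_mode, rng)
        pos = config.position_start + j * config.position_step
        records.append(
            MarkerRecord(
                snp_id=f"snp{j + 1}",
                rs_id=f"rs{j + 1}",
                chrom=config.chrom,
                position=pos,
                allele_a="A",
                allele_b="G",
                probs=probs,
            )
        )
    sample_ids = tuple(f"ind{i + 1}" for i in range(n))
    return records, sample_ids, lambdas


def write_dataset(config: SimulationConfig, gen_path, sample_path):
    """Generate a dataset and write it as GEN + SAMPLE files.

    Returns the per-marker accuracy vector used.  Byte-identical output for
    identical configs (probabilities written with round-tripping precision).
    """
    records, sample_ids, lambdas = simulate_dataset(config)
    write_gen(records, gen_path)
    write_sample_file(sample_ids, sample_path)
    return lambdas
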