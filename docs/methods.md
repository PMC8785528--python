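# Methods

## Model and rationale

Genotype imputation emits, per marker and individual, a triplet of
a-posteriori genotype probabilities (p₀, p₁, p₂) over allele doses
g ∈ {0, 1, 2}.  `iamhiq` assumes all imputation uncertainty is contained
in these triplets and derives two per-marker indices from them alone.

**Anti-concentration.** Q = Σ p_g(1 − p_g) = 1 − Σ p_g² measures how far a
triplet is from one-hot (Q = 0) toward uniform (Q = 2/3).  The marker mean
Q̄ is rescaled against two anchors:

- the *chance* anchor 2/3 (uniform triplet): Iam_chance = 1 − Q̄/(2/3);
- the *Hardy–Weinberg* anchor Q_HWE(f) = (−2f)(f − 1)(3f² − 3f + 2), the
  anti-concentration of the HWE triplet ((1−f)², 2f(1−f), f²):
  Iam_HWE = 1 − Q̄/Q_HWE(f̂).

The HWE triplet represents dosages that carry *only* the population
allele frequency, so Iam_HWE = 0 marks markers with no individual-specific
information.  Q_HWE shrinks rapidly with rarity (0.625 at f = 0.5, 0.039
at f = 0.01), which is why Iam_chance alone is misleading for rare
markers and both anchors are kept.  Iam_HWE can be negative (triplets
flatter than the HWE anchor, e.g. under local inbreeding or sample/
reference frequency mismatch); values are reported unclipped.  When
f̂ ∈ {0, 1} the anchor vanishes and Iam_HWE is undefined — reported as
NaN with an `IAM_HWE_UNDEFINED` flag, never as an error.

**Allele frequency.** f̂ = Σ d_i/(2N) with d_i = p₁ + 2p₂, estimated from
the same dosage matrix.  This is adequate for case–control and
cross-sectional samples; for family data a founders-only mask can be
passed to `compute_marker` so only unrelated individuals enter f̂.
Frequencies are reported unfolded (dose counts the B/ALT allele, f̂ may
exceed 0.5); every index is invariant under allele-orientation reversal,
so no folding is needed.

**Heterogeneity.** hiQ = 1 − H(f_ad, f_bg) where H is the Hellinger
distance, f_ad the component-wise mean of the triplets and f_bg the mean
of one-hot best-guess vectors.  hiQ = 1 iff the two distributions
coincide; lower values flag markers whose dosages are homogeneous across
individuals and therefore powerless for association testing even when
each triplet looks individually plausible.  Note the asymmetric floor: a
fully homogeneous marker does not reach hiQ = 0 (the shared triplet and
the degenerate best-guess distribution still overlap); the canonical
all-(0.6, 0.3, 0.1) marker yields 1 − √(1 − √0.6) ≈ 0.53.

## Numerical choices

- H² is evaluated as ½ Σ(√f_ad − √f_bg)², algebraically equal to
  1 − Σ√(f_ad f_bg) for normalized vectors but exactly zero at
  coincidence, so hiQ hits 1.0 without clipping heuristics.
- Best-guess ties split their mass equally among the tied genotypes,
  keeping f_bg a deterministic probability vector with no directional
  bias.
- Triplets with |Σp − 1| ≤ 10⁻³ are renormalized (GEN files round to few
  decimals); deviations below 10⁻⁹ are left bit-untouched so that files
  written by the simulator parse back exactly.  Larger deviations raise in
  strict mode or blank the individual (counted, flagged) in lenient mode.
- An all-zero triplet is the missing-genotype convention of GEN output;
  it is excluded from every average and decrements `n_used`.
- Q̄ is clipped into [0, 2/3] at the 10⁻¹⁵ level before rescaling.

## Thresholds

The marker cloud in the (Iam_HWE, hiQ) plane is modelled as a hidden
bivariate normal (ignoring the indices' upper bounds).  The fit is an
iterative trimmed-moment estimate: initialize with coordinate-wise
medians and a normal-consistent MAD diagonal scatter; then repeatedly
drop points whose squared Mahalanobis distance exceeds the χ²(2 df)
quantile at 1 − outlier_alpha (default 10⁻⁶) and re-estimate mean and
covariance from the retained points, until the retained set repeats
(guaranteed tie-free by the hard distance cut) or 50 iterations.  Lower
bounds are the coordinate-wise extremes of the coverage ellipse at
probability 1 − 10⁻⁹ by default: bound_j = μ_j − √(χ²₂(coverage)·Σ_jj).
The very conservative default coverage keeps the false-exclusion
probability negligible even across ten million markers.  Markers with
undefined Iam_HWE are excluded from the fit but classified conservatively
as below-threshold (and tallied separately).  Requirements: ≥ 10 usable
markers, non-degenerate spread in both coordinates; violations raise.

When no fit is wanted, the operating defaults are 0.5 (Iam_HWE) and 0.9
(hiQ) — round-number thresholds for general use, with 0.5 reading
directly as "less than ~50% individual-specific information on average".

## Region scan

Each index is smoothed per chromosome in ascending position order with a
one-sided EWMA, s₁ = x₁, s_t = α·x_t + (1 − α)s_{t−1}, α = 0.1 by
default (initialization at the first observation is the simplest
defensible convention for a causal moving average; an optional reverse
pass exposes direction sensitivity).  Undefined index values are
transparent: they neither update nor reset the state and are never region
members.  Maximal runs with s < threshold are "hot" regions; runs with
s < threshold/2 are "very hot", called independently so they typically
nest inside hot regions.  Comparison is strict.  Regions are reported as
1-based closed intervals (GEN coordinate convention) with an optional
0-based half-open BED export.

Because the smoother is causal, a region's boundaries lag a mid-
chromosome dip: the EWMA needs several markers to descend below the
threshold after the dip starts and several more to recover after it ends.
Boundary-exact recovery of a planted low-accuracy span (used in the test
suite) therefore places the span at the chromosome end against an
exactly-accurate background, where the entry marker already drops the
EWMA from 1.0 to 0.9·1 + 0.1·x < threshold and no trailing markers exist
to bleed into.

## Synthetic data generator

`simulate_marker` draws a true genotype per individual from HWE at
frequency f and emits λ·onehot(G) + (1 − λ)·B, with λ ∈ [0, 1] the
marker's imputation accuracy and B a blur distribution: the HWE triplet
at f (population-only information), the uniform triplet (chance), or one
shared arbitrary triplet (homogeneous dosages).  The three canonical
limiting situations are exact endpoints of the mixture, so endpoint
behavior is analytically forced: λ = 1 gives one-hot triplets
(Iam = hiQ = 1); λ = 0 with uniform blur gives Iam_chance = 0; λ = 0 with
HWE blur gives Q̄ = Q_HWE(f) exactly, hence Iam_HWE = 0 up to the
sampling noise of f̂.  Expected Iam is monotone in λ, and for λ > 2/3
every best guess equals the true genotype so hiQ → 1 as N grows.

Defaults: 100 individuals, 50 markers, MAF ~ uniform(0.05, 0.5); the
`low_enriched` law is an equal mixture of uniform(0.0005, 0.05) and
uniform(0.05, 0.5), emulating arrays enriched with rare variants where
roughly half the markers fall below 5% frequency.  Markers sit at 1 kb
spacing on one chromosome; spans can be assigned a reduced λ to plant
hot regions (overlapping spans rejected).  A single `numpy` Generator
seeded from the config is threaded through all draws — fixed seed, byte-
identical GEN output.

What the generator does *not* emulate: linkage disequilibrium between
markers, haplotype structure, reference-panel misphasing, genotyping
error, or relatedness.  Passing tests on synthetic data therefore
validate the indices' algebra and the pipeline's statistical behavior
under the stated model, not the accuracy of any particular imputation
engine on real cohorts.

## Problem sizes in the test suite

Statistical checks run at sizes chosen to make their tolerances sharp but
the suite quick: oracle equivalence on 200 random markers (tolerance
10⁻¹²); λ-rank-correlation at 200 markers × 10⁴ individuals (ρ > 0.9);
robust-fit recovery on 10⁵ simulated points (location within 3 Monte
Carlo standard errors, drift under 1% gross contamination bounded by a
tenth of the naive mean's shift); planted-region recovery at 200 markers
× 400 individuals.

## Known limitations

- Autosomes only: a correct HWE anchor on X/Y requires sex-aware genotype
  frequencies, which the package does not implement.
- Multi-allelic markers must be pre-split into pseudo-biallelic variants;
  no splitting rule is applied internally.
- The robust fit is a trimmed-moment scheme, not a high-breakdown MCD/
  M-estimator; with contamination fractions far above a few percent the
  initial MAD scatter may not isolate the bulk.
- The trimming uses only the χ² quantile cut; no separate leverage/
  outlier multiplier is applied.
- hiQ's floor depends on the shared-triplet shape, so its values are not
  comparable across markers of very different MAF without the companion
  Iam index — the pair is designed to be used together.
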