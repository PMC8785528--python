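# iamhiq

Post-imputation quality control for genome-wide association studies.
`iamhiq` computes **Iam** and **hiQ**, a complementary pair of per-marker
accuracy indices derived directly from the a-posteriori genotype
probability triplets ("dosages") that every imputation program emits, so
they work identically across IMPUTE2, Beagle, minimac and friends.  On top
of the per-marker indices it derives data-driven filtering thresholds from
a robust bivariate-normal random region and scans chromosomes with an
exponentially weighted moving average (EWMA) for regions enriched in
poorly imputed markers.

It is aimed at statistical geneticists doing marker filtering before (or
forensics after) the analysis of imputed GWAS data.

## The indices

For marker *m* and individual *i* with dosage triplet
(p₀, p₁, p₂), Σ p_g = 1, define the anti-concentration

> Q_{i,m} = Σ_g p_g (1 − p_g)

(the complement of the Herfindahl–Hirschman concentration index): Q = 0
for a one-hot triplet (genotype fully determined), Q = 2/3 for the uniform
triplet (imputation failed).  With Q̄_m the mean over individuals, the
imputation accuracy measure comes in two rescalings:

> Iam_chance,m = 1 − Q̄_m / (2/3)
> Iam_HWE,m  = 1 − Q̄_m / Q_HWE(f̂_A)

where Q_HWE(f) = (−2f)(f − 1)(3f² − 3f + 2) is the anti-concentration of
the Hardy–Weinberg triplet ((1−f)², 2f(1−f), f²) and
f̂_A = Σ d_i / (2N) is the allele frequency estimated from the allele
doses d_i = p₁ + 2p₂ of the same data.  Iam_HWE = 1 means fully
individual-specific information, 0 means the dosages carry only the
population allele frequency; small negative values occur by chance.
Iam_HWE is undefined (flagged) when f̂ ∈ {0, 1}.

The heterogeneity index compares the marker's average dosage distribution
f_ad (component-wise mean of the triplets) with its average best-guess
distribution f_bg (mean of one-hot best-guess vectors, ties split
equally):

> hiQ = 1 − √(1 − Σ_g √(f_ad(g) · f_bg(g)))

i.e. one minus the Hellinger distance between the two trinomial
distributions.  hiQ = 1 when the dosages are as heterogeneous across
individuals as their best guesses; a marker whose 10 individuals all share
the triplet (0.6, 0.3, 0.1) — useless for association testing — gets
hiQ = 1 − √(1 − √0.6) ≈ 0.53.

Suggested general-use filtering thresholds are 0.5 for Iam_HWE and 0.9
for hiQ; `iamhiq thresholds` instead derives study-specific lower bounds
as the coordinate-wise extremes of a robust 1 − 10⁻⁹ bivariate-normal
coverage region fitted to the (Iam_HWE, hiQ) cloud.

## Worked example

Simulate 200 markers × 500 individuals of perfectly imputed dosages with a
planted 25-marker low-accuracy span (mixture weight λ = 0.1 toward the
truth), then run the pipeline:

```sh
iamhiq simulate --n-individuals 500 --n-markers 200 --maf 0.3 --lam 1.0 \
    --hot-region "175,25,0.1" --seed 7 --out-prefix demo
iamhiq compute  --gen demo.gen --sample demo.sample --chrom 1 --out demo.metrics.tsv
iamhiq classify --metrics demo.metrics.tsv --iam-threshold 0.5 --hiq-threshold 0.9 --out demo.class.tsv
iamhiq regions  --metrics demo.metrics.tsv --iam-threshold 0.95 --out-prefix demo
```

which prints

```
200 markers x 500 individuals -> demo.gen
200 markers -> demo.metrics.tsv
200 markers, pass proportion 0.875 (0 undefined Iam) -> demo.class.tsv
3 regions -> demo.*_regions.tsv
```

The pass proportion 0.875 is exactly 175/200: the 25 planted markers fail
the thresholds, everything else passes.  The metrics table holds one row
per marker (`iam_hwe = hiq = 1` for the perfectly imputed background):

```
snp_id  rs_id  chrom  position  maf_hat  q_bar  iam_chance  iam_hwe  hiq  n_used  flags
snp1    rs1    1      10001     0.312    0      1           1        1    500     .
snp2    rs2    1      11001     0.281    0      1           1        1    500     .
```

and the region scan recovers the planted span exactly — 25 variants from
185,001 to 209,001 bp, with its deepest stretch also called "very hot"
(EWMA below half the threshold):

```
chrom  start_bp  end_bp  name            min_smoothed  n_variants  severity
1      185001    209001  iam_hot_1       0.0811965     25          hot
1      192001    209001  iam_very_hot_2  0.0811965     18          very_hot
```

`iamhiq plot --kind manhattan` and `--kind bubble` draw the dual
Manhattan-like track (hiQ upper panel, Iam_HWE lower panel, thresholds and
region shading) and the Iam-vs-hiQ bubble plot with the robust coverage
ellipse.

The same computations are available as a library:

```python
import numpy as np, iamhiq

probs = np.tile([0.6, 0.3, 0.1], (10, 1))     # ten identical triplets
acc = iamhiq.compute_marker(probs)
print(round(acc.hiq, 2))                       # 0.53
```

## Layout

- `iamhiq.io` — GEN/SAMPLE (and optional VCF/GP) streaming readers,
  metrics-table TSV I/O
- `iamhiq.metrics` — Q, Q_HWE, Iam_chance, Iam_HWE, hiQ per marker
- `iamhiq.thresholds` — robust bivariate fit, threshold derivation, 2×2
  classification
- `iamhiq.regions` — EWMA smoothing and hot / very-hot region calling
- `iamhiq.simulate` — seeded synthetic dosage generator
- `iamhiq.cli`, `iamhiq.plots` — command-line front end and figures

See `docs/methods.md` for model details, defaults and limitations.
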