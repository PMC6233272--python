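# Methods

## Working scale and the DEG criterion

All inference happens on `x = log2(RPKM + 1)`; abundance thresholds are
applied on the RPKM scale, with `2**x − 1` (clamped at 0) as the inverse
map. For a two-group comparison the pipeline is:

1. **Expressed filter** — keep genes with arithmetic mean RPKM ≥ 5 in
   *both* groups. All thresholds are inclusive (`≥`), so a gene at exactly
   5.000 passes. The filter is idempotent and monotone in the threshold.
2. **Test** — pooled-variance two-sample t test on the log scale
   (identical to a one-way linear-model F test with two levels). No
   Welch correction and no small-sample moderation: this is deliberately a
   plain linear model. Degenerate genes with zero residual variance get
   p = 1 when group means agree and p = 0 (flagged as degenerate) when
   they do not.
3. **BH adjustment** — Benjamini–Hochberg step-up over the expressed
   (tested) genes only; untested genes carry no p-value, so adjusting over
   a larger universe would be meaningless. Implementation is
   statsmodels' `fdr_bh`; the test suite checks it against a literal
   step-up enumeration on every vector up to length 20.
4. **Joint flag** — `is_deg = expressed ∧ |Δ| ≥ 5 RPKM ∧ q ≤ 0.05`.
   The Δ threshold is evaluated on group means of the matrix being
   analyzed (adjusted-scale means when the input is an adjusted matrix).

Signed fold changes use the magnitude-≥ 1 convention
(`m₁/m₂` if `m₁ ≥ m₂`, else `−m₂/m₁`), so values in (−1, 1) never occur
and antisymmetry `fc(a,b) = −fc(b,a)` holds for `a ≠ b`.

## Covariate model and "adjusted expression"

Per gene, ordinary least squares with disease status (reference NF),
a male indicator and cohort-mean-centered age:

```
x = β0 + β_DCM·I(DCM) + β_ICM·I(ICM) + β_sex·I(male) + β_age·(age − āge) + ε
```

Fits are vectorized across genes through the shared normal equations;
per-coefficient two-sided p-values use the t distribution on the common
residual df. The design matrix is checked for full rank and the
offending columns are named when it is not.

*Adjusted expression* subtracts `β̂_age·(age − āge)` and
`β̂_sex·(I(male) − mean male fraction)` from each gene. Because both
removed regressors are mean-centered, every gene's grand mean is
preserved — which keeps the RPKM-difference threshold meaningful on the
adjusted scale — and disease contrasts of a refit on adjusted data are
unchanged to numerical precision (both properties are asserted in tests).
Disease effects are never removed.

Post-adjustment DEG p-values come from re-running the two-group pipeline
on the adjusted matrix, so the adjusted and unadjusted branches are
structurally identical; the full model's disease contrast is available
from `fit_gene_models` as a diagnostic. This residualize-then-test
design has a known cost: the per-gene estimation error of `β̂_sex`/`β̂_age`
multiplied by the between-group covariate gap survives as a small,
gene-fixed shift. With the default synthetic conditions it leaves ~1–3%
of pure-confounder genes significant after adjustment — the price of
keeping the two branches identical rather than using the joint model's
contrast.

The single-covariate clinical scan (`single_covariate_scan`) restricts to
disease samples and fits `{age, sex, covariate}` per gene *without* a
disease term; a covariate that is constant in the disease subset is
rejected (it would be collinear with the intercept, and a
disease-correlated covariate in a model that also had a disease term
would be near-collinear too). Consequently a covariate strongly
correlated with etiology proxies the disease contrast — the scan reports
association, not causation.

## Label-permutation null

For one comparison, the pooled samples are relabeled uniformly at random
into groups of the original sizes and the *entire* DEG criterion
(expressed filter included) is re-run; default 1000 replicates, with a
reduced 200-replicate mode used by the acceptance script and test suite.
Replicates are drawn independently (a split can repeat; collisions are
negligible at these pool sizes) and the observed labeling is not
excluded. Inference is a one-sample t test of the null counts against
the observed count, `t = (M − observed)/(SD/√n)`, two-sided with `n − 1`
df and the sample SD; p-values below 2.2e-16 are reported as
`"< 2.2e-16"`. The empirical rank of the observed count is reported as a
diagnostic only. For log-scale plotting, 0.1 is added to each count so
zero-count replicates are displayable.

## Clustering and signature classification

Samples are compared by Spearman rank correlation (average ranks on
ties) over a gene set and clustered agglomeratively with average linkage
(UPGMA) on `1 − ρ`; merge heights match a brute-force pairwise-average
oracle on small instances to 1e-12. PCA is an SVD of the per-gene
mean-centered submatrix with component signs fixed by making the first
gene's loading nonnegative.

Classification of an external cohort: collapse probes to genes keeping
the probe with maximal mean expression (standard practice for microarray
signatures); extract the DCM-specific ∪ ICM-specific genes (an error with
a mapping report fires if under 20% are present); cluster; cut the tree
at k = number of phenotypes present; assign each cluster its majority
phenotype (ties toward the larger phenotype, then lexicographic). A
sample is *correctly segregated* iff its cluster's phenotype matches its
label. This counting rule is this package's own formalization — published
segregation counts of this kind rarely state one — and `k` is exposed
for alternative cuts. Because every step downstream of the Spearman
matrix depends only on within-sample ranks, classification is invariant
to strictly monotone per-sample transforms, and the microarray platform
distortion in the generator is verified not to change cluster
assignments.

## Synthetic cohorts

The generator renders `x = b_g + δ_{g,phen} + s_g·I(male) + a_g·z(age) + ε`,
`ε ~ N(0, σ)`, back-transformed to RPKM. Defaults (the study
conditions of the whole test battery):

| parameter | default | meaning |
|---|---|---|
| cohort sizes | 37 / 13 / 14 | DCM / ICM / NF samples |
| `n_genes` | 5000 | 4300 null, 300 HF-shared (150 up / 150 down), 100 DCM-specific, 200 ICM-specific, 50 sex-linked, 50 age-linked |
| `effect_size_log2` | 1.0 | disease shift; with the ~10 RPKM baseline it gives Δ ≈ 11 RPKM (2^(log2 11 + 1) − 1 = 21 vs 10) |
| `sex_effect_log2`, `age_effect_log2` | 2.0, 1.0 | confounder shifts (per male / per SD of age) |
| `noise_sd_log2` | 0.25 | residual sd on the log scale |
| `baseline_log2_mean/sd` | log2(11), 0.4 | log-normal baseline across genes |
| demographics | DCM 81% male, ages 36–62; ICM 77%, 52–60; NF 36%, 30–50 | realized exactly (rounded counts, quantile-grid ages, shuffled) |

Design choices worth knowing:

- Gene classes are apportioned by largest-remainder rounding and then
  seeded-shuffled, so class counts are exact.
- Down-shifted classes (and age-linked genes, whose youngest cohort sits
  ~1 SD below the age mean) have their baseline raised by one effect
  unit so both group means stay in the expressed regime; planted RPKM
  differences are therefore symmetric between up- and down-regulated
  genes.
- Demographics are phenotype-confounded on purpose (disease cohorts
  older and more male than NF) and realized deterministically, so
  sex-/age-linked genes are reliably called as DEGs on raw data (~70% of
  gene × vs-NF-comparison pairs) and drop to ~1–3% after adjustment.
  The NF composition was chosen once to land in that regime and is not a
  per-experiment tuning knob.
- `z(age)` is standardized to mean 0, sd 1 within the simulation, so the
  OLS age coefficient times the cohort age SD equals the planted
  per-SD effect exactly in the noiseless limit.
- External datasets draw fresh samples from the same gene-level truth;
  microarray mode applies a strictly monotone per-sample transform
  (`scale·x^γ`, γ ∈ [0.8, 1.3]) and expands a configurable fraction of
  genes into two probes with log-normal probe affinities.
- Binary clinical fields are Bernoulli per phenotype at configurable
  rates (defaults follow the DCM/ICM clinical-characteristics table:
  statins 27%/92%, CAD 11%/100%, diabetes 16%/62%, hyperlipidemia
  22%/69%; NF donors have no records and default to 0).

What the generator does *not* emulate: the baseline spread (sd 0.4 in
log2) is far narrower than a real transcriptome's, chosen so the
expressed filter retains ≥ 95% of genes and planted effects are cleanly
in-regime; there is no gene–gene correlation structure, no
sequencing-depth or gene-length modeling, no batch effects, and noise is
homoskedastic on the log scale. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model, not
performance on real tissue data, where expressed-gene fractions and
power are substantially lower.

## Cohort statistics

Binary characteristics are compared by exact (not asymptotic) Fisher
tests on the 2×2 table; ordinal/continuous ones by a two-sided
Mann-Whitney U — exact when the combined sample is ≤ 20 and tie-free,
otherwise the normal approximation with tie and continuity correction.
Missing values are dropped per characteristic and counted.

## Numerical conventions and degenerate inputs

- Zero-residual genes: coefficients snapped to 0 when below rounding
  noise, residual variance set to exactly 0, p = 1 (null coefficient) or
  0 (nonzero).
- BH is monotone and tie-preserving; q ≥ p always.
- Spearman on a constant sample vector is undefined → error naming the
  sample. UPGMA ties follow scipy's deterministic nearest-neighbor-chain
  order for a fixed sample ordering.
- One-sample t with SD = 0: p = 1 if the observed count equals the null
  mean, else p = 0.
- Mitochondrial filtering recognizes the chromosome aliases MT, chrM
  and M.

## Problem sizes

The test suite and acceptance script run the full 5000-gene, 64-sample
default cohort end-to-end, 200-replicate permutation nulls (the
full-fidelity 1000-replicate mode is the library default), and
replication cohorts of 13/13/10 samples. Brute-force oracles run at
small n by construction (BH ≤ 20 p-values, UPGMA ≤ 6 samples, Fisher
enumeration at cohort-scale tables, exhaustive Mann-Whitney on 3+3).

## Known limitations

- Residualize-then-test leaves a small confounder false-positive rate
  (see above); the joint-model contrast is exposed but not the default.
- The HF-shared set is an empirical intersection: rare false
  intersections can carry discordant directions, so empirical
  concordance can dip just below 1.0 even though every truly shared gene
  is concordant.
- The RPKM-difference criterion is baseline-dependent: a 5-RPKM
  difference is a large effect at 10 RPKM and a small one at 200 RPKM,
  so false positives concentrate among high-abundance genes.
- No count-level models (negative binomial), shrinkage, mixed models or
  hidden-confounder estimation; the scope is the plain linear-model
  pipeline plus its validation devices.
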