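# Methods notes

This note records the models behind `famine_metabosig`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Exposure classification

Exposure is defined from the mother's last menstrual period (LMP) and
the interval during which central rations fell below 900 kcal/day
(1944-11-26 to 1945-05-15). Each of the five gestational windows has a
fixed LMP date range; a 10-week window counts as exposed only when it
is entirely contained in the restriction interval, which the date
ranges encode. Conventions:

- All LMP ranges are **inclusive on both endpoints**. "Between X and
  Y" admits either reading; the inclusive one is conservative and
  every boundary date is unit-tested.
- The peri-conception range (1945-02-04..1945-05-12) overlaps the
  weeks-1–10 range for LMPs up to 1945-03-04; the classifier returns
  both windows and leaves the resolution to the caller. Whether a
  participant whose only window is peri-conception counts as "any
  gestational exposure" is genuinely ambiguous; the default counts
  them (any non-empty window set), and
  `any_gestational_exposure(..., include_periconception=False)` gives
  the stricter rule.
- `weeks_exposed` is the floor of overlap days / 7: partial weeks do
  not count, and the value is bounded by ⌊170/7⌋ = 24.
- Dates are parsed strictly as ISO-8601.

## Biomarker preprocessing

Order is fixed and enforced by a state flag on the matrix
(`raw` → `log_scaled`):

1. below-LOD cells → observed (non-flagged) minimum of that biomarker;
2. +1 to every value of any biomarker column containing an exact zero;
3. natural log, then z-scoring with the **sample** SD (n−1) — the
   default of mainstream statistical environments; effect sizes
   downstream are therefore "SD units of the analyzed sample";
4. exclusions: non-fasted samples first, then PCA outliers, then
   re-standardization so the mean-0/SD-1 invariant holds for the
   analysis sample.

The outlier rule had to be made concrete (the source analysis names
PCA but no criterion): a sample is excluded when its standardized score
on PC1 or PC2 exceeds 5 SD in absolute value, configurable via
`outlier_sd`. Whether standardization originally preceded or followed
the exclusion is unknown; this package standardizes first and
re-standardizes after, which keeps the PCA well-defined.

Missing covariates are handled complete-case per regression, with
counts retained in the fit output.

## MWAS model

Per biomarker: Gaussian identity-link GEE of the standardized log
concentration on the exposure indicator plus age, sex, and
cholesterol-lowering medication, clustered on sibship with an
**exchangeable** working correlation and robust sandwich standard
errors, two-sided Wald p-values. With sibships of size ≤ 2 every
symmetric working structure coincides with exchangeable, so nothing
hinges on the choice; it is still explicit and configurable. The
statsmodels GEE implementation is used; tests validate it against an
independently coded Liang–Zeger IRLS oracle (agreement to 10⁻⁶ on a
6-row fixture) and against robust OLS in the singleton-cluster limit
(10⁻⁸).

A perfect fit (zero residuals) makes the moment estimators degenerate;
`fit_gee` returns the least-squares solution with zero SEs in that
case rather than NaNs.

Multiple testing: the effective number of tests is the smallest k such
that the top-k principal components of the standardized matrix explain
at least 95% of variance; the per-test threshold is alpha/k. The
sensitivity suite re-fits the main model with BMI, waist, type-2
diabetes, or the biomarker's polygenic score added; runs sex-stratified
models plus a pooled model with a sex×exposure product term (the
phrase "interaction term for sex and metabolic marker" is read as
standard effect modification, sex×exposure); and replaces the single
exposure indicator with the five window indicators. Participants
exposed in two adjacent windows carry two active indicators, so window
coefficients are partial effects, not five separate subgroup means.

Descriptive tables use pooled-variance t-tests (Welch optional) for
continuous fields and chi-square **without** continuity correction for
categorical fields — the uncorrected test reproduces the printed
reference p-values from the printed 2×2 counts, the corrected one does
not.

## Signature comparison

Signatures are vectors of per-biomarker effect sizes; panels are
harmonized by case-folded, punctuation-collapsed names with an
optional synonym map. Atlas filters are applied as a conjunction:
case count ≥ 1000 (inclusive) and minimum biomarker p < 5×10⁻⁴
(strict), as stated. Pearson r is tested with the t transform on n−2
degrees of freedom, treating biomarkers as independent observations —
a known simplification, since biomarkers are correlated; p-values
should be read as descriptive orderings rather than calibrated
frequencies. Attenuation is defined on |r|
(100·(|r_adj|−|r_main|)/|r_main|), because several diseases correlate
negatively and "strength" is the quantity being attenuated; diseases
with |r_main| < 10⁻⁶ are excluded with a log entry. Heatmap ordering
uses complete-linkage hierarchical clustering on Euclidean distances
of the per-disease effect profiles of nominally famine-associated
biomarkers (p < 0.05).

## Synthetic-data generator

The generator's defaults are the stated study conditions: 480 exposed
and 464 controls, a 168-biomarker panel, exposure effects of
0.28 / 0.21 / 0.23 / 0.18 SD on the tyrosine / leucine / glucose /
isoleucine analogs (plus 0.12 on the phenylalanine and valine analogs,
which the study reports as nominal), within-sibship ICC 0.3, polygenic
scores explaining ~3% of target-biomarker variance, and a panel whose
top 14 principal components explain 95% of variance.

**Covariance calibration.** The panel covariance is 14
compound-symmetric blocks of 12 biomarkers with within-block
correlation 0.97 (between-block 0), plus a rank-one BMI axis with
loadings of SD 0.1. The block eigenvalues are 1+11ρ (one per block)
and 1−ρ; at ρ = 0.97 the population cumulative variance is ≈ 0.90 at
13 components and ≈ 0.96 at 14, so the 95% threshold lands on k = 14
with margin on both sides of the sampling noise at n = 944. The block
parameters are calibration targets, not estimates of any real
correlation structure; only the PC-count summary is matched.

**Effect semantics.** `true_effects` are *total* exposure effects in
SD units of the standardized log biomarker — the scale on which the
MWAS reports. Because standardization divides by the full-sample SD
(which includes the between-group shift), the raw-scale shift is
pre-compensated as δ_raw = δ/√(1 − δ²p(1−p)) with p the exposed
fraction, so an unbiased estimator recovers the configured value in
expectation. Parameter-recovery checks therefore test the estimator,
not generator bookkeeping.

**BMI as a shared axis.** Standardized BMI is β_E·exposed + z with
β_E = 0.27 (the reference BMI difference of ≈1.2 kg/m² over a pooled
SD of ≈4.5) and z standard normal. Biomarker b loads on z with a
background axis loading w_b ~ N(0, 0.1²) and, when a fraction m of its
exposure effect is mediated, an additional m·δ_raw/β_E on BMI itself;
the direct exposure path carries (1−m)·δ_raw, so the total is δ_raw
regardless of m and a null truth map yields exactly null exposure
effects (family-wise soundness). Residual scale is √(1−a²) for total
loading a, keeping unit conditional variance. This caps feasible
mediation: m·δ ≤ β_E·a_max, so the default is m = 0.3 (BMI→biomarker
loadings ≈ 0.3 SD/SD, in line with observed BMI–metabolite
associations); m = 0.7 or 1.0 remain usable for smaller effects and
are exercised in tests. BMI adjustment of the MWAS then recovers
(1−m)·δ_raw − β_E·w_b, which is what drives signature-level
attenuation.

**Sibship structure.** A configurable fraction of controls (default
0.5 — the real mix of time controls and sibling controls is not
printed) are same-sex siblings of exposed participants; the sibship
random effect carries the same block covariance as the individual
residual, scaled by √ICC, so the total covariance is unchanged while
each biomarker's within-sibship correlation equals the configured ICC.

**Concentrations and censoring.** Values are exp(μ_b + τ_b·y) with
per-biomarker log-means U(ln 0.05, ln 3) and log-SDs U(0.2, 0.8), so
the log step is exercised and positivity is guaranteed. Below-LOD
flags are confined to 10 low-abundance "trace" biomarkers (2% lowest
values each): in serum NMR, amino acids and glucose are never below
detection, so the named analogs stay clean. Two further trace
biomarkers have their lowest quantile set to exact zeros to exercise
the +1 shift. Planted PCA outliers are a panel-wide +10 SD shift (a
sample-level artifact such as dilution); a shift confined to one
covariance block would spread across the 14-fold-degenerate top
eigenspace (~2.7 SD per component) and be undetectable on PC1/PC2,
which was verified empirically before choosing the global form.

**Atlas.** Disease signatures are τ_d·(L_d·g + √(1−L_d²)·ε) with g
the standardized shared axis (the expected famine signature), loadings
L_d uniform on [0.3, 0.9] (10% sign-flipped), and per-disease scales
τ_d — Pearson correlation is invariant to that scale, mirroring the
comparison of hazard-type against linear effects. P-values come from
se = τ·10/√cases; ~8% of diseases are pure estimation noise (they pass
the case filter but almost never the p filter) and ~10% have 100–999
cases, so both sides of both atlas filters occur. Case counts and
disease mix are desk-scale stand-ins (190 diseases rather than 674).

**What a green test does not establish.** The generator draws
Gaussian log-concentrations with an idealized block covariance; it has
no skewness beyond log-normality, no batch effects, no missingness
other than LOD flags, no LD or genotype structure behind the polygenic
scores (phenotypic stand-ins), and the atlas is not a re-estimated
biobank. Green tests establish that the *pipeline machinery* —
classification, preprocessing order, clustered estimation, multiple
testing, signature algebra — behaves correctly under the stated
statistical structure, not that real-data effect sizes would be
reproduced.

**Determinism.** One RNG stream per component (cohort, biomarkers,
atlas, polygenic scores) is spawned from the master seed, so enlarging
the atlas cannot perturb the cohort draw; a fixed `SimConfig` plus
seed reproduces the study byte-identically.

## Numerical conventions and degenerate inputs

- Sample SD (n−1) everywhere a scale is estimated.
- Constant biomarker columns, all-below-LOD columns, rank-deficient
  designs, constant outcomes, empty harmonizations (<3 shared names),
  and zero-variance signatures raise with the offending name in the
  message rather than propagating NaNs.
- PCA uses SVD of the centered matrix (scores) or the eigendecomposition
  of the correlation matrix (variance shares); eigenvalues are clipped
  at zero before cumulating.
- 95% CIs use the normal quantile 1.95996…, consistent with Wald
  inference from the sandwich variance.

## Known limitations

- The interaction and timing sensitivity models follow one concrete
  reading of ambiguous prose (see above); both are flagged rather than
  silently assumed certain.
- Correlation p-values across biomarkers ignore inter-biomarker
  correlation (shared with the source analysis).
- The desk-scale atlas and cohort sizes make the end-to-end
  disease-correlation magnitudes smaller than biobank-scale analyses
  would give; only their structure (sign split, attenuation direction,
  family-wise error control) is asserted.
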