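# Methods

This note documents the statistical model behind `mrpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical corner cases.

## Two-sample summary-data MR model

Instruments are variants j = 1…J with exposure associations γ̂ⱼ ~
N(γⱼ, σ²_γⱼ) from one GWAS and outcome associations Γ̂ⱼ ~ N(Γⱼ, σ²_Γⱼ) from
an independent GWAS (strict two-sample setting: no sample overlap, so the
two errors are independent). Under the instrumental-variable assumptions
Γⱼ = β·γⱼ; horizontal pleiotropy adds a direct effect αⱼ, giving
Γⱼ = β·γⱼ + αⱼ. Binary traits are handled on the log-odds scale throughout
and exponentiated only for reporting, so "OR per 1-log-odds of exposure"
means exp(β̂).

### Estimators

**Wald ratio.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ. Delta-method SE, three expansions:
`first_simple` σ_Γⱼ/|γ̂ⱼ|; `first_full` (reporting default)
√(σ²_Γⱼ/γ̂ⱼ² + Γ̂ⱼ²σ²_γⱼ/γ̂ⱼ⁴); `second` adds σ²_Γⱼσ²_γⱼ/γ̂ⱼ⁴. Pooling uses
`first_simple` weights so that IVW is algebraically identical to the
weighted through-origin regression of Γ̂ on γ̂ with weights 1/σ²_Γⱼ — the
identity the test suite checks to machine precision.

**IVW.** Point estimate Σwβ̂/Σw. Fixed SE 1/√Σw. Default "random-effects"
flavour is multiplicative overdispersion floored at 1 (SE × max(1,
√(Q/(J−1)))), matching the convention of the standard MR software stacks;
additive DerSimonian–Laird is available (`re_model="additive_dl"`). The
floor means the random-effects p-value can never undercut the fixed one.
CIs and p-values use the normal approximation. A single instrument
degrades to its Wald ratio.

**Cochran's Q.** Q = Σwⱼ(β̂ⱼ − β̂_IVW,fixed)² referred to χ²(J−1); the
omnibus heterogeneity/pleiotropy screen.

**Weighted median.** Ratios ordered; normalized cumulative weights taken
at interval midpoints (cwⱼ = Σ_{k≤j}w_k − wⱼ/2, normalized); the estimate
is the linear interpolation of the ratios at cw = 0.5. Consistent while
valid instruments hold >50% of weight. SE from a seeded parametric
bootstrap (γ̂, Γ̂ resampled from their sampling distributions; default
1,000 draws).

**MR-Egger.** WLS of Γ̂ on γ̂ *with* intercept, weights 1/σ²_Γⱼ, after
orienting all instruments exposure-increasing (the fit is not invariant to
per-variant sign flips; orientation is the standard convention).
Coefficient SEs use multiplicative dispersion floored at 1, built from the
residual-free normalized covariance so an exactly-fitting configuration
(zero residual dispersion) stays well defined; t(J−2) reference
distributions. The intercept estimates the mean pleiotropic effect μ_α;
its slope is consistent for β under InSIDE (instrument strength
independent of direct effects).

**PRESSO-style outlier test.** Observed weighted residual sum of squares
RSS = Σⱼ wⱼ(Γ̂ⱼ − γ̂ⱼ·β̂₋ⱼ)² with β̂₋ⱼ the leave-one-out IVW slope and wⱼ =
1/σ²_Γⱼ. The null distribution comes from parametric simulation: γ* ~
N(γ̂, σ_γ), Γ* ~ N(γ̂·β̂₋ⱼ, σ_Γ), RSS recomputed per replicate (default
1,000; seed mandatory in pipeline runs). Monte-Carlo p-values carry +1/+1
continuity, so they are never 0 and have resolution 1/(n_sim+1). Per-variant
outlier calls compare each variant's observed squared residual to its own
simulated distribution, Bonferroni-adjusted, flagged at α = 0.05.

One refinement over the plain leave-one-out construction: for the
*per-variant* test (not the global RSS), residuals are taken around a
"peeled" leave-one-out slope that also excludes the single most-outlying
variant of the full sample, identically in observed and simulated data. A
gross outlier otherwise contaminates every clean variant's leave-one-out
slope and systematically inflates false outlier calls (masking in
reverse); peeling removes that shift while leaving clean-data
family-wise error at the nominal 5%. Note the resolution constraint:
with J instruments, no Bonferroni-adjusted Monte-Carlo p can fall below
J/(n_sim+1), so detecting outliers at α = 0.05 requires n_sim ≳ 20·J.

The corrected estimate is IVW on the unflagged variants (reported only
when outliers exist); the distortion test compares the full-vs-corrected
shift against shifts obtained by removing equally many randomly chosen
variants from each simulated dataset (two-sided, with continuity).

**Multivariable IVW.** WLS of Γ̂ on the J×K matrix of exposure effects,
no intercept, weights 1/σ²_Γⱼ, multiplicative dispersion floored at 1,
t(J−K) inference. Cluster exposures are built as (cluster weight) ×
(variant effect), zero where a variant does not load; an adjustment trait
(e.g. the variants' effects on glycated hemoglobin) is appended as one
more exposure column — the alternative operationalization (subtracting
its effect from the outcome) is not implemented. Rank deficiency is
reported with the names of collinear exposure columns.

## Harmonization

Variants are matched by `variant_id`. For each shared variant the outcome
alleles are matched to the exposure's literally, then after strand
complementation; a label swap negates the outcome beta and complements its
frequency. Palindromic variants (A/T, C/G), where strand cannot be
resolved from letters, follow a policy:

- `infer_by_frequency` (default): after literal alignment the variant is
  kept only if both effect-allele frequencies are on the same side of 0.5
  and both minor-allele frequencies are below 0.42; otherwise dropped. The
  opposite-side case is dropped rather than sign-flipped — conservative,
  since a frequency disagreement may reflect population difference rather
  than strand. Missing frequency also drops the variant (with a warning).
- `drop_all` / `keep_as_is` for stricter or trusting pipelines.

The 0.42 threshold and the policy itself follow common two-sample MR
practice; the underlying study design this package reproduces does not
state its palindrome handling, so it is configurable. Every shared variant
receives exactly one action (`direct`, `flipped`, `frequency_inferred`,
`dropped_palindromic`, `dropped_mismatch`); dropped variants stay in the
harmonized table for auditing and are excluded from estimation by
`kept()`. Proxy lookup for missing variants and genome-build liftover are
out of scope.

## Instrument selection

Greedy p-ordered clumping (the PLINK convention): repeatedly retain the
most significant remaining variant, discard same-chromosome variants
within ±window whose r² with it exceeds the cutoff. Ties broken
deterministically by (p, chrom, pos, variant_id), making the output
permutation-invariant. Defaults p ≤ 5×10⁻⁸, r² < 0.01, window 10,000 kb
(±10 Mb); the bidirectional reverse direction relaxes to p < 10⁻⁶ because
outcome GWAS rarely offer many genome-wide hits. LD is consumed as a
sparse pair table (absent pair ⇒ r² = 0); computing LD from genotype
panels is out of scope.

Variance explained: continuous traits default to the summary-statistic
form z²/(z²+n−2) with z = β̂/SE (the squared sample correlation implied by
the Wald test); 2·f(1−f)β² is available for standardized effects. Binary
traits use a liability-threshold construction: solve genotype penetrances
consistent with a multiplicative per-allele odds ratio and the disease
prevalence (8.5% default, a global type-2-diabetes figure) under
Hardy–Weinberg, map each genotype's penetrance to a mean liability via the
inverse normal, and report the variance of the genotype means on the
unit-variance liability scale. The multiplicative-odds assumption is
stated explicitly because published descriptions often leave it implicit.

## Pipeline conventions

- FDR family: the primary-method (IVW) p-values of the primary analysis
  variant across the grid — one family per `run_grid` call, the analogue
  of one reported figure/table. Benjamini–Hochberg step-up q-values
  (via statsmodels) with q < 0.05 declared significant; raw p < 0.05 with
  q ≥ 0.05 is tiered "nominal".
- Annotation-based exclusions (e.g. variants associated with
  erythrocyte-related traits at p < 0.001, which could move glycated
  hemoglobin without hyperglycemia) run as additional analysis variants of
  the same grid; exclusion uses strict inequality at the cutoff.
- Every dropped variant — clumping, harmonization, annotation exclusion —
  is appended to an audit log with a reason.
- All randomness (median bootstrap, PRESSO simulations) derives from the
  single config seed through per-cell CRC-keyed substreams, so reruns are
  byte-identical; cell failures (too few instruments, no overlap) are
  recorded per cell and never abort the grid.

## Synthetic data: what it emulates, what it does not

The generator simulates summary statistics directly (never genotypes):
eaf ~ U(bounds); γⱼ ~ N(0, τ), optionally floored at a minimum magnitude
`min_abs_gamma` to emulate that published instrument lists contain only
detected, genome-wide-significant hits (a detection-truncated effect-size
distribution); SEs follow the textbook GWAS scaling 1/√(2f(1−f)n);
observed effects are drawn around truth with independent exposure/outcome
noise. Pleiotropy regimes: none, balanced (mean-0), directional (mean
μ_α, InSIDE holding), InSIDE-violating (α correlated with |γ|), and
sparse outliers (offset in units of the variant's outcome SE). Directional
parameters are defined relative to each variant's exposure-increasing
allele, so estimators that orient instruments see the intended direction
regardless of allele labelling. Allele pairs include a configurable
palindromic fraction; `scramble_alleles` produces label-swapped and
strand-flipped re-encodings for harmonization round-trips.

Not emulated: individual-level liability-scale case/control sampling
(binary outcomes are generated directly on the log-odds scale), sample
overlap between the two GWAS, population stratification, relatedness, and
winner's-curse inflation of γ̂ (effects are truncated, not biased). Passing
tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to those additional features of
real consortium data.

The study-shaped fixture mirrors a diabetes→stroke study design: a binary
exposure with exactly 289 instruments at a case/control effective sample
size of ~272,000, a continuous exposure with 333 instruments at n ≈
422,000, and three case/control outcomes at effective sizes implied by
~60,000/6,700/11,700 cases against ~454,000 controls, with generative
odds ratios 1.11/1.22/1.18 (binary exposure) and 1.36/2.06/1.85
(continuous exposure). Effect floors are set ~11 noise-SDs above zero so
the instrument counts are exact by construction for any seed.

## Problem sizes for validation

Monte-Carlo checks use sizes chosen to make the targeted property visible
above simulation noise while staying desk-scale: null calibration with
10,000 replicates at J = 10; CI coverage with 1,000 replicates at J = 30;
per-regime recovery with 500 replicates at J = 100 with strong instruments
(τ = 0.1, floor 0.05, n = 2×10⁶) — the "large-J, large-n" regime in which
the weighted median's 10%-bias guarantee under ≤49% contamination is an
asymptotic statement; planted-outlier detection with 200 replicates at
J = 20 and n_sim = 1,000 (see the resolution constraint above).

## Known limitations

- No Steiger filtering, mode-based estimators, MR-RAPS or contamination
  mixtures; no conditional F-statistics for multivariable instrument
  strength.
- The PRESSO-style test makes no claim of numerical identity with any
  published implementation; it is validated by calibration and
  planted-truth properties.
- First-order IVW weights only (no second-order weighting option).
- The liability calculation assumes Hardy–Weinberg and multiplicative
  allelic odds; penetrance solutions outside (0,1) raise a numerical
  error rather than being clipped.
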