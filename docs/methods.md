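# Methods

This note documents the statistical models implemented in `mrmediate`, the
assumptions they rest on, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Two-sample MR model

All estimators work on summary statistics from two non-overlapping GWAS: a
SNP–exposure effect γ̂ⱼ with SE σ_γⱼ and a SNP–outcome effect Γ̂ⱼ with SE
σ_Γⱼ, aligned to the exposure's effect allele. The instrumental-variable
assumptions are the usual three: relevance (association with the exposure),
exclusion restriction (no effect on the outcome except through the
exposure) and exchangeability (no confounding of the variant–outcome
relationship). Binary-trait effects are held on the natural-log-odds scale
throughout; odds ratios are derived views. Positions are 1-based and only
ever used for clumping windows.

### Harmonization

Exposure and outcome records are intersected on variant id and aligned to
the exposure's effect allele: same-allele pairs pass through, swapped-allele
pairs have the outcome beta negated and eaf complemented. Palindromic pairs
(A/T, C/G) are strand-ambiguous; they are kept only when both effect-allele
frequencies are informative — outside [0.5 − w, 0.5 + w], default w = 0.08 —
and the frequency-implied orientation agrees with the allele-implied one.
Disagreement, a frequency in the window, or a missing frequency drops the
pair (`palindromic_ambiguous`); a wrong silent flip would negate a true
effect, so drop-when-ambiguous is the safe default. Kept rows plus dropped
rows always partition the intersection, and harmonization is involutive:
re-coding the outcome file's alleles yields identical output.

### Instrument selection

- p-value screen: default 1 × 10⁻⁵, the conventional threshold for
  underpowered exposures such as microbial taxa (genome-wide 5 × 10⁻⁸
  typically leaves too few instruments).
- LD clumping: greedy, best-p-first (ties broken lexicographically by
  variant id for determinism), removing variants within 10,000 kb with
  r² > 0.001 against the index — the standard stringent setting for MR.
  The r² matrix is user-supplied; absent pairs count as independent. No
  remote LD panel is consulted; proxies may be supplied as an explicit
  missing-id → proxy-id table.
- Instrument strength: per-SNP variance explained R²ⱼ, either
  2β²·eaf(1−eaf) (standardized trait; requires eaf) or t²/(t² + n − 2)
  (always available; the default, and the fallback when eaf is missing).
  Per-SNP F = R²ⱼ(N−2)/(1−R²ⱼ); SNPs with F < 10 are excluded. The overall
  F uses the summed R² with K the retained count and
  F = R²(N−K−1)/[(1−R²)K].
- Steiger filtering retains rows with R²_exposure > R²_outcome (strict).
  The reported z uses Fisher-transformed |r| values divided by
  √(2/(n_h − 3)) with n_h the harmonic mean of the two sample sizes — a
  normal approximation adequate for filtering, not a substitute for the
  exact dependent-correlation test.

### Estimators

Defaults: IVW with multiplicative random effects (the common default in
two-sample MR software; the fixed-effect flavor is available and is the one
with exactly nominal test size — see Calibration). Egger regression orients
rows to γ̂ ≥ 0 first, inflates the residual variance to at least 1
(multiplicative model) and uses t-distribution p-values with J − 2 degrees
of freedom; all other estimators use normal p-values. The weighted median
interpolates the weighted empirical quantile function at 0.5 and takes its
SE from a parametric bootstrap (default 1,000 resamples, seed recorded in
the result). The profile-score estimator is the simple variant without an
overdispersion parameter — a deliberate simplification; it optimizes over
β ∈ [−10, 10] (Brent, tolerance 1e-10) and errors out rather than returning
a boundary solution, with the SE from a central-difference observed
information (step 1e-4·max(1, |β̂|)).

Power uses the non-centrality approximation for a binary outcome:
NCP = n·R²_xz·β²·v(1−v) with v the case fraction;
power = Φ(−z_{1−α/2} + √NCP) + Φ(−z_{1−α/2} − √NCP).

### Sensitivity battery

Cochran's Q at a given β over Wald ratios with inverse-variance weights
(χ²_{J−1} upper tail); Q is minimized at the fixed-effect IVW estimate.
Leave-one-out re-runs IVW J times and flags sign changes and significance
crossings. The residual-sum outlier test follows the published algorithm's
structure: leave-one-out IVW expected values, observed weighted RSS, and a
simulated null (Γ*ⱼ ~ N(β̂₋ⱼγ̂ⱼ, σ_Γⱼ), default 1,000 draws) with add-one
Monte-Carlo p-values so no p is exactly zero; per-SNP outlier p-values are
Bonferroni-adjusted across the J instruments. The distortion test here
compares the raw-minus-corrected IVW change against the distribution of
changes from removing equally many randomly chosen non-outlier SNPs — a
simple permutation-style variant chosen because the reference procedure's
bootstrap is not fully specified by its citation.

## Two-step mediation

Indirect effect b₁·b₂ (product method) with first-order delta SE
√(b₂²σ₁² + b₁²σ₂²), valid under independence of the two estimates
(non-overlapping samples) and small relative SEs. Direct effect
= total − indirect, so additivity is exact by construction. Proportion
mediated = indirect/total. Two interval variants:

- `delta_indirect_over_fixed_total` (default): (indirect ± 1.96·SE)/total,
  treating the total as fixed. Simple and what the ratio-of-log-OR
  worked examples imply.
- `delta_full_ratio`: additionally propagates the total effect's variance
  through the ratio (var ≈ σ_ind²/c² + ind²σ_c²/c⁴).

The exact interval construction used for the published proportion CIs is
not recoverable from printed ORs alone; both variants are provided and the
default is declared, not inferred. Proportions outside [0, 1] are reported
as-is with a warning — negative proportions legitimately arise when the
indirect and total effects disagree in sign, which the
`consistent_direction` flag surfaces. Step 2 instruments the mediator from
its own GWAS (univariable two-step MR); multivariable adjustment of the
step-2 estimate is out of scope.

## Synthetic-data generator

The generator emulates the statistical structure of the motivating setting:
an exposure GWAS of ~7,700 samples (a gut-microbiome cohort scale), a
mediator GWAS of ~8,300 (a blood-metabolite cohort scale), and a binary
outcome GWAS whose default n = 14,500 is the *effective* sample size
4/(1/cases + 1/controls) of a ~3,600-case / ~441,000-control study.
Summary statistics are drawn directly at the summary level:
β̂ = β_true + N(0, SE²) with SE = 1/√(2n·maf(1−maf)), the large-sample SE
for a standardized trait (and the logistic-asymptotics analogue on the
log-odds scale for the binary outcome). The three studies get independent
noise — the two-sample non-overlap assumption holds by construction.

True effects follow the mediation diagram with defaults equal to the
central worked example: total log-OR ln(1.149), exposure→mediator
ln(1.112), mediator→outcome ln(1.214), hence a true mediated proportion of
0.148. SNP–exposure effects are N(0, 0.08²), sized so that a 100-SNP panel
yields a few dozen instruments past the 1e-5 screen at the default sample
sizes — the instrument counts real analyses of this kind report.

The panel contains three disjoint SNP classes: exposure instruments (which
propagate to the mediator via b₁ and the outcome via the direct and
mediated paths), mediator instruments (direct mediator effects, propagating
to the outcome via b₂ — the variants step-2 MR needs), and outcome-specific
variants (giving a reverse analysis its own instruments while keeping
reverse causation truly null). Without mediator-specific instruments,
step-2 MR would be instrumented entirely by variants acting through the
exposure and the estimated "mediated" proportion would tend to 1 regardless
of the truth — the generator therefore treats mediator instruments as
first-class.

Horizontal pleiotropy gives exposure SNPs additional direct outcome
effects: `balanced` ~ N(0, m²); `directional` ~ sign(γⱼ)·N(m, (m/2)²),
i.e. a positive mean in the exposure-increasing-allele orientation. The
orientation matters: with symmetric γ and orientation-free directional
effects, the IVW numerator Σwⱼγⱼαⱼ has expectation zero and no bias
appears; the oriented definition is the textbook setting in which IVW is
biased and the Egger intercept absorbs the offset (the InSIDE assumption
holds since |α| is independent of γ).

Alleles are drawn from non-palindromic pairs so harmonizing generated files
is loss-free; palindromic handling is exercised by dedicated unit tests.
LD, when requested, is an idealized block-diagonal r² structure with blocks
placed ≥ 50 Mb apart. The generator does **not** emulate: realistic LD
maps, winner's-curse selection bias, sample overlap, population
stratification, allele-frequency differences between studies, or
liability-scale subtleties of binary traits. Passing recovery tests
therefore demonstrate internal consistency of the pipeline under the
model's own assumptions, not robustness to those real-data complications.

## Calibration experiments and their design

- **Type-I error**: 500 null systems (all true effects zero), exposure-side
  instrument selection only, fixed-effect IVW. Two deliberate choices:
  the fixed-effect flavor, because its z-statistic is the one with an
  exactly nominal null distribution (the multiplicative random-effects SE
  scaling √max(Q/(J−1),1) can only inflate, measured size ≈ 0.03 under the
  same null); and no Steiger filtering, because filtering on outcome
  statistics conditions the retained set on the outcome noise and makes
  the reference distribution non-standard. Both conservative layers remain
  the pipeline defaults for analysis; the experiment isolates the test.
- **Cochran's Q null**: homogeneous systems with exactly known exposure
  effects (σ_γ → 0) so Q is exactly χ²_{J−1}; 1,000 draws,
  Kolmogorov–Smirnov comparison.
- **Proportion CI coverage**: 2,000 synthetic effect triples around the
  default true effects with SEs typical of well-powered constituent fits
  (0.010/0.015/0.004); delta intervals are first-order, so coverage is
  expected near, not exactly at, 95%.
- **Recovery**: 500 full-pipeline replicates (selection → filtering →
  harmonization → Steiger → estimation → mediation) at sample sizes 20,000
  per study ("strong instruments"); the mean estimated proportion is
  compared with the true 0.148. Problem sizes (100 + 100 + 50 SNPs per
  replicate) keep each replicate light while leaving ~25–35 instruments
  per fit.
- **Robustness**: a single 10-SE displaced outcome beta in an otherwise
  clean ~35-instrument set must be flagged by the outlier test; under
  directional pleiotropy (mean 0.01) the absolute IVW bias must exceed the
  absolute Egger bias over 100 replicates.

## Numerical choices and degenerate inputs

Zero exposure betas are excluded from Wald ratios (logged); a single
instrument reduces IVW to the Wald ratio and suppresses random-effects
scaling; Egger and the weighted median require ≥ 3 instruments, the
outlier test ≥ 4. Variance-explained values are clamped to [0, 1).
Bootstrap and simulation seeds are explicit arguments recorded in results;
rerunning any pipeline entry point with the same config and seed is
byte-identical. Clumping ties on p-value break lexicographically.
Floating-point round-trips through the TSV writer use 17-significant-digit
formatting and round-trip float parsing.

## Known limitations

Single-mediator decomposition only (each mediator treated marginally);
no multivariable MR; no overdispersion parameter in the profile-score
estimator; the Steiger z is an approximation; the distortion test is a
package-specific variant; delta-method intervals degrade when the total
effect is near zero or relative SEs are large — exactly the regimes the
`consistent_direction` flag and out-of-range warnings are meant to
surface, not hide.
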