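# mrmediate

Two-sample Mendelian randomization (MR) and two-step MR mediation analysis
on GWAS summary statistics.

`mrmediate` is for epidemiologists and statistical geneticists who want to
ask whether an exposure (say, the abundance of a gut microbial taxon)
causally affects a disease outcome (say, chronic gastritis), and how much of
that effect flows through an intermediate trait (say, a blood metabolite) —
using only published per-variant association summaries, never
individual-level data.

## The statistical core

Genetic variants robustly associated with the exposure serve as instrumental
variables. For instrument *j* with SNP–exposure effect γ̂ⱼ (SE σ_γⱼ) and
SNP–outcome effect Γ̂ⱼ (SE σ_Γⱼ), the per-SNP Wald ratio is
β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Γⱼ/|γ̂ⱼ|. The estimator suite:

- **IVW** — β̂ = Σwⱼβ̂ⱼ / Σwⱼ with wⱼ the inverse ratio variances; fixed-effect
  or multiplicative random-effects SE (the default inflates the SE by
  √max(Q/(J−1), 1) under heterogeneity).
- **MR-Egger** — weighted regression of Γ̂ⱼ on γ̂ⱼ with a free intercept
  (rows oriented to γ̂ⱼ ≥ 0); the intercept estimates average directional
  pleiotropy, the slope the causal effect.
- **Weighted median** — the inverse-variance-weighted median of the Wald
  ratios, consistent when instruments carrying ≥ 50% of the weight are valid;
  SE by parametric bootstrap.
- **Profile score (RAPS-style)** — maximizes −½ Σρ(tⱼ(β)) with
  tⱼ(β) = (Γ̂ⱼ − βγ̂ⱼ)/√(σ_Γⱼ² + β²σ_γⱼ²), squared or Huber ρ, accounting for
  measurement error in γ̂ⱼ.

Instrument hygiene: p < 1×10⁻⁵ screening, greedy LD clumping
(10,000 kb window, r² > 0.001), exclusion of weak instruments with
F = R²(N−K−1)/[(1−R²)K] < 10, and Steiger filtering (keep SNPs explaining
more variance in the exposure than the outcome). Diagnostics: Cochran's Q,
funnel coordinates, the Egger intercept test, leave-one-out, and a
simulation-based residual-sum-and-outlier (MR-PRESSO style) test with
global, per-SNP and distortion components.

**Two-step mediation.** With total effect *c* (exposure→outcome), step-1
effect *b₁* (exposure→mediator) and step-2 effect *b₂* (mediator→outcome,
instrumented by the mediator's own variants), the indirect effect is
*b₁·b₂* (product method, delta-method SE
√(b₂²σ₁² + b₁²σ₂²)), the direct effect is *c − b₁b₂*, and the proportion
mediated is *b₁b₂/c* with a delta-method 95% interval. All arithmetic is on
the natural-log-odds scale; odds ratios are `exp` views.

## Worked example

The packaged worked example takes published IVW odds ratios for five
gut-microbiota → blood-metabolite → chronic-gastritis pathways and
decomposes each total effect:

```bash
$ mrmediate reproduce-paper
                                                                           label  proportion_pct  consistent_direction
PWY-6708 ubiquinol-8 biosynthesis -> 4-hydroxyphenylacetate -> chronic gastritis       14.822062                  True
         Coprococcus sp. ART55/1 -> phosphate/alanine ratio -> chronic gastritis       10.638090                  True
                         Coprococcus sp. ART55/1 -> X-12839 -> chronic gastritis        8.460886                  True
                     Odoribacter -> phosphate/alanine ratio -> chronic gastritis        7.909157                  True
                       Odoribacter -> palmitoleate (16:1n7) -> chronic gastritis        6.965634                  True
```

Reading the first row: the taxon's total effect on chronic gastritis is
OR 1.149 per SD (log-OR 0.139); it raises 4-hydroxyphenylacetate by
OR 1.112 per SD, and that metabolite raises gastritis risk by OR 1.214 per
SD, so the indirect effect is ln(1.112)·ln(1.214) = 0.0206 — 14.8% of the
total. `consistent_direction` confirms the indirect and total effects share
a sign, the qualitative requirement for a mediation interpretation.

The same decomposition runs on your own estimates via
`mrmediate mediate triples.csv --out table.tsv`, and the full
summary-statistics workflow via `mrmediate mr`, `mrmediate bidirectional`
and `mrmediate workflow-mediate` (see `--help`; synthetic demonstration
inputs come from `mrmediate simulate`).

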