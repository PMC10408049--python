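# Methods

## Statistical model

`cismr` estimates the causal effect of a continuous exposure (SD units) on
binary outcomes (log-odds units) from two-sample GWAS summary statistics,
using genetic variants in one or more *cis* gene regions as instruments.
For variant *j*, γ̂ⱼ is the variant–exposure association and Γ̂ⱼ the
variant–outcome association (possibly itself a fixed-effect meta-analysis
over cohorts). Under the instrumental-variable assumptions (relevance, no
confounding of the variant–outcome relationship, effects on the outcome
only through the exposure) each Wald ratio θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates a common
slope β, the log-OR per SD of exposure.

Because cis instruments are correlated, pooling uses generalized least
squares of Γ̂ on γ̂ through the origin. With R the signed LD correlation
matrix aligned to the harmonized effect alleles and
Ωⱼₖ = se(Γ̂ⱼ)·se(Γ̂ₖ)·rⱼₖ:

    β̂  = (γ̂ᵀΩ⁻¹γ̂)⁻¹ γ̂ᵀΩ⁻¹Γ̂
    v   = (γ̂ᵀΩ⁻¹γ̂)⁻¹
    Q   = (Γ̂ − β̂γ̂)ᵀ Ω⁻¹ (Γ̂ − β̂γ̂)
    φ   = max(1, Q/(J−1))        (J ≥ 2; φ = 1 for J = 1)
    se  = √(vφ),  CI = β̂ ± 1.96·se,  p two-sided normal.

The multiplicative random-effects factor φ absorbs residual heterogeneity
(e.g. mild pleiotropy) by inflating the variance without moving the point
estimate; the floor at 1 means it can only widen intervals. Weights are
first-order: exposure-side uncertainty enters neither Ω nor the weights.
That choice matches the mean-F diagnostic, whose reciprocal 1/F̄ then
approximates the relative weak-instrument bias of β̂. With R = I the
estimator is algebraically the textbook IVW of Wald ratios with
first-order weights, and with J = 1 it is exactly the Wald ratio — both
identities are enforced by tests against independent oracles.

Normal (not t) reference distributions are used throughout, consistent
with the large-GWAS regime the method targets.

## Instrument processing

**Region selection.** Variants with p below `p_threshold` (default
5×10⁻⁵, the Bonferroni scale for ~10³ region variants: 0.05/955 ≈
5.2×10⁻⁵) whose position lies within `[start − flank, end + flank]`
(1-based inclusive, GRCh37) of a configured region. Defaults ship the
caffeine-metabolism regions *AHR* 7:17,338,246–17,385,776 and *CYP1A2*
15:75,041,185–75,048,543 with 100 kb flanks. Overlapping regions resolve
first-listed-wins.

**Clumping.** Greedy by ascending p (rsid tie-break, so results are
deterministic): keep the most significant remaining variant, remove every
other variant with r² > `clump_r2` (default 0.3) within
`clump_window_kb` (default 10,000 kb) on the same chromosome. Greedy
selection by p is the de facto standard; an exhaustive oracle validates it
on all small instances.

**FIQT winner's-curse correction.** Selected effect sizes are
conditionally biased away from zero. The FDR inverse quantile
transformation BH-adjusts the two-sided p-values using `m_total` tests —
defaulting to the count of variants measured in the regions, *not* just
the selected ones, since that is the family selection acted on — and maps
p_BH back to a shrunken z. Adjusted p ≥ 1 maps to β̂ₐdⱼ = 0 (warned).
Shrinkage never increases |β| and preserves the |z| order. FIQT is applied
after clumping to the retained instruments.

**Harmonization.** Outcome records are aligned to the exposure effect
allele: swapped alleles flip the outcome beta and complement its
frequency; non-matching allele pairs are excluded. Palindromic (A/T, C/G)
variants can only be aligned by frequency: both EAFs must fall outside
0.5 ± `eaf_ambiguity_band` (default 0.08, a conventional band — exposed as
a parameter since practice varies) and agree in direction, otherwise the
variant is excluded; a missing EAF on a palindromic variant excludes it.
Every input variant is either retained or logged with a reason.

**LD input.** Signed r from TSV (symmetrized, unit diagonal forced) or
computed from a dosage table by row-wise Pearson correlation. Matrices
with eigenvalues below −10⁻⁸ are repaired by clipping eigenvalues at
10⁻¹⁰, reconstructing and rescaling the diagonal to 1; the repair is
logged. Sub-analyses (leave-one-out, per-gene, lead-variant) reuse
submatrices of the repaired matrix without re-repair, for determinism.

## Meta-analysis

Per-variant outcome associations from multiple cohorts are pooled by
fixed-effect inverse variance (weights 1/se²); a variant measured in only
some sources is pooled over those sources, which is how instrument counts
can differ across outcomes. Heterogeneity uses Cochran's Q with
I² = max(0, (Q − df)/Q). MR estimates across sources, when heterogeneous,
are additionally combined by DerSimonian–Laird additive random effects
(τ² from the moment estimator, floored at 0). REML/Paule–Mandel
estimators are out of scope.

## Multiple testing and reporting

BH-FDR (via statsmodels) runs across the primary estimate of each outcome
in a run — the family is the configured outcome list; sensitivity analyses
never enter it. Odds ratios are exp of the slope and CI bounds, reported
to 3 decimals in the TSVs and at full precision in `run.json`. All outputs
are plain TSV plus one JSON metadata file, byte-identical across re-runs
of the same configuration.

## Synthetic-data generator

The generator emulates the summary-data regime directly — no
individual-level genotypes — which is faster and matches exactly what the
estimators consume. Per region: rⱼₖ = ρ^|j−k| (AR(1), default ρ = 0.75);
MAFs uniform on (0.1, 0.5); sparse causal exposure effects whose marginal
effects propagate through LD as γ = R·γ_causal, so selection and clumping
behave realistically; γ̂ ~ MVN(γ, D·R·D) with
se(γ̂ⱼ) = 1/√(2nₓfⱼ(1−fⱼ)). Outcome associations are
Γ = β·γ (+ optional per-variant pleiotropy), observed per case-control
source with se(Γ̂ⱼ) = 1/√(2nv fⱼ(1−fⱼ)), v = φ_case(1−φ_case) — the
effective-sample-size approximation for log-odds standard errors, adequate
for calibration though not exact for rare outcomes. A single seed feeds a
SeedSequence spawn (structure, exposure, one stream per source), so adding
a source never changes the exposure draws.

Defaults mirror the motivating study's conditions: exposure n = 9876,
selection at p < 5×10⁻⁵, two regions of 30 variants (one causal signal of
0.20 SD at *AHR*; 0.16 and 0.11 SD at *CYP1A2*), consortium
(100k/200k) and biobank (6.5k/350k) outcome sources. Under these
conditions about 7 instruments survive clumping, matching the cis-MR
setting the pipeline targets.

What the generator does **not** emulate: realistic human LD (haplotype
block structure, allele-frequency-dependent LD), strand ambiguity and
allele-coding errors (all simulated variants are A/G and pre-aligned, so
harmonization is exercised by handwritten fixtures instead), sample
overlap between exposure and outcome studies, population stratification,
and covariate-adjustment artefacts. Passing calibration tests therefore
demonstrates correctness of the estimation chain under its own
assumptions, not robustness to those real-data complications.

## Calibration experiments and numerical choices

`recovery_experiment` repeats simulate → select → clump → FIQT →
harmonize → meta → correlated IVW, with the winner's-curse correction on
and off on the same draws (paired arms), and reports mean bias with its
Monte-Carlo standard error, empirical vs model SE, 95% CI coverage,
rejection rate, and the exposure-side selection bias
mean(|γ̂| − |γ|) per arm. At 1000 replicates (the scale the test suite and
acceptance script use; each replicate is a ~60-variant problem, so the
full experiment runs in seconds) the estimator recovers a true slope of
0.1 with |bias| within three Monte-Carlo standard errors of zero, coverage
near 0.95 and nominal type-I error under the null. A residual bias of
order 1/F̄ (~2% of the slope, attenuating without FIQT and slightly
anticonservative with it) is expected from first-order weighting and sits
well inside that band; it is the same 2–4% magnitude the mean-F diagnostic
advertises.

Other numerical conventions: Ω is solved directly (no explicit inverse);
an exactly-fitting model can produce Q ≈ −10⁻¹⁶ by round-off, floored at
0; p-values are floored at the smallest positive double to keep them in
(0, 1]; clumping ties on p break lexicographically by rsid; region
p-thresholds are strict (`p < threshold`) and positional bounds inclusive.

## Known limitations

- First-order weights ignore exposure-side uncertainty (NOME-style
  assumption); with weak instruments (mean F ≲ 10) the slope attenuates
  and FIQT only partially compensates.
- The multiplicative random-effects model treats pleiotropy as
  undirected overdispersion; directional pleiotropy (MR-Egger-type
  intercepts) is unidentifiable with a handful of correlated cis variants
  and deliberately out of scope, as are median/mode estimators.
- Binary-outcome standard errors use the effective-sample-size
  approximation; very unbalanced case fractions push its accuracy.
- LD matrices estimated from small reference panels are noisy; the
  eigenvalue-clip repair guards positive-definiteness but cannot fix a
  mismatched reference population.
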