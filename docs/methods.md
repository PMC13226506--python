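# Methods

## Model and assumptions

All analyses operate on two-sample GWAS summary statistics. An
instrument j for exposure X carries an estimated per-allele effect
β_Xj with standard error σ_Xj; the same variant's effect on outcome Y
is β_Yj ± σ_Yj, taken from an independent study. Under the
instrumental-variable assumptions (relevance: the variant affects X;
independence: no confounding of the variant–outcome relation;
exclusion: no effect on Y except through X), each Wald ratio
β_Yj/β_Xj estimates the causal effect θ of X on Y. For binary
outcomes all effects are on the log-odds scale, so exp(θ) is an odds
ratio per unit (SD) of exposure.

The estimators differ in how they pool ratios and in which violations
they tolerate:

- **IVW** is the precision-weighted mean of the ratios (equivalently,
  weighted regression of β_Y on β_X through the origin, weights
  1/σ²_Y). Unbiased only if every instrument is valid; the primary
  analysis.
- **MR-Egger** frees the intercept; under the InSIDE assumption
  (pleiotropic effects independent of instrument strength) the slope
  stays consistent and the intercept estimates average directional
  pleiotropy. Exposure effects are oriented positive before fitting —
  without a fixed orientation the intercept is not identified.
  Inference is t-based on n−2 df.
- **Weighted median** is consistent when instruments carrying at least
  half the total weight are valid; implemented as linear interpolation
  of the weighted empirical CDF of ratios at 0.5.
- **Simple/weighted mode** take the argmax of a normal-kernel density
  over the ratios; consistent when the largest group of
  equal-ratio instruments is valid (ZEMPA).

## Numerical choices

- **Random effects.** IVW and Egger report multiplicative
  random-effects standard errors: the fixed-effect SE is inflated by
  √(Q/df) when Cochran's Q exceeds its degrees of freedom, and never
  deflated. This is the dominant two-sample convention.
- **Egger intercept test.** The pleiotropy *test* uses the plain
  weighted-regression t-test (residual-scaled SE without the
  inflation floor). With known outcome variances this test is exactly
  calibrated under the no-pleiotropy null (measured 4.6% type-I error
  at α = 0.05 over 500 null replicates), whereas the floored SE is
  conservative (2.2%). The reported Egger *estimate* keeps the floored
  SE for consistency with the other estimators.
- **Bootstrap SEs.** Weighted median and the mode estimators use a
  seeded parametric bootstrap (default 1000 replicates) resampling
  β_X and β_Y from their normal sampling distributions.
- **Mode bandwidth.** h = φ · 0.9 · min(SD, MAD) · n^(−1/5) over the
  ratios, φ = 1 by default; MAD is scaled to be consistent for the
  normal SD. Degenerate spreads (all ratios equal) return the common
  ratio directly.
- **Cochran's Q** uses outcome-variance weights around the fitted
  model, df = n−1 (IVW) or n−2 (Egger); I² = max(0, (Q−df)/Q)·100;
  p is the upper-tail χ² probability. The df convention reproduces
  printed heterogeneity p-values of the motivating analysis
  (Q = 10.430 with 13 SNPs → df 12 → p = 0.578).
- **MR-PRESSO.** The observed residual sum of squares (each SNP
  against the IVW fit of the others) is compared to 1000 simulated
  datasets drawn from the fitted no-pleiotropy model; empirical
  p-values use (r+1)/(n_sim+1), so they can never be exactly zero.
  Outliers are per-SNP Bonferroni-flagged at α = 0.05; the distortion
  test compares the estimate shift after outlier removal against
  removals of random subsets of equal size.
- **Clumping ties** break on (p-value, then lexicographic SNP id), so
  selection is fully deterministic.
- **Harmonization.** Swapped and reverse-complement allele frames are
  reconciled by negating β_Y and complementing EAF; palindromic (A/T,
  C/G) variants with MAF > 0.42 on either side are dropped, and
  below that cutoff are oriented by EAF agreement (both sides on the
  same side of 0.5 ⇒ same strand). Missing EAF fails closed for both
  palindrome resolution and MAF filtering.
- **Mediation.** Direct effect by difference (β₃ − β₁β₂), so
  β₃ = direct + indirect holds exactly. The proportion CI is
  delta-method with the three estimates treated as independent
  normals (a parametric-bootstrap CI is available); reportability
  requires sign alignment of total, direct and indirect effects and
  |proportion| > 5%. In a panel screen, step-1 and step-2 p-values
  are BH-FDR-adjusted across mediators and a hit additionally needs
  both adjusted p-values below α = 0.05.

## The synthetic-data generator

The generator works at the summary level; no genotypes are simulated.
Per SNP, se = 1/√(2·maf·(1−maf)·n) with n the (effective) sample
size, and observed effects are the true effects plus normal noise,
optionally equicorrelated within declared LD blocks. The causal chain
is exposure → mediator → outcome with true per-SNP effects
γ_j (exposure), β₁γ_j (mediator) and
direct·γ_j + β₂β₁γ_j + α_j (outcome), where α_j is a direct
SNP→outcome (pleiotropic) effect. A disjoint trans panel instruments
each mediator alone, so the second mediation step has its own
instruments, as in a real screen. The identity
total = direct + β₁β₂ holds exactly by construction.

Default parameters mirror a cis-eQTL drug-target analysis of a rare
binary outcome: 13 exposure instruments; γ ~ N(0.061, 0.01²) with
exposure study n = 31,684, giving per-SNP F ≈ 38; outcome effective
n = 3,622 (a 909-case/238k-control study on the log-odds scale);
mediator n = 3,757; θ = −0.306, β₁ = 0.463, β₂ = −0.188,
direct = −0.219 (proportion mediated 28.4%); MAF uniform on
[0.1, 0.4]. Under these conditions the IVW standard error is ≈ 0.13,
matching the precision regime of the motivating study.

What the generator does **not** emulate: realistic LD maps from
reference panels (blocks are idealized equicorrelated sets), sample
overlap between studies, winner's-curse selection of instruments, and
case-fraction effects beyond the effective-n approximation. Passing
simulation tests therefore demonstrate correctness of the estimators
and pipeline under the stated sampling model, not robustness to every
artefact of real GWAS data.

## Simulation study sizes

Calibration experiments use 500 replicates (type-I error, CI
coverage), MR-PRESSO power/null calibration 100 replicates with 1000
inner simulations, and the end-to-end mediation recovery 200
replicates of a 10-mediator screen. The mediation-recovery experiment
scales exposure and mediator sample sizes ×16 and the outcome ×8
relative to the defaults: the proportion estimate is a plug-in ratio
β̂₁β̂₂/β̂₃ whose finite-sample bias shrinks with the total-effect SE,
while the outcome-association exclusion filter (p < 1e−5) — inert at
realistic outcome precision — would begin removing true-effect
instruments (and thereby attenuate β̂₃ by ~5%) if the outcome study
were scaled much further. The ×8 outcome scaling keeps that filter
inert while making the ratio bias negligible (measured −0.01
percentage points over 200 replicates); this attenuation-by-filtering
behaviour is a real property of outcome-exclusion rules worth knowing
about when interpreting screens against well-powered outcomes.

## Known limitations

- Single-variant, bi-allelic SNPs only; no indels or multi-allelics.
- No Steiger directionality filtering or multivariable MR; the direct
  effect is obtained by difference, not from a joint model.
- The delta-method proportion CI assumes independence of the three
  estimates; with shared instruments between steps this is an
  approximation (the bootstrap option inherits the same independence
  assumption at the estimate level).
- The LD provider abstraction expects the caller to supply pairwise
  r²; no reference-panel computation is included.
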