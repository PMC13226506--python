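# targetmr

Drug-target Mendelian randomization (MR) from GWAS summary statistics:
cis-eQTL instrument selection, exposure/outcome harmonization, the
standard five-estimator battery with full sensitivity diagnostics, and
two-step mediation MR with mediation-proportion reporting.

## The problem

When a drug's protein target is encoded by a gene with known cis-eQTLs,
variants that shift the gene's expression act as lifelong, randomized
proxies for pharmacological modulation of the target. Two-sample MR
uses per-SNP association statistics from an exposure GWAS (here,
expression of the target gene) and an outcome GWAS (a disease) to
estimate the causal effect of target modulation on disease risk —
without individual-level data. A second, two-step design asks how much
of that effect is *mediated* by an intermediate trait (here, immune-cell
phenotypes): step 1 estimates the exposure→mediator effect β₁, step 2
the mediator→outcome effect β₂, and the proportion mediated is
β₁β₂/β₃ of the total effect β₃.

`targetmr` implements this workflow end to end for summary statistics,
with a synthetic-data generator that emulates the whole causal chain
(exposure → mediator → outcome, plus pleiotropy, outliers, LD blocks,
palindromic and strand-flipped records) so every stage is testable with
known ground truth.

## Methods at a glance

For harmonized pairs (β_Xj ± σ_Xj, β_Yj ± σ_Yj), with weights
w_j = 1/σ²_Yj:

- **IVW** (primary): β̂ = Σw_jβ_Xjβ_Yj / Σw_jβ²_Xj — weighted
  regression through the origin; multiplicative random-effects SE
  (inflation by √(Q/(n−1)) when Cochran's Q exceeds its df).
- **MR-Egger**: the same regression with a free intercept; the
  intercept estimates average directional pleiotropy.
- **Weighted median**: median of the weighted empirical distribution of
  Wald ratios β_Yj/β_Xj; robust when ≥50% of the weight is valid.
- **Simple/weighted mode**: argmax of a kernel density over the Wald
  ratios (MAD-based modified-Silverman bandwidth × φ).
- **Diagnostics**: Cochran's Q and I², Egger intercept test,
  leave-one-out, and MR-PRESSO (simulation-based global RSS, per-SNP
  outlier, and distortion tests).
- **Mediation**: indirect = β₁β₂, direct = β₃ − β₁β₂, proportion
  mediated = 100·β₁β₂/β₃ % with a delta-method CI; a mediator is
  reportable when all three effects share a sign and the proportion
  exceeds 5%; panels are screened with Benjamini–Hochberg FDR control.

Instrument selection follows the drug-target preset (p < 1e−5,
r² < 0.30 within 100 kb, MAF > 0.05, cis ±300 kb, per-SNP F > 10,
outcome-associated SNPs excluded at p < 1e−5) or the immune-trait
preset (r² < 0.001 within 10,000 kb, no cis restriction).

## Worked example

```python
from targetmr.pipeline import PipelineConfig, run_uvmr, run_mediation

cfg = PipelineConfig(seed=2, outdir="example")
out = run_uvmr(cfg)          # synthetic drug-target scenario by default
print(out["results"].round(3).to_string(index=False))
```

```
                   method   beta    se    OR  CI_low  CI_high  pvalue  n_snp
Inverse variance weighted -0.306 0.119 0.737   0.583    0.930   0.010     11
                 MR Egger  0.088 0.571 1.092   0.356    3.346   0.881     11
              Simple mode -0.330 0.260 0.719   0.432    1.197   0.205     11
          Weighted median -0.339 0.161 0.712   0.520    0.976   0.035     11
            Weighted mode -0.348 0.220 0.706   0.459    1.088   0.115     11
```

The default scenario encodes a protective causal effect of −0.306
log-odds per SD of exposure; the IVW row recovers it (OR 0.737,
95% CI 0.583–0.930): genetically proxied target modulation lowers
disease odds by ~26%. Diagnostics on the same run show no
heterogeneity (I² = 0%, Q = 9.9, p = 0.45) and no directional
pleiotropy (Egger intercept p = 0.50; MR-PRESSO global p = 0.48) —
the estimate is not driven by a single variant or a pleiotropic subset.

The mediation screen over a 10-trait panel with one true mediator
(β₁ = 0.463, β₂ = −0.188, direct = −0.219):

```python
cfg = PipelineConfig(seed=2, outdir="example",
                     mediator_panel={"n_mediators": 10, "true_index": 3},
                     scenario={"n_exp": 31684*16, "n_out": 3622*8, "n_med": 3757*16})
print(run_mediation(cfg)["report"])
```

```
total effect beta3 = -0.308 (OR 0.735, p 9.01e-13)
1 reportable mediator(s) of 10 screened
  mediator_03: proportion mediated 26.8% (16.1 to 37.5)
```

The screen singles out the causal mediator and estimates that it
carries ~27% of the total effect (ground truth 28.4%).

A CLI wraps the same entry points: `targetmr simulate|mr|positive-control|mediate
--config config.yaml --seed 2 --outdir results`.

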