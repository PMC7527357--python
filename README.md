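# mratlas

Two-sample Mendelian randomisation (MR) for atlas-style screens: estimate the
causal effects of many exposures on one binary outcome from GWAS summary
statistics alone, with false-discovery-rate control across the screen,
sensitivity analyses for invalid instruments, replication checking in an
independent outcome dataset, and analytic power.

The package is aimed at epidemiologists and statistical geneticists who want a
tested, scriptable implementation of the standard two-sample MR workflow —
the kind used to screen ~100 candidate risk factors against a large
case-control outcome GWAS — without genotype-level data: every input is a
per-SNP summary table (variant, alleles, allele frequency, beta, SE, p, N).

## The model

For instrument SNP $j$, let $\hat\gamma_j$ (SE $\sigma_{Xj}$) be its effect on
the exposure and $\hat\Gamma_j$ (SE $\sigma_{Yj}$) its effect on the outcome
log-odds, both per copy of the same effect allele. Each valid instrument gives
a Wald ratio $\hat\theta_j = \hat\Gamma_j/\hat\gamma_j$ for the causal effect
$\theta$. The estimator suite:

- **IVW** — inverse-variance-weighted mean of the ratios with first-order
  weights $w_j = \hat\gamma_j^2/\sigma_{Yj}^2$ (equivalently, weighted
  regression of $\hat\Gamma$ on $\hat\gamma$ through the origin). Fixed
  effects for 1–2 SNPs; for ≥ 3 SNPs the SE is inflated by
  $\sqrt{\max(1, Q/(n-1))}$ (multiplicative random effects), with Cochran's
  $Q$ and $I^2 = \max(0, (Q-\mathrm{df})/Q)$ reported as heterogeneity
  diagnostics.
- **Weighted median** — the ratio at the 50% point of the IVW-weight
  cumulative distribution (linear interpolation of sorted ratios against
  cumulative weight midpoints); consistent while > 50% of weight comes from
  valid instruments. SE by parametric bootstrap.
- **MR-Egger** — weighted regression with a free intercept: the slope
  estimates $\theta$ under InSiDE, the intercept the average directional
  pleiotropy, and the intercept p-value is the horizontal-pleiotropy test.
- **Multivariable IVW** — joint weighted regression on two exposures' genetic
  effects (no intercept) for direct effects, e.g. adjustment for adulthood
  BMI.

Instruments are built by genome-wide selection ($p < 5\times10^{-8}$,
strict), greedy LD clumping (exclude $r^2 \ge 0.01$ with any kept SNP),
rsID join to the outcome, proxy substitution ($r^2 \ge 0.8$) when a trait is
missing at most 10 SNPs, and harmonisation to the exposure-increasing allele
with ambiguous palindromic SNPs (EAF in [0.42, 0.58]) dropped. Screen-wide,
primary IVW p-values get Benjamini–Hochberg adjustment; associations are
**significant** (adjusted p < 0.05), **suggestive** (IVW or weighted-median
p < 0.05 with concordant direction), or null; nominal discoveries are
re-estimated against a replication outcome (direction concordance, p < 0.1).

A synthetic summary-statistics generator (`SimScenario`,
`simulate_two_sample`, `simulate_atlas`) produces datasets with known causal
effects, configurable pleiotropy regimes and a missing-SNP/proxy pathway, so
the whole pipeline is testable end to end.

## Worked example

`examples/single_exposure.py` simulates a 40-SNP exposure with true causal
effect 0.2 log-odds (OR $e^{0.2} = 1.221$) against a 74,124-case /
824,006-control outcome, and runs the suite:

```
instruments: 30 of 31 genome-wide-significant SNPs (missing 0, dropped in harmonisation 1)
instrument strength: F = 229.5 (strong)

ivw_random: OR 1.238 (95% CI 1.184, 1.295), p = 4.16e-21
heterogeneity: Q = 31.6 on 29 df, I2 = 0.08
weighted median: OR 1.215, p = 1.43e-09
MR-Egger slope: OR 1.356, p = 1.20e-06
MR-Egger intercept p = 0.12 -> possible pleiotropy: False

true OR: 1.221
```

All three estimators bracket the true OR; heterogeneity is at its null level
($I^2 \approx 0$) and the pleiotropy test correctly stays quiet. The other
examples cover the multi-exposure screen with FDR control and replication
(`atlas_screen.py`), the power surface (`power_analysis.py`) and estimator
behaviour under directional pleiotropy (`pleiotropy_robustness.py`).

A thin CLI mirrors the library: `mr-atlas run --config atlas.yaml --out
report.tsv --seed 17`, plus `simulate`, `estimate` and `power` subcommands
(`mr-atlas power --n 898130 --cases 74124 --r2 0.01 --or 1.1` prints
`0.700`).

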