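# Methods

## Setting and assumptions

`mratlas` implements two-sample summary-statistic Mendelian randomisation: the
SNP-exposure effects $\hat\gamma_j$ come from one GWAS, the SNP-outcome
log-odds effects $\hat\Gamma_j$ from another, and the two samples are treated
as independent. Estimation assumes the instruments are (after clumping)
mutually independent, associated with the exposure, and — for the core IVW
estimate — affect the outcome only through the exposure. The sensitivity
estimators relax the last assumption in the usual ways: the weighted median
tolerates up to half the instrument weight being invalid, and MR-Egger allows
directional pleiotropy provided instrument strength is independent of the
direct effects (InSiDE).

## Instrument construction

- **Selection**: keep SNPs with exposure $p < 5\times10^{-8}$, strictly.
- **Clumping**: greedy, in ascending p-value order (ties by variant id); a
  SNP is kept iff its recorded $r^2$ with every kept SNP is $< 0.01$.
  Unrecorded pairs count as $r^2 = 0$; there is no distance window — LD is
  whatever the supplied pair table says. Output therefore depends only on
  (p, id, LD), not input order.
- **Outcome join** by rsID. If a trait is missing at most 10 SNPs from the
  outcome table, each missing SNP may be replaced by its highest-$r^2$ proxy
  with $r^2 \ge 0.8$ among outcome-present variants (ties by smallest id).
  Proxy orientation uses the LD table's phase-concordance flag; without phase
  information a proxy is used only when its allele labels exactly match the
  index SNP's. With more than 10 missing, missing SNPs are dropped and no
  proxies are used.
- **Harmonisation**: the exposure record is oriented so the effect allele is
  exposure-increasing ($\hat\gamma_j \ge 0$, the orientation MR-Egger
  requires); outcome alleles are matched directly, by label swap (sign flip),
  or after strand complement. Palindromic SNPs (A/T, C/G) with EAF in
  [0.42, 0.58] in either dataset are dropped as strand-ambiguous; palindromes
  outside the band are kept, with a sign flip when the two datasets' EAFs fall
  on opposite sides of 0.5. A missing EAF disables the frequency checks for
  that SNP (labels are then taken at face value).
- **Strength**: $F = \frac{R^2}{1-R^2}\cdot\frac{n-k-1}{k}$, flagged strong
  when $F > 10$ (strict). $R^2$ comes from the registry when supplied;
  otherwise it is approximated per SNP by $2\,\mathrm{eaf}(1-\mathrm{eaf})
  \hat\gamma_j^2$ (standardised trait) and summed.

## Estimators

All use first-order weights $w_j = \hat\gamma_j^2/\sigma_{Yj}^2$ (uncertainty
in $\hat\gamma$ ignored in the weights), normal-reference two-tailed p-values,
and 95% CIs at $z = 1.959964$.

- **IVW**: $\hat\theta = \sum w_j\hat\theta_j/\sum w_j$,
  $\mathrm{se}_{\mathrm{fixed}} = (\sum w_j)^{-1/2}$,
  $Q = \sum w_j(\hat\theta_j - \hat\theta)^2$ on $n-1$ df. Under the
  automatic policy, exposures with ≥ 3 SNPs use multiplicative random
  effects, $\mathrm{se} = \mathrm{se}_{\mathrm{fixed}}\sqrt{\max(1, Q/(n-1))}$;
  1–2-SNP exposures use fixed effects. $Q$ is computed whenever $n \ge 2$ but
  SEs are never inflated below 3 SNPs. The floor at 1 means random-effects
  IVW is mildly conservative under homogeneity (measured type-I error ~0.045
  at $\alpha = 0.05$, 50 SNPs), which we accept as the cost of robustness to
  overdispersion.
- **Weighted median**: sort ratios, form cumulative weight midpoints
  $p_j = (S_j - w_{(j)}/2)/S_n$, interpolate at $p = 0.5$; outside the
  midpoint range the extreme ratio is returned. SE by parametric bootstrap
  (default 1,000 draws of $\hat\gamma_j$ and $\hat\Gamma_j$ from their
  sampling distributions, seeded; the bootstrap is the only stochastic step
  in the whole pipeline).
- **MR-Egger**: WLS of $\hat\Gamma$ on $\hat\gamma$ with intercept, weights
  $1/\sigma_{Yj}^2$; covariance scaled by $\max(1, Q_{\mathrm{res}}/(n-2))$.
  Intercept p < 0.05 raises the "possible pleiotropy" flag.
- **Multivariable IVW**: WLS of $\hat\Gamma$ on two exposures' effects, no
  intercept, same overdispersion with df $n-2$. An identically-zero second
  column degenerates gracefully to univariable IVW (the absent coefficient is
  reported as 0 with infinite SE); colinear nonzero columns raise an
  identifiability error. In the atlas, BMI adjustment runs for registry-
  flagged exposures with nominal IVW significance, excluding traits flagged
  as highly BMI-correlated; instruments absent from the BMI summary table
  contribute a zero BMI effect (the adjusting GWAS is assumed near-complete).

## Screen-level decisions

Benjamini–Hochberg adjustment (delegated to statsmodels' step-up
implementation) is applied once across all analysable exposures' primary IVW
p-values. Classification: significant iff adjusted p < 0.05; else suggestive
iff IVW or weighted-median p < 0.05 with concordant signs (exposures with
< 3 SNPs have no weighted median and so cannot be suggestive); else null.
Replication re-harmonises the same discovery instruments against the second
outcome dataset — instruments are not reselected — reruns IVW(auto), and
reports direction concordance and p < 0.1. ORs are rescaled on the log-odds
scale (`exp(beta * unit_scale)`) before exponentiation.

## Analytic power

For a binary outcome with total sample $n$, case fraction $c$, instrument
variance explained $R^2$ and true odds ratio $\mathrm{OR}$:
$\mathrm{power} = \Phi\!\big(\sqrt{n R^2 c(1-c)}\,|\ln \mathrm{OR}| -
z_{1-\alpha/2}\big)$. The lower-tail rejection term is dropped (conservative
by at most $\alpha/2$; at OR = 1 the formula returns exactly $\alpha/2$).
This non-centrality matches the SE model the synthetic generator uses, so
generator and power module are mutually consistent. At 74,124 cases /
824,006 controls, $R^2 = 0.01$ and OR 1.1 the formula gives 0.700. Power for
continuous outcomes is out of scope.

## Synthetic data generator

Per SNP: MAF ~ Uniform(0.05, 0.45); true effect $\gamma_j \sim
N(0.04, 0.04^2)$ on a standardised exposure; $\sigma_{Xj} =
(2\,\mathrm{maf}(1-\mathrm{maf})\,n_X)^{-1/2}$ with $n_X = 200{,}000$;
observed $\hat\gamma_j \sim N(\gamma_j, \sigma_{Xj})$. Outcome:
$\sigma_{Yj} = (2\,\mathrm{maf}(1-\mathrm{maf})\,n\,c(1-c))^{-1/2}$ with a
74,124 / 824,006 case-control discovery sample and an independent 11,006 /
82,655 replication sample; $\hat\Gamma_j \sim N(\theta\gamma_j + \alpha_j,
\sigma_{Yj})$, where $\alpha_j$ is zero for valid SNPs and drawn from the
balanced (mean-zero) or directional (nonzero-mean) regime for an
`invalid_fraction` of SNPs, shared between discovery and replication. About a
third of SNPs get palindromic allele pairs to exercise the ambiguity
handling. A `missing_fraction` of SNPs can be withheld from the discovery
outcome, with phase-concordant proxies ($r^2 \sim U(0.8, 1)$, outcome effect
carried over unchanged) emitted for a `proxy_fraction` of them.

Design notes, chosen once:

- The effect-size spread equals its mean ($sd = 0.04$). Real instrument sets
  mix a few large-effect loci with many small ones, and MR-Egger is only
  regular when the spread of true effects dominates their estimation error
  (the $I^2_{GX}$ condition); with a much narrower spread the Egger intercept
  carries a known dilution bias even at per-SNP F ≈ 100.
- No LD among retained instruments is simulated (estimation theory assumes
  independence after clumping at $r^2 \ge 0.01$); LD appears only in
  deliberate clumping/proxy fixtures.
- Winner's curse is off by default — $\gamma_j$ is drawn, not selected;
  `select_on_significance` enables selection-based generation for stress
  tests.

What the generator does **not** emulate: real LD structure and population
stratification, sample overlap between exposure and outcome GWASs, binary
exposures, non-normal effect distributions, and allele-frequency differences
between cohorts. Passing simulation checks therefore validates the estimator
algebra and the screening logic, not robustness to those data pathologies.

## Validation sizes and numerical choices

The packaged studies (tests and `scripts/acceptance.py`) use 1,000 replicates
of 50-SNP scenarios for recovery, type-I error and robustness, and 200
replicates of the 97-exposure screen (90 nulls, 7 effects of 0.2, 30 SNPs
each) for FDR behaviour — sizes at which Monte-Carlo error is small relative
to the bands checked. Ties in clumping are broken by variant id and in proxy
search by lexicographically smallest id, for determinism. Degenerate inputs
(empty instrument sets, $\hat\gamma_j = 0$ Wald ratios, zero-variance Egger
designs) raise errors rather than returning NaNs; an exposure whose
instrument set comes out empty is marked non-analysable and skipped rather
than failing the screen. Report files round floats to 10 significant digits,
so round-trips agree to well within 6.

## Known limitations

First-order weights ignore exposure-side uncertainty (NOME); with weak
instruments IVW attenuates toward the null and $Q$ is inflated. The weighted
median bootstrap assumes normal sampling of the summary statistics. The
replication step reuses discovery instruments without re-checking LD in the
replication cohort. No MR-PRESSO / mode-based / radial variants are provided.
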