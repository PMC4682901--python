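# Methods

## The shape statistic

All morphometry derives from the three pathologic diameters of a tumor,
sorted to `a ≥ b ≥ c` (cm) before any formula is applied — the
volume equations are asymmetric in the three axes, and pathology reports do
not guarantee an ordering.  The four volume estimators are the ellipsoid
family `V = 4/3·π·r₁·r₂·r₃` with semi-axes `(a,a,a)/2` (spheroid),
`(a,a,b)/2` (oblate), `(a,b,c)/2` (ellipsoid) and `(a,c,c)/2` (prolate).
For every valid triple `spheroid ≥ oblate ≥ ellipsoid ≥ prolate > 0`, with
equalities exactly where the corresponding diameters coincide; the
implementation factors the shared terms so this ordering is exact in floating
point, not merely approximate.

The spheroid–ellipsoid discrepancy

```
SED = (STV − ETV)/STV = 1 − b·c/a²
```

is scale-invariant, lies in `[0, 1)`, and is 0 exactly on spheres.  SED is
returned at full floating precision; report-style rounding (one decimal on
percentages, half-up) is applied only at the output layer, so tertile
cut-points never depend on display rounding.  Degenerate flat tumors are
legal as long as `c > 0`; a configurable minimum thickness (default 0.05 cm,
about half the granularity of pathology rulers) flags suspect records
without rejecting them.

## Cohort stratification and association tests

Hormonal-receptor status is positive when ER **or** PR staining reaches 10 %
of cells; crossed with HER2 this yields the four molecular subtypes.  SED
tertiles are cohort-wide empirical 1/3 and 2/3 quantiles under the
inverse-CDF convention with ties assigned to the lower group — deterministic,
and reproducing near-exact n/3 splits on continuous data.  Node-status
association uses Pearson's χ² without continuity correction (the tables of
interest have large cells); tumor-size differences across tertiles are
summarised as mean ± sample SD with a one-way ANOVA headline p-value and
pairwise Welch t-tests available.  Where the three tertile groups are all
internally constant the F statistic is undefined and the result is flagged
rather than fabricated.

The χ² p-value is validated against an exact conditional (hypergeometric
enumeration) oracle.  At tiny counts the two genuinely differ — the
asymptotic χ² p is anti-conservative relative to the discrete exact null
(e.g. 0.021 vs 0.078 on a 12-subject 2×2 table) — so the equivalence test is
run at large cell counts where the asymptote is valid, and the small-table
behaviour is asserted as the documented discrepancy it is.

## Survival

The endpoint is distant-metastasis-free survival in months; death without
metastasis and end of follow-up are censoring.  Kaplan–Meier estimation,
the k-group log-rank test (hypergeometric variance, quadratic form on k−1
components) and Cox proportional-hazards regression are implemented
in-package and cross-checked against an independent survival library in the
test suite.  Cox fitting maximises the Breslow partial likelihood
(simplest tie convention; ties are common in month-resolution data) by
Newton–Raphson with step-halving, so the log partial likelihood is
non-decreasing across accepted iterations; convergence is a successive
change below 1e-9 within 50 iterations, Wald standard errors come from the
inverse observed information, and monotone-likelihood fits (complete
separation) return `converged=False` instead of raising.  On tie-free data
the score test at β=0 reproduces the two-group log-rank statistic exactly —
a classical identity used as an internal consistency check.  Survival-curve
comparisons support both the global k-group test and pairwise tests against
a reference group (High SED), matching how eccentricity survival figures
are annotated.  The multivariate model's covariate set (tumor size, nodal
status, grade, SED-tertile indicators) is configurable rather than fixed,
since no canonical covariate list exists for this analysis.

## Expression screen

Each gene's FPKM profile is Pearson-correlated with per-sample SED on the
FPKM scale (a log2(FPKM+1) option exists, off by default); the two-sided p
comes from the t transform on n−2 df and is validated against a permutation
null in the tests.  Candidates must pass **all** of `p < 0.01`,
`mean > 10`, `CV > 1` — strict inequalities, no multiple-testing filter;
Benjamini–Hochberg q-values are attached as an informational column only.
Genes with missing values, constant expression, or zero mean are dropped
with logged counts.  Output is partitioned by correlation sign and sorted
ascending by r within partitions.  The stratified variant recomputes (r, p)
within hormone-receptor strata, skipping strata below 3 samples.

At n = 41 the analytic power of the `p < 0.01` filter is ≈ 0.95 at
|r| = 0.6 and ≈ 0.79 at |r| = 0.5, so a screen of this size reliably
recovers strong correlates while genes at |r| ≈ 0.41–0.45 sit near the
detection limit — visible in the worked example, where 12 of 20 planted
genes survive the full cascade.

## Synthetic cohort

The generator defines the package's reference study conditions
(`src/tumorshape/data/default_config.yaml`); all randomness flows through a
single seeded generator, so outputs are byte-reproducible.

* **Diameters.** Per subtype, `a ~ lognormal` (median 2.1–2.7 cm, log-SD
  0.45) truncated to the (0, 10] cm inclusion range by rejection;
  `b = a·u₁`, `c = b·u₂` with independent `Beta` ratios, so the ordering
  constraint holds by construction.  Triple-negative tumors use Beta(8, 2)
  (mass near 1 → spherical), HR+ tumors Beta(4, 4), HER2+/HR− in between —
  giving mean SED ≈ 0.47 for triple negatives vs ≈ 0.86 for HR+ disease.
* **Nodal status.** `logit P(node+) = −2.0 + 1.5·SED + 0.2·a`, chosen so the
  node-positive fraction rises roughly 33 % → 47 % across SED tertiles at an
  overall rate near 40 %.
* **Survival.** Exponential event times at baseline 0.0015/month with
  log-hazard shifts of 0.4/0.8 for the Middle/High SED tertiles and modest
  subtype shifts (0, 0.2, 0.3, 0.3).  The subtype shifts are deliberately
  equal within HR− disease: triple-negative tumors concentrate in the
  low-SED tertile, so a large triple-negative hazard excess would exactly
  cancel the SED effect in marginal analyses and leave the planted
  association undetectable.  Censoring is exponential (0.006/month) with an
  administrative cap at 150 months, giving ≈ 20 % observed events.
* **Expression.** 2,000 genes × 41 samples.  Null genes are independent
  lognormal with per-gene dispersion spanning both sides of the CV = 1
  filter and abundances spanning mean = 10.  A planted gene with target r is
  `exp(σ·(ρ·z + √(1−ρ²)·ε))` around an anchored mean, where `z` is the
  standardized SED vector; because exponentiation attenuates the correlation
  while heavy-tailed noise inflates the finite-sample estimate, ρ is
  calibrated per gene by root-finding on the **expected sample correlation**
  (estimated from 400 fixed noise draws at generation time).  Realized mean
  r is unbiased to within ±0.01 of target at n = 41.

Effect sizes (node model, hazard shifts) are model assumptions chosen to
reproduce the qualitative clinical gradients; no published values exist for
them.  Features of real data the generator does **not** emulate: tumor size
is independent of shape within a subtype (so the size-by-SED-tertile
gradient seen in real cohorts is absent — the subtype size differences in
fact weakly reverse it); FPKM marginals are exactly lognormal with no
gene–gene correlation structure; hazards are exponential (constant over
time).  Passing tests therefore validate the statistical machinery and the
planted structures, not distributional realism of breast-cancer data.

## Simulation sizes and numerical choices

End-to-end checks run at sizes chosen to keep Monte-Carlo error well inside
the asserted tolerances: type-I error of log-rank and ANOVA at 2,000 null
replicates against a [0.04, 0.06] band; Cox log-HR recovery (truth 0.7,
n = 500) over 200 replicates within ±0.1; screen false-positive rate over
20 replicates of 2,000 null genes within ±0.0025 of 1 %; planted-gene
recovery at |r| = 0.6 over 200 replicates above 90 %.  SED range checks use
10,000 random triples.  Covariates are centered before Cox fitting and
linear predictors clipped at ±500 for numerical stability; quantile
computation uses `inverted_cdf` throughout for exact reproducibility.

## Known limitations

The cohort-level published results this design mirrors (actual patient
medians, survival curves, the specific gene list) are not reproducible —
the underlying hospital and RNA-seq data are not deposited — so the
end-to-end evidence here is property-based: operating characteristics of
each statistical engine plus qualitative reproduction of the planted
structure.  The screen's per-gene sample handling assumes a single shared
cohort (no per-gene exclusions), and the Cox stage implements Breslow ties
only.
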