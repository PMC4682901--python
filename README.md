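# tumorshape

Three-dimensional tumor morphometry from pathologic diameters: ellipsoid-family
volume estimators, the **spheroid–ellipsoid discrepancy (SED)** eccentricity
statistic, and the clinical and transcriptomic analyses built on it — subtype
association, distant-metastasis-free survival, and a gene-expression
correlation screen.

## The problem

Breast-cancer staging uses the single largest tumor diameter, which implicitly
treats the tumor as a sphere.  Pathology reports, however, record all three
diameters `a ≥ b ≥ c` (cm), supporting four volume estimators of the
ellipsoid family:

| estimator | formula | uses |
|---|---|---|
| spheroid (STV) | 4/3·π·(a/2)³ | a only |
| oblate | 4/3·π·(a/2)²·(b/2) | a, b |
| ellipsoid (ETV) | 4/3·π·(a/2)·(b/2)·(c/2) | a, b, c |
| prolate | 4/3·π·(a/2)·(c/2)² | a, c |

The proportional gap between the single-diameter and full-ellipsoid estimates,

```
SED = (STV − ETV) / STV = 1 − b·c / a²
```

is a dimensionless measure of how far the tumor departs from a sphere: 0 for
`a = b = c`, approaching (never reaching) 1 for flat or elongated tumors.
The package computes these quantities and carries SED through the downstream
epidemiological pipeline: four-way molecular subtype classification
(HR ± / HER2 ±, with ER/PR positivity at the 10 % staining cut-off),
cohort-wide SED tertiles, contingency and ANOVA association tables, Kaplan–
Meier / log-rank / Cox survival analysis (Breslow ties, Newton–Raphson), and
a gene-by-gene Pearson screen of FPKM expression against SED with the filter
cascade `p < 0.01`, `mean > 10`, `CV > 1`.

Because no patient-level data are distributed, a seeded synthetic-cohort
generator (`tumorshape.simulate`) produces clinical, survival, and expression
data with the same statistical structure — triple-negative tumors most
spherical, node positivity rising across SED tertiles, an SED-dependent
hazard of distant metastasis, and expression genes planted at calibrated
correlation strengths — so every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # 2,250 patients + 41-sample FPKM matrix
python analysis/02_morphometry.py
python analysis/03_shape_associations.py
python analysis/04_survival_analysis.py
python analysis/05_expression_screen.py
```

`02_morphometry.py` prints the estimator comparison (cm³):

```
              median    mean     std
spheroid_tv    5.883  14.791  26.852
oblate_tv      3.345   9.125  18.618
ellipsoid_tv   1.018   4.326  12.333
prolate_tv     0.558   3.231  10.552
sed            0.817   0.751   0.205
```

The single-diameter spheroid estimate runs ~3–6× above the full ellipsoid
estimate, and 18.0 % of patient pairs change order between the
longest-diameter and ellipsoid-volume rankings — the volume definition is not
merely a rescaling.  `03_shape_associations.py` shows the node-metastasis
gradient across SED tertiles (counts with column percentages, χ² p):

```
All  node_positive   253 (33.7%)   316 (42.1%)   355 (47.3%)   p = 4.6e-07
```

`04_survival_analysis.py` tests the planted SED–hazard structure
(global log-rank p = 5.5e-04 over all patients; 5.3e-03 within
hormone-receptor-negative patients; multivariate Cox HR 1.60 for High-vs-Low
SED), and `05_expression_screen.py` runs the correlation screen on the
41-sample matrix: 22 candidate genes pass all three filters, recovering 12 of
the 20 planted genes — the weaker plants (|r| ≈ 0.41–0.45) sit near the
detection limit at n = 41, which is the scientifically expected behaviour.

The same machinery is importable directly:

```python
from tumorshape import normalize_dimensions, sed
dims = normalize_dimensions(1.8, 3.1, 2.4)   # sorted to a >= b >= c
print(sed(dims).sed)                          # 0.55046...
```

or from the command line (`tumorshape simulate|morpho|associate|survival|screen|run-all`).

## Layout

- `src/tumorshape/` — the library: `morphometry`, `cohort`, `survival`,
  `screen`, `simulate`, `io`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — unit, property (hypothesis), and end-to-end acceptance tests
- `docs/methods.md` — model assumptions, parameter choices, limitations
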