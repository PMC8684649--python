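# munophen

Adiposity-index discrimination of the **metabolically unhealthy nonobese
(MUNO)** phenotype in maintenance-hemodialysis cohorts.

Nonobese dialysis patients (BMI < 25 kg/m²) are often metabolically
unhealthy, and simple visceral-obesity surrogates computed from
anthropometry and fasting lipids are candidate screening tools for that
phenotype. `munophen` implements the full analysis a nephrology
epidemiology study of this question needs, as a tested, reusable library:

* **Seven adiposity indices** per patient, with the sex-specific published
  formulas:
  * BMI = weight / height² (kg/m²), WC (cm), WHtR = WC / height
  * LAP = (WC − 65) × TG for men, (WC − 58) × TG for women
  * VAI = WC/[39.68 + 1.88·BMI] × TG/1.03 × 1.31/HDL (men);
    WC/[36.58 + 1.89·BMI] × TG/0.81 × 1.52/HDL (women)
  * CVAI = sex-specific linear score in age, BMI, WC, log₁₀TG, HDL-C
  * ABSI = WC(m) / (BMI^{2/3} · height^{1/2})
* **Rule-based MUNO classification**: BMI < 25 plus ≥ 2 of the four
  metabolic-syndrome components (BP ≥ 130/85 or antihypertensives;
  TG ≥ 1.7 mmol/L; HDL-C < 1.0 (men) / < 1.3 (women) mmol/L or
  lipid-lowering drugs; FPG ≥ 5.6 mmol/L or antidiabetic treatment).
* **Group descriptives** — median (IQR), Mann–Whitney U (tie-aware exact
  enumeration for small groups, continuity-corrected normal otherwise),
  Pearson chi-square.
* **Quartile logistic regression** — per-index quartile indicators versus
  the lowest quartile, adjusted for age, sex, education and smoking; odds
  ratios with 95% Wald CIs from an IRLS maximum-likelihood fitter with
  explicit separation diagnostics.
* **Sex-stratified ROC analysis** — empirical ROC curves, trapezoidal AUC
  (provably equal to the Mann–Whitney pair statistic), DeLong variance and
  95% CI, Youden-optimal cutoffs, and **paired DeLong tests** comparing
  correlated AUCs on the same subjects.
* **A seeded synthetic cohort generator** (Gaussian copula over lognormal
  marginals, medication flags via logistic links, a calibrated MUNO
  prevalence knob, and "separability scenarios" with a designated dominant
  index) so that every pipeline stage is testable without patient data.

## Worked example

```python
from munophen import GeneratorConfig, generate_cohort, MunoStudy

cohort = generate_cohort(GeneratorConfig(n=1302, seed=1))
results = MunoStudy(cohort).fit()
print(results.summary())
```

prints (abridged):

```
MUNO discrimination study
============================================================
Cohort: synthetic seed=1 n=1302
Input records: 1302   analysed: 1195   excluded: 107 {'vintage_le_3': 1, 'bmi_ge_25': 106, 'missing_mandatory': 0}
Phenotype: 753 MUNO / 1195 eligible (63.0%)  [complete-case analysis]

AUC by sex stratum (Youden-optimal cutoff):
  female  vai   AUC 0.87 (0.84-0.90)  cutoff 2.02  sens 0.70  spec 0.93  J 0.63
  female  lap   AUC 0.79 (0.75-0.83)  cutoff 30.89  sens 0.59  spec 0.89  J 0.48
  ...
  male    vai   AUC 0.86 (0.83-0.88)  cutoff 1.53  sens 0.73  spec 0.85  J 0.58

Adjusted OR (95% CI) per quartile vs Q1:
  vai   Q2 2.69 (1.89-3.82)  Q3 12.75 (8.59-18.93)  Q4 227.57 (81.62-634.53)
  lap   Q2 1.98 (1.42-2.77)  Q3 3.86 (2.72-5.48)  Q4 25.49 (15.12-42.97)
  ...
```

Reading it: of 1302 generated patients, 107 fail eligibility (dialysis
vintage ≤ 3 months or BMI ≥ 25); 63.0% of the eligible cohort meets the
MUNO rule. VAI separates MUNO from MHNO best in both sexes (AUC ≈ 0.86),
LAP second, while BMI/WC/WHtR/ABSI sit near 0.61–0.66 — and the adjusted
odds of MUNO rise steeply across VAI quartiles. `results.table1` …
`results.table4` hold the full tables as DataFrames;
`results.plot_roc("male")` draws the ROC curves.

The same run is available from the shell:

```bash
munophen generate --n 1302 --seed 1 --out cohort.csv
munophen analyze cohort.csv --out out/
munophen run-all --config run.yaml      # YAML: seed, n, output_dir, ...
```

Outputs are deterministic given (config, seed): tables as CSV (2-decimal
presentation plus full-precision copies), ROC coordinates, and a
`manifest.json` whose per-stage record counts telescope.

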