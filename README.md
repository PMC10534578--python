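# asgo

Scoring and psychometric validation of the **ASGO** (General Assessment of
the Hospitalised Patient), a weighted 10-variable checklist of non-medical
functions used to profile the functional dependence of hospitalised adults,
against the **Barthel Index** (BI), the standard 0–100 activities-of-daily-
living scale.

The package is aimed at nursing-research and health-services analysts who
need to (a) score ASGO and BI assessments reproducibly, and (b) run the
full concurrent-validity workup of a weighted ordinal instrument against a
gold standard: rank correlation, internal consistency, optimal cut-off,
ROC discrimination and factor structure.

## The score and the statistics

Each ASGO variable `v` has a weight `w_v` (Σ w_v = 10) and up to seven
ordered modalities; the modality at level `l` contributes a ranking value
`w_v·l`. An assessment is scored as

    raw score = Σ selected ranking values            (10.0 – 70.0 single-select)
    FD index  = raw score / 10                       → care profile bands

Four variables (circulation, feeding, elimination/sphincter control,
sensory system) allow several simultaneous modalities, combined by
summation. Dependence is classified by `raw score ≥ cutoff`; the BI is
dichotomised at ≥ 60 = independence.

The validation pipeline computes, per timepoint (admission/discharge):
Spearman's rho between ASGO and BI, Cronbach's α, the Youden-optimal
cut-off (max J = sensitivity + specificity − 1), the dependence confusion
table with sensitivity/specificity, and the ROC curve with trapezoidal
AUC; and, cohort-wide: KMO sampling adequacy, Bartlett's sphericity test,
and PCA-based exploratory factor analysis with varimax rotation and Kaiser
retention. All statistics are implemented from first principles in
`asgo.psychometrics` and are cross-checked in the test suite against
independent oracles (scipy, scikit-learn, pingouin, closed-form
arithmetic).

Because no patient data ship with the package, `asgo.cohort` generates
synthetic paired cohorts with the assumed structure — a latent dependence
trait driving both instruments inversely (configurable target rho per
timepoint) and a planted two-factor item structure (physical functionality
vs sensory behaviour). See `docs/methods.md` for the generative model and
all numerical conventions.

## Worked example

```bash
asgo simulate --out cohort.csv --seed 42 --n 842
asgo validate --input cohort.csv --out report --cutoff 22.5
```

`report/report.md` then starts:

```
Patients: 842 (842 paired) — cut-off 22.50 (fixed), EFA on admission assessments, weighted item values.

## Correlation and descriptives

| Timing    | ASGO mean (SD) | BI mean (SD) | Spearman rho | p      |
|-----------|----------------|--------------|--------------|--------|
| admission | 28.7 (12.0)    | 41.7 (26.5)  | -0.59        | <0.001 |
| discharge | 24.5 (11.8)    | 51.4 (29.0)  | -0.81        | <0.001 |
```

Reading the numbers: the two instruments correlate negatively (higher ASGO
= more dependent, higher BI = more independent), more tightly at discharge
(rho −0.81) than at admission (−0.59), exactly the coupling the generator
was configured for; the mean ASGO falls and the mean BI rises between
timepoints because patients improve on average. The same run reports
discrimination of BI-defined dependence by the ASGO score (AUC 0.78 at
admission, 0.90 at discharge for this seed), KMO 0.91 with Bartlett
χ² ≈ 2543 (p < 0.001), and a two-factor varimax solution assigning the six
physical-functionality items to factor 1 and the four sensory-behaviour
items to factor 2 (`report/loadings.csv`). Full-precision values are in
`report/report.json`; ROC point sets in `report/roc_admission.csv` /
`report/roc_discharge.csv`.

The same operations are available as library calls:

```python
from asgo import CohortConfig, generate_cohort, run_validation

records = generate_cohort(CohortConfig(seed=42))
report = run_validation(records)
print(report.admission.spearman_rho, report.discharge.auc)
```

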