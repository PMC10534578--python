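# Methods

## The instrument and its score

The ASGO (General Assessment of the Hospitalised Patient) profiles a
hospitalised adult on ten non-medical functions: mental status,
movement/ambulation, circulation, breathing, elimination/sphincter control,
feeding, sleep/wake, sensory system, self-care ability and prevailing mood.
Each variable carries a priority weight `w_v` (the ten weights sum to 10)
and offers up to seven ordered modalities; the modality at level `l`
contributes a *ranking value* `w_v × l`. An assessment selects one modality
per variable — except circulation, feeding, elimination/sphincter control
and the sensory system, which may carry several simultaneously.

The package scores an assessment as

    raw score  = Σ selected ranking values          (range 10.0 – 70.0 single-select)
    FD index   = raw score / 10                      (functional-dependence index)

and maps the FD index to a care profile: minimum [1.0, 2.6), medium
[2.6, 3.7), high [3.7, 4.8), maximum [4.8, ∞). Three scale conventions are
deliberate design choices:

* **Multi-select combination.** The instrument definition does not state how
  simultaneous modalities combine. The default is to *sum* their ranking
  values, because the scale measures cumulative commitment to support needs
  and summation preserves additivity and strict monotonicity. `combine="max"`
  is available for sensitivity analysis.
* **Band edges.** The printed care-profile bands leave gaps (e.g. between
  2.59 and 2.6). Bands are implemented as left-closed, right-open intervals
  with the minimum band extended down to the analytic floor of 1.0, giving
  exhaustive, non-overlapping coverage while preserving the printed interior
  edges 2.6 / 3.7 / 4.8.
* **Movement/ambulation** is encoded with exactly its six published
  modalities at levels {1, 2, 3, 4, 5, 7}; no seventh value is invented.

The Barthel Index (BI) is the comparison standard: ten activities-of-daily-
living items on the classic 0/5/10/15 allocation (15-point transfer and
walking; 10-point feeding, toilet use, dressing, bowel, bladder, stairs;
5-point bathing and grooming), total 0–100, dichotomised at ≥ 60 =
independence. ASGO dependence classification uses `raw score ≥ cutoff`, with
ties at the cut-off classed as dependent.

## Psychometric statistics

All validation statistics are implemented from first principles in
`asgo.psychometrics` (numpy linear algebra; scipy only for t and chi-square
tail areas). Key numerical conventions:

* **Spearman rho** is the Pearson correlation of midranks (ties averaged).
  The two-sided p-value uses the t approximation
  `t = rho·sqrt((n−2)/(1−rho²))` on `n−2` df; for `n ≤ 10` an exact
  permutation p-value is computed by full enumeration instead.
* **Cronbach's alpha** uses sample (n−1) variances:
  `alpha = (k/(k−1))(1 − Σ s²_item / s²_total)`.
* **ROC curves** place one candidate threshold per unique observed score
  plus ±∞ sentinels, under the `score ≥ threshold → dependent` rule.
  Midpoint threshold placement (halfway between adjacent unique scores) is
  available via `roc_midpoint=True` but is off by default. AUC is the
  trapezoidal area, which equals the Mann–Whitney concordance probability
  with ties counted ½.
* **Youden cut-off** maximises `J = sensitivity + specificity − 1`; ties on
  J resolve to the smallest threshold (the most sensitive choice).
* **KMO** is `Σr²/(Σr² + Σq²)` over off-diagonal entries with anti-image
  partials `q_ij = −s_ij/√(s_ii s_jj)`, `S = R⁻¹`; **Bartlett's test** is
  `χ² = −(n − 1 − (2p+5)/6)·ln det R` on `p(p−1)/2` df.
* **EFA** is the eigendecomposition of the sample correlation matrix
  (loadings = eigenvector × √eigenvalue); factors are retained by the strict
  Kaiser rule (eigenvalue > 1).
* **Varimax** uses iterative pairwise Jacobi plane rotations with Kaiser row
  normalisation on, convergence when the criterion improves by < 1e−8,
  a cap of 1000 sweeps (exceeding it raises an error carrying the criterion
  trace), column signs fixed so each column's largest-magnitude loading is
  positive, and columns ordered by explained variance. Row communalities
  are preserved to 1e−10 by construction.

Raw two-sided p-values are reported throughout; no multiple-testing
correction is applied, and no confidence intervals are produced for AUC or
rho.

## Synthetic cohort generator

No patient data ship with the package; `asgo.cohort` generates a cohort
with the structure the validation assumes. Per patient:

1. A latent dependence trait `D_adm ~ N(0,1)`; at discharge
   `D_dis = D_adm + improvement_shift + N(0, innovation_sd²)`.
   `improvement_shift` is the mean latent-trait *change*, so a negative
   value (default −0.35) means patients improve, pushing mean ASGO down and
   mean BI up between timepoints.
2. Two latent factors per timepoint — physical functionality (mental
   status, movement, elimination, feeding, sleep, self-care) and sensory
   behaviour (circulation, breathing, sensory system, mood) — each
   `F_k = c_t·Z_t + sqrt(1−c_t²)·U_k` where `Z_t` is the standardised trait.
3. Item latents `x = λ'F + sqrt(1−λ'Φλ)·e` (unit variance by construction)
   are cut into ordinal modalities by equally spaced thresholds starting at
   −0.5 with step 0.5, chosen so the default mean raw score sits near 27 at
   admission. Multi-select variables add a second random modality with
   probability 0.1.
4. The BI total is `40 − 27·D_t` plus `N(0, 10²)` noise, clipped to
   [0, 100], snapped to the 5-point lattice and decomposed across the ten
   items so the item sum equals the total exactly.

**Coupling calibration.** The per-timepoint coupling `c_t` is solved from
the target Spearman rho by inverting `|rho| = η·K(c)·r_B`, where `K(c)` is
the analytic correlation between the continuous weighted item composite and
the trait, `r_B` the BI–trait correlation, and `η = 0.94` a frozen
attenuation constant absorbing ordinal discretisation, lattice snapping,
clipping and the rank transform. η was calibrated once by simulation (30
seeds at three target pairs spanning couplings 0.5–0.95; observed range
0.93–0.95) and is not data-dependent. Targets exceeding the feasible
ceiling `η·K(1)·r_B` raise a configuration error that reports the bound.

Defaults define the study conditions: 842 patients, target rho −0.59 on
admission and −0.79 at discharge, block loadings 0.65 (own factor) / 0.20
(cross). The loading magnitudes were chosen from the population eigenvalue
analysis of the implied correlation matrix so that exactly two eigenvalues
exceed 1 and the two retained components explain roughly half the variance,
matching the qualitative structure the instrument is expected to show; they
were fixed before any acceptance run. Demographics (age 76.4 ± 12.3, 55%
male, stay 20.1 ± 13.4 days, eight admission-reason categories) are
decorative — no statistic uses them.

Randomness is counter-based: each patient's draws come from a Philox stream
keyed by (root seed, patient index), so record *i* is bit-identical
whatever the cohort size.

**What the generator does not emulate:** ward-level clustering, mortality
or length-of-stay dynamics, informative missingness (the optional
pairing-loss mechanism is missing-completely-at-random), rater effects, and
floor/ceiling artefacts of real BI scoring. Passing tests therefore show
that the pipeline recovers planted structure of this kind, not that the
instrument behaves identically on real hospital data.

## Pipeline conventions

* The classification cut-off is the configured value when given; otherwise
  the Youden-optimal cut-off computed on admission scores is applied at both
  timepoints (a single cut-off across timepoints mirrors how such an
  instrument is used clinically). The mode is logged in the report header.
* The EFA runs on admission assessments by default (options: discharge,
  pooled), on the matrix of per-variable summed ranking values (option:
  raw levels). Cronbach's alpha uses the same item matrix per timepoint.
* Paired statistics use listwise exclusion; descriptives are reported both
  for all rows and for the paired subset, labelled.
* Degenerate inputs degrade gracefully: a timepoint with a single BI class
  has its ROC/cut-off block marked unavailable; a rank-deficient item matrix
  marks the factor block unavailable; the rest of the report is computed.
* The JSON report is deterministic — keys sorted, floats at 6 significant
  digits — so identical input and config give byte-identical output.
  Rendered Markdown tables round to the conventional two decimals for
  rho/alpha/sensitivity/specificity and one for means and SDs.

## Problem sizes used in the test suite

Unit tests run on hand-sized fixtures and a shared 120-patient cohort; the
full-scale checks use 842-patient cohorts across 50 seeds (correlation and
AUC ordering) and 20 seeds (factor-structure recovery), sizes chosen to
estimate the relevant means and proportions precisely while keeping the
default suite quick to run.

## Known limitations

* The exact-permutation Spearman p-value enumerates up to 10! orderings;
  it is intended for the tiny samples where it applies.
* KMO and Bartlett require a positive-definite correlation matrix; highly
  collinear item sets are rejected rather than regularised.
* The coupling inversion assumes the default equally spaced thresholds;
  strongly skewed custom thresholds may shift the realised rho by more than
  the calibrated attenuation accounts for.
* Only orthogonal (varimax) rotation is provided; no oblique rotations, no
  maximum-likelihood or principal-axis factoring.
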