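# dyntac

Dynamic-PET time-activity-curve (TAC) kinetics and survival-based risk
stratification, end to end on fully synthetic cohorts:

1. **`dyntac.synthetic_cohort`** — synthetic dynamic-PET cohorts with known
   ground truth: a Feng-style bolus input function, two-tissue-compartment
   (2TC) tissue kinetics for tumor and bone-marrow ROIs on a 28-frame /
   65-min schedule, frame-duration-dependent Gaussian noise, and
   progression-free-survival times whose hazard depends log-linearly on the
   true bone-marrow free-tracer 10–30 min slope.
2. **`dyntac.kinetics`** — forward 2TC simulation (exact exponential
   integrator for piecewise-linear inputs), weighted bounded multi-start
   nonlinear least-squares fitting, and decomposition of a measured TAC into
   blood / free / metabolized components.
3. **`dyntac.features`** — the six TAC feature operators (10–30 min slope,
   trapezoid AUC, rise and washout slopes, peak time, peak value) applied to
   the decomposed components: 14 features per ROI, 28 per patient, plus
   conventional SUV/MTV/TLG metrics from voxel SUV arrays.
4. **`dyntac.selection`** — bootstrap-LASSO-Cox stable feature selection
   (5-fold CV, 1-SE rule, frequency > 50%), multivariate Cox modelling,
   optimism-corrected Harrell C-index, Schoenfeld proportional-hazards tests.
5. **`dyntac.stratify_eval`** — log-rank optimal-cutoff stratification,
   Kaplan–Meier curves, cumulative/dynamic time-dependent ROC, IPCW Brier
   score and calibration slope/intercept, survival decision-curve analysis,
   and the two-group comparison battery (Shapiro–Wilk gate, t /
   Mann–Whitney, Fisher exact).
6. **`dyntac.pipeline` / `dyntac.cli`** — orchestration, CSV/JSON dialects,
   reproducible manifests.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the heavier property-based acceptance
criteria (oracle equivalences, Monte-Carlo calibration of the statistical
tests, replicate selection-stability experiments, an end-to-end multi-cohort
run); the rest of the suite is fast unit/property tests.

## CLI

```sh
# generate a 32-patient synthetic cohort (TAC CSV + cohort CSV + truth sidecar)
dyntac simulate --n 32 --seed 1 --out out/cohort

# fit the 2TC model to every tissue TAC
dyntac fit --tacs out/cohort/tacs.csv --out out/fits.json

# full pipeline: simulate -> fit -> features -> select -> stratify -> evaluate
dyntac run-all --seed 1 --out out/run1
```

`run-all` writes `features.csv`, `selection.csv`, `report.json` (selection
frequencies, Cox summary, optimism-corrected C-index, optimal cutoff,
log-rank result, time-dependent AUCs, calibration, net-benefit table) and a
`manifest.json` whose config hash + seed reproduce the report exactly.

## File dialects

- **TAC CSV** — `patient_id, roi, frame_start_s, frame_end_s,
  activity_kbq_per_ml`; `roi ∈ {tumor, bone_marrow, blood}`. Tissue rows use
  the 28-frame schedule (6×10 s, 4×30 s, 4×60 s, 4×120 s, 10×300 s; 3900 s
  total); blood rows use a fine 2-s binning so the bolus peak survives
  serialization.
- **Cohort CSV** — `patient_id, <covariates...>, pfs_days, event` with
  `event ∈ {0, 1}` (1 = progression/death).
- **Feature CSV** — one row per patient; 28 kinetic features in a frozen
  canonical order, then 8 conventional features, then clinical covariates.
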