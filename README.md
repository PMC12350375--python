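# alcsofa

Severity scoring for sepsis cohorts that extends the six-system SOFA
organ-dysfunction score (0–24) with a lymphocyte-count immune component
(0–4), giving a combined ALC-SOFA total of 0–28, together with the full
validation pipeline used to compare the two scores:

- **`alcsofa.cohort`** — patient-level domain types and CSV I/O with fixed
  units and explicit missingness (empty cell = absent, never 0).
- **`alcsofa.scoring`** — the six SOFA component scorers, the lymphocyte
  score, and the combined total, with documented band closures for every
  printed cutoff gap.
- **`alcsofa.filters`** — the sequential exclusion cascade (repeat
  admissions, undeterminable 28-day status, age < 18, ICU stay ≤ 24 h,
  missing lymphocyte count, Tukey's-fences outliers) with an attrition log.
- **`alcsofa.discrimination`** — AUROC (Mann–Whitney form), the DeLong
  paired test for correlated AUROCs, logistic risk calibration, continuous
  NRI, IDI, percentile bootstrap CIs, and Youden operating points.
- **`alcsofa.survival`** — Kaplan-Meier curves, log-rank tests across
  5-point score classes, horizon mortality, and univariate→multivariate
  Cox screening (covariates entering at p < 0.05; Breslow ties).
- **`alcsofa.synthetic`** — a calibrated sepsis-like cohort generator with
  known ground truth (correlated severity and immune axes; band-inverted
  raw measurements so re-scoring reproduces the intended sub-scores).
- **`alcsofa.pipeline`** / **`alcsofa.cli`** — orchestration
  (filter → score → evaluate) and a deterministic JSON report.

## CLI

```sh
# generate a synthetic cohort calibrated to realistic sepsis marginals
alcsofa simulate --n 10000 --seed 1 --params params/default.yaml \
    --out cohort.csv --truth truth.csv

# exclusion cascade with attrition log
alcsofa filter --in cohort.csv --out kept.csv --attrition attrition.json

# append score breakdown columns
alcsofa score --in kept.csv --out scored.csv

# full evaluation: AUROCs, DeLong, NRI/IDI with bootstrap CIs,
# operating points, KM classes, subgroups
alcsofa evaluate --in cohort.csv --horizons 7,28,90 --boot 1000 --seed 1 \
    --subgroup-col age_gt_65 --out report/

# everything from a YAML config
alcsofa run --config config.yaml
```

Identical config + seed produces a byte-identical `report.json`.

## Input format

CSV with a header row; canonical columns are listed in
`alcsofa.cohort.CANONICAL_COLUMNS` (a schema map can rename them). Units
are fixed: bilirubin/creatinine mg/dL, platelets ×10³/µL, lymphocyte count
×10⁹/L, vasopressor doses µg/kg/min, survival time days. Any extra column
is carried as a named covariate (usable in Cox screening and subgroups).
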