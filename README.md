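# voltgrade

Cyclic-voltammetry feature engineering and machine-learning grading for
electrochemical tumor-biomarker immunosensors, built around a canine
mammary-tumor application: a sensor detecting CA 15-3 (serum) and MUC-1
(tissue) whose current–potential curves, recorded from −0.05 V to −0.45 V
at 50 mV/s, carry a redox peak that grows with biomarker concentration
over a 5–100 U/mL linear range.

The package is aimed at electroanalytical and veterinary-oncology groups
who want the full computational chain as tested, reusable code:

* **synthetic data** — seeded generators for voltammograms (linear
  baseline + Gaussian redox peak + noise, concentration-dependent
  amplitude) and clinical cohorts with tunable variable↔grade coupling;
* **feature extraction** — fourteen descriptors per trace: charge Q,
  half-peak potential, peak width at half height, mean/median/SD of
  current, skewness, excess kurtosis, first/second derivative extrema,
  positive/negative peak currents and potentials;
* **clinical statistics** — the packaged 17-case + 1-control cohort and
  its Spearman rank-correlation analysis against histological grade
  (tie-averaged ranks; two-sided p from t = ρ·√((n−2)/(1−ρ²)) on n−2 df);
* **feature ranking** — Spearman correlation with grade and normalized
  random-forest importance, with strict-threshold selection (default 0.08);
* **model benchmark** — leave-one-out cross-validated random forest,
  XGBoost, LightGBM and feed-forward network, scored by pooled
  confusion-matrix accuracy/precision/recall/F1;
* **calibration** — OLS dose–response fit, LOD = 3.3·σ/slope,
  area-normalized sensitivity, selectivity ratio.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import voltgrade as vg

# published cohort: correlation of clinical variables with grade
records = vg.load_packaged_cohort()
print(vg.correlation_table(records))
```

```
              rho  p_value   n label
location    0.512    0.036  17     +
size        0.622    0.008  17    ++
lymph_node  0.069    0.792  17    NS
lung        0.410    0.102  17    NS
muc1       -0.193    0.457  17    NS
```

Tumor size (T stage) and mammary-lobe location correlate significantly
with histological grade in this cohort; lymph-node status, lung metastasis
and the MUC-1 IHC score do not. The same numbers are available from the
shell via `voltgrade clinical table3`.

```python
# synthetic end-to-end: simulate, extract features, rank, benchmark
traces, labels = vg.simulate_labeled_dataset(vg.grade_class_specs(), 10, seed=1)
frame = vg.extract_feature_matrix(traces, labels)
imp = vg.rf_importance(frame.drop(columns="label"), frame["label"], seed=1)
print(vg.select_features(imp, 0.08))
```

```
['charge_Q', 'std_current', 'positive_peak_current', 'mean_current',
 'median_current', 'skewness']
```

On this synthetic run the amplitude-linked descriptors (charge, peak
current, current moments) dominate the forest's importance and clear the
0.08 selection threshold — the expected outcome when class signal enters
through the dose–response amplitude.

A full pipeline run (`voltgrade run config.yaml`) writes feature matrices,
importance tables, model reports and a manifest with per-stage seeds and
output checksums; identical configs produce bit-identical runs.

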