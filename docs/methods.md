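# Methods

## Scope and model of the data

`voltgrade` implements the computational chain from raw cyclic-voltammetry
(CV) curves of an electrochemical immunosensor to tumor-presence and
tumor-grade predictions for canine mammary tumors, plus the clinical
rank-correlation analysis of the accompanying 17-case cohort. The sensor
detects CA 15-3 (serum) and MUC-1 (tissue homogenate); its response is a
current–potential curve recorded over −0.05 V to −0.45 V at a 50 mV/s scan
rate, with a redox peak whose amplitude grows with biomarker concentration
over a 5–100 U/mL linear range.

The raw instrument curves behind the original study are not publicly
available. The package therefore separates what can be recomputed exactly —
the clinical cohort analysis, whose inputs are fully transcribed in the
packaged fixture — from what can only be supported behaviourally, via a
synthetic-data generator that emulates the statistical structure the
analysis assumes.

## Synthetic voltammograms

A simulated sweep is

```
I(E) = b0 + b1·E + A·exp(−(E − E0)² / 2σ²) + ε,   ε ~ N(0, s²) i.i.d.
```

a linear capacitive baseline plus a single Gaussian faradaic peak plus
white noise, sampled on a uniform potential grid (default 256 points,
−0.05 → −0.45 V, one sweep branch). This is the simplest signal model that
makes all fourteen engineered descriptors non-degenerate. An exponentially
modified Gaussian peak (`peak_tau > 0`) is available so skewness and
kurtosis can carry class information; full two-branch cycles are out of
scope because every descriptor is branch-agnostic. No electrode kinetics
(Butler–Volmer, Randles–Ševčík) are modelled: the generator reproduces the
*shape* family of the curves, not the sensor physics, so passing tests
certify the feature extraction and modelling machinery, not the chemistry.

Concentration enters through a clamped linear dose–response
`A = a + b·c` for `c` inside the 5–100 U/mL window, saturating at the
boundaries (defaults `a = 0.05 µA`, `b = 0.004 µA·mL/U`, chosen to put
amplitudes in the sub-µA range typical of the instrument window).
Class labels (control, grade I–III) map to lognormal concentration
distributions with increasing means (2, 20, 45, 80 U/mL; CV 0.25) —
grade-dependent biomarker elevation is an empirical observation the
generator encodes, not a mechanism. A small multiplicative jitter
(default 5%) perturbs peak centre, width and baseline per trace so classes
differ by more than amplitude.

Synthetic clinical cohorts couple each categorical variable (lobe, T, N,
M, MUC-1 score) to grade through a Gaussian copula: latent score
`a·z_grade + √(1−a²)·ε` cut at the variable's marginal quantiles. Coupling
`a = 0` gives exact independence; `a → 1` gives strong monotone (rank)
association. Marginals mirror the packaged cohort's shape.

All generators are deterministic given their seed (bit-identical reruns).

## The fourteen descriptors

Per trace: signed charge (trapezoidal integral of current over time, time
reconstructed as |ΔE|/scan-rate); positive/negative peak currents and their
potentials (raw extrema); half-peak potential and peak width at half
height; mean, median, sample standard deviation (n−1), skewness and excess
kurtosis of the current samples (biased standardized-moment estimators,
Fisher convention); and the signed extrema of the first and second
derivatives of current with respect to potential (central differences,
one-sided at the ends; value taken at the argmax of the absolute
derivative, which is baseline-robust).

Half-height geometry requires a baseline, which instrument exports do not
carry: the package uses the straight line through the mean (E, I) of the
first and last 10% of samples. The *dominant* peak is the baseline-corrected
extremum of larger magnitude; the half-peak potential is the interpolated
half-maximum crossing on the flank preceding the peak in sweep order, and
the width spans the two crossings bracketing the peak (clamped to the sweep
ends if a flank never falls below half height). Flat traces yield flagged
zeros rather than errors so batch extraction survives a dead electrode.
Note the endpoint baseline biases half-height quantities when a peak's
tails reach the estimation windows; oracle tests therefore use peaks at
least ≈4σ from both sweep ends.

Closed-form oracles for the noiseless Gaussian fixture: charge
`A·σ·√(2π)/v`, FWHM `2√(2 ln 2)·σ`, maximum |dI/dE| `A·e^(−1/2)/σ`. The
extractor matches these within 0.5%, two grid steps, and 1% respectively
on a 4096-point grid.

## Clinical cohort analysis

The packaged fixture transcribes the published clinical/histopathology
tables: 17 tumour cases (age, breed, weight, staging string such as
`R5/T1N0M0`, histological grade I–III, superficial-inguinal-lymph-node
metastasis, MUC-1 IHC score 0–3) and one healthy control. A SHA-256
checksum guards the file; N stage and SILN status are cross-validated at
load.

Association with grade uses Spearman's rank correlation with tie-averaged
ranks (appropriate for ordinal, non-normal variables), with the two-sided
p-value from `t = ρ·√((n−2)/(1−ρ²))` on n−2 degrees of freedom. The
variable coding — lobe number (3/4/5), T stage (1/2), binary N and M,
MUC-1 score (0–3), grade (1–3) — and the t-approximation were fixed because
together they reproduce all five published coefficient/p-value pairs to
three decimals; an exact/Monte-Carlo permutation p-value is available for
small samples. The control animal is excluded (n = 17). Significance labels:
NS (p > 0.05), `+` (p ≤ 0.05), `++` (p ≤ 0.01).

Two documented quirks of the source tables: the "median age 11.17 ± 1.59"
figure equals the arithmetic mean ± SD of the listed ages (the median is
11.0) — the summary reports mean, SD and median; and the stated 54.5%
MUC-1 positivity rate is inconsistent with the 11-of-17 stained count the
same text gives — the summary reports the count, which is reconstructable.

## Feature ranking and selection

Two rankings: per-feature Spearman correlation against grade (constant
columns flagged `undefined`, never dropped), and normalized
mean-decrease-in-impurity importances from a random forest (500 trees,
seeded; permutation importance available as an option). Selection keeps
features whose importance *strictly exceeds* the threshold (default 0.08),
preserving rank order; selected sets are nested across increasing
thresholds. The published importance table ships as a fixture for
selection-logic tests only — its generating dataset is not available, so
no attempt is made to reproduce its values.

## Model benchmark

Four families: random forest (500 trees), XGBoost-backed gradient boosting
(200 rounds, depth 3, learning rate 0.1, exact split finding), LightGBM-
backed gradient boosting (same, `min_data_in_bin = 1`,
`min_child_samples = 2`), and a small feed-forward network (hidden layers
32/16, standardization fitted per training fold, early stopping off for
determinism). None of these hyperparameters were published; they are fixed
choices sized for tabular datasets of tens of samples. The two histogram-
related settings deserve note: on cohort-sized data, default quantile/
histogram split finding can place a threshold flush against (or inside) a
class cluster instead of mid-margin, misclassifying held-out boundary
points even on perfectly separated classes; exact splits (XGBoost) and
single-sample bins (LightGBM) remove that artefact.

Evaluation is leave-one-out cross-validation — with n ≈ 18 the only
defensible split — with all n held-out predictions pooled into a single
confusion matrix before scoring (per-fold metrics are degenerate for
single-sample folds). Accuracy, precision, recall and F1 follow the
standard confusion-matrix formulas; multiclass tasks macro-average
one-vs-rest precision/recall/F1; zero-denominator cases score 0 with a
flag. A class with a single member triggers a warning and its fold is
scored with the class absent from training, which is what leave-one-out
semantics dictate.

Because the study's own CV dataset is unavailable, its headline accuracies
are not reproduction targets. The benchmark is instead certified
behaviourally under three fixed synthetic conditions (`voltgrade.benchmarks`):

* **Separable presence task** (n = 40: 20 control at 2 U/mL, 20 tumor at
  90 U/mL, no dose scatter, low noise): every family must reach pooled
  LOOCV accuracy 1.0; a z-scored nearest-centroid classifier certifies
  separability independently of the model families.
* **Label-permutation null** (n = 30, three balanced grades, 50 label
  shuffles): no family's mean accuracy may exceed chance (1/3) + 3 standard
  errors, and each mean must sit within ±0.1 of chance. Reduced-size
  models (`null_model_specs`) are used here — chance-level behaviour does
  not depend on ensemble size, and the null repeats the full benchmark 50
  times; n = 30 is likewise the deliberate problem size for this
  calibration.
* **Three-grade task** (n = 60, overlapping lognormal doses, default
  noise): the nearest-centroid reference must clear 70% pooled accuracy
  (certifying the dataset carries that much signal) and the best family
  must do at least as well.

## Calibration figures of merit

Ordinary least squares on (concentration, response) panels with ≥3 distinct
concentrations; R² is the standard coefficient of determination. A flat
response returns a flagged degenerate fit (slope 0, R² 0, infinite LOD)
rather than raising. LOD follows the 3.3·σ_blank/slope convention (ICH
Q2), multiplier configurable (3.0 option); when blank replicates are
absent, σ falls back to the fit's residual standard error and the source
is recorded. Area-normalized sensitivity is slope/electrode-area (default
2 cm², the working electrode used with this sensor). Selectivity is
|target response| / mean |interferent responses| — the simplest definition
consistent with quoting one selectivity value per analyte; it is not an
IUPAC-standard quantity and should be read comparatively. The source
study's LOD units are stated once in U/mL and once in μM with the same
digits; the package computes LOD in the slope's own concentration units
and leaves that clash unresolved.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline runner fans
a single run seed out to fixed per-stage offsets so stages can be rerun
independently, and writes a manifest (config echo, package version, stage
seeds, SHA-256 of every output). `scripts/acceptance.py --seed N --out f`
recomputes the headline quantities end to end.

## Known limitations

* The synthetic generator reproduces curve shapes, not electrochemistry:
  no capacitive/faradaic current decomposition, no scan-rate dependence of
  peak position, no multi-peak chemistry, no inter-electrode drift.
  Benchmark results on it certify the software, not sensor performance.
* The concentration axis is treated as a single abstract dose (the source
  material mixes U/mL and cells/mL); no unit conversion is attempted.
* Published model accuracies (98/96/95/97% presence; 76%/62% grade) and
  the printed importance/correlation tables are not reproducible without
  the undeposited raw dataset; they appear only as fixtures for schema and
  selection-logic tests.
* With 17 tumours vs 1 control, presence accuracies that are not multiples
  of 1/18 cannot arise from a single pooled LOOCV pass; the package reports
  exact fractions only.
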