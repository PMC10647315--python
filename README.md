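# lrtrend

Longitudinal radiomic trend analysis for treatment-response prediction from
daily in-room imaging.

## The problem

Patients receiving fractionated radiotherapy (e.g. for locally advanced
rectal cancer) are imaged with cone-beam CT before every daily treatment
fraction. Radiomic features extracted from the tumour region of each scan
form, per patient, a multivariate time series over the course (typically 28
fractions). Single-time-point radiomic values are notoriously sensitive to
image quality, but their *trend* across the course is far more robust — and
it is the trend that carries the early signature of whether the tumour is
responding. `lrtrend` implements the full analysis chain for this setting:
registration-consistency QC, per-patient normalization, per-feature trend
fitting, feature screening, two classifiers, and a cross-validated
consistency audit that asks how early in the course the response call
stabilizes.

## The model

For patient-specific feature series RF_ij (feature *i*, fraction X_j),
each series is first z-scored with the patient's own series mean and
sample sd, with |z| bounded at 3. A linear trend is then fitted by
ordinary least squares:

    RF_ij = LRT_i · X_j + β_i

where LRT_i (the *longitudinal radiomic trend*) is the slope and β_i the
intercept. Each (patient, feature) pair is reduced to the trend statistic

    LRTF_i = LRT_i + β_i

(the fitted value at the first fraction), plus a fit error ERR_i (mean
absolute residual). Features whose LRTF differs between responders and
non-responders (two-sided Mann–Whitney U-test, p < 0.05; optional
univariate logistic LOOCV filter at accuracy ≥ 0.7) feed two classifiers:

* a **random forest** whose score is the predicted responder probability;
* an interpretable **statistical-weight (SW) model**: each retained LRTF is
  weighted by w_i = (0.05 − p_i)/0.05, oriented by the sign of the group
  mean difference, and averaged; a score > 0 calls the patient a responder.

A course of M fractions yields M − 1 experiments (N = 2..M, using only
fractions 1..N), each evaluated by leave-one-out cross-validation over
patients. The per-patient **consistency index** — the fraction of
experiments in which the patient is classified correctly — separates
patients whose call is stable (late-course consistency > 0.8) from those
prone to overfitting at small sample size.

Because no public cohort exists for this setting, the package ships a
synthetic-cohort simulator (`simulate_cohort`) that generates feature
tables with exactly the structure the analysis assumes — group-dependent
linear trends plus noise, with known ground truth — at the study scale of
30 patients × 28 fractions × 1688 features.

## Worked example

`examples/03_loocv_experiment_suite.py` simulates a 14-patient,
14-fraction cohort and runs the full experiment suite:

```
13 experiments (N = 2..14)

accuracy by fraction band (mean over experiments in the band):
      n_experiments  rf_accuracy  sw_accuracy  rf_auc  sw_auc  mean_fit_err
band
2-7               6        0.917        0.714   0.954   0.993         0.460
8-14              7        0.990        0.796   1.000   1.000         0.681

headline RF AUC: 0.979 (95% bootstrap CI 0.951-0.998)
```

Accuracy in the early band (N = 2–7, mean 0.917 for the random forest)
rises and stabilizes in the late band (0.990): with more fractions
observed, the fitted trends — and hence the response call — settle. The
headline AUC is the mean pooled held-out AUC over all 13 experiments. The
script also prints each patient's consistency index and high/low grouping.

The other examples show trend fitting on its own
(`01_simulate_and_fit_trends.py`) and the screening + classifier stages
(`02_screen_and_classify.py`).

## Command line

```
lrt simulate --out sim/ --seed 1          # synthetic cohort + ground truth
lrt validate sim/features.csv sim/labels.csv
lrt regqc transforms.csv --threshold 0.05 # day-1 registration consistency
lrt fit sim/features.csv --upto 15 --out fits.csv
lrt select sim/features.csv sim/labels.csv --upto 15 --out sel.csv
lrt evaluate --features sim/features.csv --labels sim/labels.csv --out out/
lrt run-all --out out/ --seed 1           # simulate + evaluate + report
```

All stochastic stages are governed by one seed; every artifact is stamped
with the configuration hash.

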