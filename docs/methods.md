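# Methods

## Pipeline overview

The analysis chain is: registration QC (optional) → per-patient z-score
normalization → per-feature OLS trend fitting over fractions 1..N →
Mann–Whitney screening → univariate logistic LOOCV filter → random-forest
and statistical-weight classification → per-N LOOCV experiment suite with
consistency audit. Every stage is importable on its own; `run_pipeline`
orchestrates them and stamps all artifacts with a configuration hash and
the seed.

## Registration consistency QC

Daily scans are assumed rigidly registered to the planning image by an
external tool; the module audits the six rigid parameters (tx, ty, tz in
mm; rx, ry, rz in degrees) of each fraction against the manually verified
day-1 transform. The relative deviation is |p_j − p_1| / max(|p_1|, floor)
with floors of 1 mm / 1°; any parameter above the threshold (default 5%)
flags the fraction for manual review. A relative criterion is undefined at
a near-zero reference, which is common (a well-set-up patient has day-1
shifts near 0), so the floor prevents spurious warnings on sub-millimetre
jitter; the floor values are the scale at which a deviation starts to be
clinically meaningful rather than set-up noise. Comparison is parameter-wise
rather than via a matrix norm so that a warning is auditable per axis.

## Normalization

Each (patient, feature) series is standardized with that patient's own
series mean and sample (n−1) standard deviation, then clipped to
|z| ≤ 3. Clipping rather than discarding keeps the fraction grid intact
for trend fitting. Constant series are set to zero and flagged;
downstream stages skip them per patient (their LRTF enters classifier
matrices as 0, exactly what an all-zero series would yield). Constancy is
detected from the exact series range plus a relative sd tolerance
(1e−13·(|mean|+1)), because the two-pass sd of an exactly constant series
can come out as ~1 ulp instead of 0 and would otherwise explode the
z-scores.

A consequence worth knowing: per-patient standardization erases the
*magnitude* of a trend and keeps only its shape relative to the series'
own variability. A noiseless linear series normalizes to the same values
whatever its slope (up to sign), and a flat noisy series becomes unit-sd
noise. Trend information survives as the slope-to-variability ratio, which
is exactly what makes the statistic robust to scanner-dependent feature
scales — but it means the SW model's fixed threshold of 0 is only
well-centred when the two groups trend in opposite directions or one group
is flat. With one-sided effects the SW accuracy saturates below the random
forest's, which learns its own boundary; the same gap is visible in the
band accuracies the two models produce.

## Trend fitting

Ordinary least squares per (patient, feature) series on fractions 1..N,
vectorized across features with per-series missing-scan masks (absent
fractions are simply missing from the design; no imputation). The fitted
slope is the longitudinal trend LRT, and LRTF = LRT + β is the fitted
value at fraction 1 — dimensionally safe because the z-normalization makes
both terms unitless. The fit error is the mean *absolute* residual: a
signed mean residual is identically zero for any OLS fit and carries no
information, so it cannot serve as an error summary; a root-mean-square
option (`err_kind="rmse"`) is provided. Fits require ≥ 2 points and a
non-degenerate design; patients with fewer observed fractions at a given N
are skipped with a logged warning.

## Feature screening

Stage 1 is a per-feature two-sided Mann–Whitney U-test of LRTF between
responders and non-responders, retaining p < 0.05. The exact null
distribution is used when both groups have ≤ 8 patients and the column is
tie-free; otherwise the normal approximation with tie correction. A fully
tied column gets p = 1. Raw p-values are used deliberately — the screen is
a univariate filter, not an inference — with a Benjamini–Hochberg switch
(`bh_correct`) for users who want FDR control.

Stage 2 keeps retained features whose single-covariate logistic model
reaches a held-out LOOCV accuracy ≥ 0.7 (configurable; 1.0 gives the
strict all-correct reading). The fits are ridge-penalized Newton
iterations (penalty 1/C on the slope only, C = 1 matching the common
library default), vectorized over all (feature, fold) pairs — the screen
runs inside every fold of every per-N experiment, on the order of 1e5
univariate fits per suite, so a per-fit library call is impractical; the
vectorized solver is verified against scikit-learn's logistic regression
fold-by-fold in the tests. The ridge keeps coefficients bounded under
perfect separation. An empty survivor set falls back to the U-retained set
with a warning rather than failing.

## Classifiers

**Random forest** (scikit-learn): default 500 trees, unlimited depth,
fixed seed recorded in every report; the score is the predicted responder
probability.

**SW model**: weight w_i = (0.05 − p_i)/0.05 from the U-test p-values of
the U-retained set (the interpretable model is deliberately built on the
statistical screen alone); orientation sign s_i = sign(responder mean −
non-responder mean) of LRTF in training data; patient score
Σ w_i s_i LRTF_i / Σ w_i, called responder when > 0. The orientation is an
extension (default on, `sw_orient=False` for the literal unoriented form):
without it, informative features trending in opposite directions cancel in
the average. Weight normalization makes the score invariant to duplicating
a feature and keeps the 0 threshold meaningful regardless of how many
features are retained.

## Experiment suite and consistency

For a course of M fractions, experiments N = 2..M each use fractions 1..N
(27 experiments for the standard 28-fraction course, banded 2–14 / 15–20 /
21–28, i.e. 13 + 6 + 8). Within each experiment, leave-one-out
cross-validation over patients: screening, the logistic filter, the SW
orientation and the forest are all fitted on the training patients only.
Per-patient z-normalization depends only on that patient's own series, so
it is computed once and is leakage-free by construction; the suite's tests
verify that flipping a held-out patient's label never changes that
patient's scores, and that label permutation drives AUC to chance. AUC is
computed on the pooled held-out scores of each experiment; the headline
number is the mean over experiments with a percentile bootstrap CI (the
aggregation is declared in reports since pooling across experiments and
averaging are not equivalent).

The consistency index is the per-patient mean of correct/incorrect
indicators across experiments; the high/low grouping applies a 0.8 cut to
the mean over the late-course window N ≥ 15 (configurable), where the
trend fits have stabilized. Folds whose training set collapses to a single
class are skipped with a warning and excluded from the affected summaries;
if nothing survives screening in a fold, the fold's scores fall back to
the uninformative values (RF 0.5, SW 0).

## Synthetic cohort

The simulator emulates a fractionated-radiotherapy cohort observed with
one scan per fraction: value = intercept + slope·fraction + i.i.d.
Gaussian noise. Defaults are the study scale — 30 patients, 28 fractions
(840 scans), 1688 features, 14/30 responders. All slopes are drawn
N(0, effect_slope_sd) and responders additionally receive
+effect_slope_mean on the `n_informative` informative features, so the
group *difference*, not the absolute slope, carries the signal. Defaults
effect_slope_mean = 0.1 (z-trend accumulating to ~3 series-sd over a
course), effect_slope_sd = 0.02, noise_sd = 0.3, n_informative = 40 —
a strong but not trivial effect: early-course experiments are noticeably
harder than late-course ones, which is the regime the consistency analysis
is about. Labels are assigned deterministically (first ⌈n·p⌉ patients
respond) to avoid label-count jitter across seeds. Outliers replace a
value with truth ± 10·noise_sd to exercise the |z| = 3 bound; missing
scans drop whole (patient, fraction) records except fractions 1–2, which
are always kept so every patient supports a trend fit and a day-1 QC
reference.

What the simulator does *not* model: scanner drift and day-to-day image
quality variation (noise is i.i.d.), inter-feature correlation (real
radiomic families are strongly collinear), non-linear response
trajectories, and class-dependent missingness. Passing tests therefore
demonstrate that the statistical machinery recovers the structure it
assumes, not that real cohorts satisfy that structure.

## Problem sizes in tests and reports

The simulator's feature axis is freely sizeable; multi-seed test suites
run on 100–200-feature panels with 25-tree forests, while
`scripts/acceptance.py` runs the full 1688-feature, 500-tree configuration
once. Panel size only dilutes the screen's false-positive pool, and tree
count beyond ~25 changes scores negligibly on cohorts of this size, so
these choices trade nothing but wall-clock time.

## Known limitations

* The SW threshold of 0 presumes symmetric (or one-flat) group trends
  after orientation; for one-sided effects its accuracy plateaus below the
  forest's (see Normalization).
* Exact Mann–Whitney p-values are only used for groups of ≤ 8; cohorts in
  between rely on the tie-corrected normal approximation.
* The consistency grouping needs the course to reach the window start
  (default fraction 15); shorter courses fall back to all experiments.
* Registration QC audits transform parameters only; it cannot detect a
  registration that is consistently wrong from day 1.
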