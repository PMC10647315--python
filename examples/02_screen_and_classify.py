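"""Feature screening and the two classifiers on one train/score pass.

Runs the Mann-Whitney U-test screen and the univariate logistic LOOCV
filter on fitted LRTFs, then trains the random forest and the p-value-
weighted SW model and prints each patient's scores.  (For honest held-out
performance use lrtrend.run_loocv, which wraps this inside per-patient
cross-validation.)
"""

from lrtrend import (
    CohortConfig, RFModelSpec, build_sw_model, fit_course, logistic_screen,
    rf_score, simulate_cohort, sw_score, train_rf, utest_screen,
    zscore_normalize,
)

cfg = CohortConfig(n_patients=16, n_fractions=15, n_features=80, n_informative=15,
                   fraction_responders=0.5, noise_sd=0.25, seed=3)
table, _ = simulate_cohort(cfg)
course = fit_course(zscore_normalize(table), upto_fraction=15)
lrtf, y = course.lrtf_matrix(), table.label_vector()

sel = utest_screen(lrtf, y, alpha=0.05)
print(f"U-test retained {len(sel.u_retained)}/{cfg.n_features} features (p < 0.05)")
sel = logistic_screen(lrtf, y, sel, min_accuracy=0.7)
print(f"logistic LOOCV filter kept {len(sel.logistic_retained)} of those "
      f"(held-out accuracy >= 0.7)")

rf = train_rf(lrtf[sel.effective], y, RFModelSpec(n_trees=200, seed=0))
sw = build_sw_model(lrtf, y, sel)

print("\npatient  label          RF score  SW score")
for i, p in enumerate(course.patients):
    lab = "responder    " if y[i] else "non-responder"
    print(f"{p}     {lab}  {rf_score(rf, lrtf[sel.effective].iloc[[i]])[0]:8.3f} "
          f"{sw_score(sw, lrtf.iloc[[i]])[0]:9.3f}")
print("\nRF score is the forest's responder probability (call at > 0.5); "
      "the SW score is a p-value-weighted mean of oriented LRTFs (call at > 0).")
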