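from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lrtrend.errors import ModelDegenerateError, ScreeningError
from lrtrend.selection import (
    RFModelSpec,
    build_sw_model,
    logistic_screen,
    mannwhitney_pvalues,
    rf_score,
    sw_score,
    sw_weight,
    train_rf,
    univariate_logistic_loocv_accuracy,
    utest_screen,
)


def exact_utest_p(x, y):
    """Exhaustive-enumeration oracle for the two-sided Mann-Whitney p-value
    (tie-free data): enumerate every assignment of the pooled values into
    groups of sizes (|x|, |y|), compute the U distribution, and return the
    doubled smaller tail including the observed point."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        us.append(sum(a > b for a in g1 for b in g2))
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestUTest:
    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the exact two-sided p is 2/20 = 0.1,
        so the feature is NOT retained at alpha 0.05."""
        m = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6.0]})
        labels = [1, 1, 1, 0, 0, 0]
        sel = utest_screen(m, labels)
        assert sel.p_values[0] == pytest.approx(0.1, abs=1e-12)
        assert sel.u_retained == []

    def test_identical_groups_p_one(self):
        m = pd.DataFrame({"f": [2.0, 2.0, 2.0, 2.0]})
        sel = utest_screen(m, [1, 1, 0, 0])
        assert sel.p_values[0] == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (2, 5)])
    def test_matches_exhaustive_enumeration(self, n1, n2, rng):
        for _ in range(10):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            p = mannwhitney_pvalues(x[:, None], y[:, None])[0]
            assert p == pytest.approx(exact_utest_p(x, y), abs=1e-10)

    def test_recovers_informative_features_beyond_chance(self):
        """Retention overlaps the true informative set far beyond chance
        (hypergeometric p < 0.01) on strong-effect simulations."""
        from lrtrend import CohortConfig, fit_course, simulate_cohort, zscore_normalize

        hyper_ps = []
        for seed in range(20):
            cfg = CohortConfig(n_patients=30, n_fractions=10, n_features=80,
                               n_informative=20, noise_sd=0.3, seed=300 + seed)
            table, truth = simulate_cohort(cfg)
            course = fit_course(zscore_normalize(table), 10)
            sel = utest_screen(course.lrtf_matrix(), table.label_vector())
            retained_idx = {course.feature_ids.index(f) for f in sel.u_retained}
            overlap = len(retained_idx & set(truth.informative_idx))
            hyper_ps.append(stats.hypergeom.sf(
                overlap - 1, cfg.n_features, cfg.n_informative, len(retained_idx)
            ) if retained_idx else 1.0)
        assert np.median(hyper_ps) < 0.01

    def test_single_class_labels_rejected(self):
        with pytest.raises(ScreeningError):
            utest_screen(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])

    def test_bh_option_is_more_conservative(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 50)))
        y = rng.integers(0, 2, size=20)
        y[:2], y[-2:] = 1, 0
        raw = utest_screen(m, y, bh_correct=False)
        bh = utest_screen(m, y, bh_correct=True)
        assert set(bh.u_retained) <= set(raw.u_retained)


class TestWeights:
    def test_weight_endpoints_and_midpoint(self):
        assert sw_weight(0.05) == pytest.approx(0.0)
        assert sw_weight(0.0) == pytest.approx(1.0)
        assert sw_weight(0.025) == pytest.approx(0.5)


class TestLogisticScreen:
    def test_perfect_separator_retained(self):
        m = pd.DataFrame({"f": [-2.0, -1.5, -1.0, -1.2, 1.0, 1.5, 2.0, 1.2]})
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        sel = utest_screen(m, y)
        assert sel.u_retained == ["f"]
        sel2 = logistic_screen(m, y, sel, min_accuracy=1.0)
        assert sel2.logistic_retained == ["f"]
        assert sel2.logistic_accuracy["f"] == 1.0

    def test_random_features_rarely_retained(self, rng):
        """A label-independent feature passes the 0.7 accuracy bar with low
        probability (balanced labels)."""
        n = 20
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.normal(size=(200, n))  # 200 independent random "features"
        acc = univariate_logistic_loocv_accuracy(X, y)
        assert (acc >= 0.7).mean() < 0.15

    def test_matches_sklearn_per_fold_oracle(self, rng):
        """The vectorised Newton solver reproduces sklearn's per-fold
        held-out predictions (same ridge penalty)."""
        from sklearn.linear_model import LogisticRegression

        n = 14
        y = np.r_[np.ones(7), np.zeros(7)].astype(int)
        X = rng.normal(size=(5, n)) + 0.8 * y
        acc_fast = univariate_logistic_loocv_accuracy(X, y, C=1.0)
        for f in range(5):
            correct = 0
            for k in range(n):
                tr = np.arange(n) != k
                clf = LogisticRegression(C=1.0).fit(X[f, tr, None], y[tr])
                correct += clf.predict(X[f, k, None][:, None])[0] == y[k]
            assert acc_fast[f] == pytest.approx(correct / n, abs=1e-12)

    def test_empty_survivor_set_falls_back(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        y = np.r_[np.ones(6), np.zeros(6)].astype(int)
        sel = utest_screen(m, y, alpha=1.01)  # force-retain everything
        sel2 = logistic_screen(m, y, sel, min_accuracy=1.0)
        if not sel2.logistic_retained:
            assert sel2.effective == sel2.u_retained


class TestRandomForest:
    def _toy(self):
        m = pd.DataFrame({"f1": [-1.0, -2.0, -1.5, 1.0, 2.0, 1.5],
                          "f2": [0.1, 0.2, 0.0, 0.1, 0.0, 0.2]})
        y = [0, 0, 0, 1, 1, 1]
        return m, y

    def test_separable_training_scores(self):
        m, y = self._toy()
        model = train_rf(m, y, RFModelSpec(n_trees=50, seed=0))
        s = rf_score(model, m)
        assert (s[np.array(y) == 1] > 0.5).all()
        assert (s[np.array(y) == 0] < 0.5).all()

    def test_deterministic_given_seed(self):
        m, y = self._toy()
        s1 = rf_score(train_rf(m, y, RFModelSpec(n_trees=50, seed=7)), m)
        s2 = rf_score(train_rf(m, y, RFModelSpec(n_trees=50, seed=7)), m)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_training_rejected(self):
        with pytest.raises(ScreeningError):
            train_rf(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])


class TestSWModel:
    def _selection(self, m, y):
        return utest_screen(m, y)

    def test_single_feature_reduction(self):
        m = pd.DataFrame({"f": [3.0, 2.5, 2.8, 2.6, -3.0, -2.5, -2.8, -2.6]})
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        sel = self._selection(m, y)
        model = build_sw_model(m, y, sel)
        assert model.signs[0] == 1.0
        score = sw_score(model, pd.DataFrame({"f": [2.0]}))[0]
        assert score == pytest.approx(2.0)
        assert score > 0  # classified responder

    def test_orientation_flips_negative_effects(self):
        m = pd.DataFrame({"f": [-3.0, -2.5, -2.8, -2.6, 3.0, 2.5, 2.8, 2.6]})
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        model = build_sw_model(m, y, self._selection(m, y), orient=True)
        assert model.signs[0] == -1.0
        assert sw_score(model, pd.DataFrame({"f": [-2.0]}))[0] > 0
        plain = build_sw_model(m, y, self._selection(m, y), orient=False)
        assert plain.signs[0] == 1.0

    def test_monotone_in_oriented_lrtf(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)) + np.r_[np.ones(5), np.zeros(5)][:, None],
                         columns=list("abcd"))
        y = [1] * 5 + [0] * 5
        sel = utest_screen(m, y, alpha=1.01)
        model = build_sw_model(m, y, sel)
        x = pd.DataFrame(rng.normal(size=(1, 4)), columns=list("abcd"))
        base = sw_score(model, x)[0]
        j = model.feature_ids[0]
        x2 = x.copy()
        x2[j] += 1.0 * model.signs[0]  # increase the oriented value
        assert sw_score(model, x2)[0] > base

    def test_duplicate_feature_invariance(self):
        """Weight normalization makes the score invariant to duplicating a
        feature with identical p-value and values."""
        m = pd.DataFrame({"f": [2.0, 1.8, 2.2, -2.0, -1.8, -2.2]})
        y = [1, 1, 1, 0, 0, 0]
        sel1 = utest_screen(m, y, alpha=1.01)
        model1 = build_sw_model(m, y, sel1)
        m2 = pd.DataFrame({"f": m["f"], "g": m["f"]})
        sel2 = utest_screen(m2, y, alpha=1.01)
        model2 = build_sw_model(m2, y, sel2)
        x1 = pd.DataFrame({"f": [1.3]})
        x2 = pd.DataFrame({"f": [1.3], "g": [1.3]})
        assert sw_score(model1, x1)[0] == pytest.approx(sw_score(model2, x2)[0], abs=1e-12)

    def test_empty_selection_rejected(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        y = [1, 1, 0, 0]
        sel = utest_screen(m, y, alpha=1e-12)
        with pytest.raises(ModelDegenerateError):
            build_sw_model(m, y, sel)


def test_rf_and_sw_agree_on_separated_lrtfs(rng):
    """Both classifiers reach perfect accuracy on LRTFs whose groups
    separate cleanly on either side of zero."""
    n = 12
    y = np.r_[np.ones(6), np.zeros(6)].astype(int)
    signal = np.where(y == 1, 2.0, -2.0)[:, None]
    m = pd.DataFrame(
        signal * np.ones((n, 5)) + 0.1 * rng.normal(size=(n, 5)),
        columns=[f"f{k}" for k in range(5)],
    )
    sel = utest_screen(m, y)
    assert sel.u_retained  # groups differ on every feature
    rf = train_rf(m[sel.effective], y, RFModelSpec(n_trees=100, seed=0))
    sw = build_sw_model(m, y, sel)
    rf_pred = (rf_score(rf, m[sel.effective]) > 0.5).astype(int)
    sw_pred = (sw_score(sw, m) > 0).astype(int)
    assert (rf_pred == y).all() and (sw_pred == y).all()


def test_end_to_end_zero_noise_cohort_both_models_perfect():
    """Flat non-responder series and a clean responder trend: both models
    classify every patient correctly from the fitted LRTFs."""
    from lrtrend import CohortConfig, fit_course, simulate_cohort, zscore_normalize

    cfg = CohortConfig(n_patients=12, n_fractions=20, n_features=30, n_informative=10,
                       noise_sd=0.0, effect_slope_sd=0.0, fraction_responders=0.5,
                       seed=9)
    table, _ = simulate_cohort(cfg)
    course = fit_course(zscore_normalize(table), 20)
    m, y = course.lrtf_matrix(), table.label_vector()
    sel = utest_screen(m, y)
    rf = train_rf(m[sel.effective], y, RFModelSpec(n_trees=100, seed=0))
    sw = build_sw_model(m, y, sel)
    rf_pred = (rf_score(rf, m[sel.effective]) > 0.5).astype(int)
    sw_pred = (sw_score(sw, m) > 0).astype(int)
    assert (rf_pred == y).all() and (sw_pred == y).all()
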