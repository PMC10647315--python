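"""Feature screening and the two response classifiers.

Screening is two-stage: a per-feature two-sided Mann-Whitney U-test
comparing LRTF between responders and non-responders (keep p < alpha,
default 0.05), then a univariate logistic screen that keeps features whose
single-covariate leave-one-out accuracy reaches a threshold (default 0.7).

Two classifiers consume the retained LRTFs:

* a random forest whose score is the predicted responder probability;
* an interpretable statistical-weight (SW) model: each U-retained LRTF is
  weighted by w_i = (0.05 - p_i)/0.05, oriented so that larger oriented
  values point toward response, and the patient's score is the weighted
  mean; a score above 0 calls the patient a responder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ModelDegenerateError, ScreeningError, ValidationError

log = logging.getLogger(__name__)

EXACT_MAX_GROUP = 8  # use the exact U distribution when both groups are this small


def _as_matrix(lrtf_matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(lrtf_matrix, pd.DataFrame):
        return lrtf_matrix.to_numpy(dtype=float), list(lrtf_matrix.columns)
    m = np.asarray(lrtf_matrix, dtype=float)
    return m, [f"feature_{k}" for k in range(m.shape[1])]


@dataclass
class SelectionResult:
    """Outcome of the U-test and (optionally) the logistic screen."""

    feature_ids: list[str]
    p_values: np.ndarray  # per feature, two-sided Mann-Whitney
    alpha: float
    u_retained: list[str]
    logistic_retained: list[str] | None = None
    logistic_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def effective(self) -> list[str]:
        """Features the final classifier uses: the logistic survivors, or
        the U-retained set when the logistic screen is absent or empty."""
        if self.logistic_retained:
            return self.logistic_retained
        return self.u_retained

    def p_value(self, feature_id: str) -> float:
        return float(self.p_values[self.feature_ids.index(feature_id)])


def mannwhitney_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per column of ``x`` (group 1) vs ``y``.

    Uses the exact null distribution when both groups have <= 8 patients
    and a column is tie-free; otherwise the normal approximation with tie
    correction.
    """
    n1, n2 = len(x), len(y)
    small = max(n1, n2) <= EXACT_MAX_GROUP
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.mannwhitneyu(
            x, y, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.atleast_1d(res.pvalue).astype(float)
    p[np.isnan(p)] = 1.0  # fully tied column: no evidence of a difference
    if small:
        pooled = np.vstack([x, y])
        for j in range(x.shape[1]):
            col = pooled[:, j]
            if len(np.unique(col)) == len(col):  # tie-free -> exact
                p[j] = stats.mannwhitneyu(
                    x[:, j], y[:, j], alternative="two-sided", method="exact"
                ).pvalue
    return p


def utest_screen(
    lrtf_matrix, labels, alpha: float = 0.05, bh_correct: bool = False
) -> SelectionResult:
    """Mann-Whitney screen of each feature's LRTF across response groups.

    Parameters
    ----------
    lrtf_matrix
        Patients x features matrix (DataFrame or ndarray).
    labels
        Binary vector aligned with rows, 1 = responder.
    alpha
        Retention threshold on the (optionally BH-adjusted) p-value.
    bh_correct
        Apply a Benjamini-Hochberg adjustment before thresholding.  Off by
        default: the screen is deliberately a raw per-feature test.
    """
    m, feature_ids = _as_matrix(lrtf_matrix)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("both response groups must be non-empty")
    if m.shape[0] != len(y):
        raise ValidationError("labels length does not match matrix rows")
    p = mannwhitney_pvalues(m[y == 1], m[y == 0])
    p_screen = stats.false_discovery_control(p) if bh_correct else p
    retained = [f for f, pv in zip(feature_ids, p_screen) if pv < alpha]
    return SelectionResult(
        feature_ids=feature_ids, p_values=p, alpha=alpha, u_retained=retained
    )


def univariate_logistic_loocv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, n_iter: int = 50
) -> np.ndarray:
    """Held-out accuracy of a single-covariate logistic model per feature.

    ``X`` is (n_features, n_patients).  For every feature and every
    leave-one-out fold, a ridge-penalised logistic model (penalty 1/C on
    the slope, none on the intercept) is fitted by Newton iterations,
    vectorised over all (feature, fold) pairs; the held-out patient is
    classified at probability 0.5.  The ridge keeps coefficients bounded
    under perfect separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_feat, n = X.shape
    train = ~np.eye(n, dtype=bool)  # (fold, sample)
    b0 = np.zeros((n_feat, n))
    b1 = np.zeros((n_feat, n))
    xs = X[:, None, :]  # (feat, fold=1, sample)
    lam = 1.0 / C
    for _ in range(n_iter):
        eta = b0[..., None] + b1[..., None] * xs
        p = 1.0 / (1.0 + np.exp(-eta))
        r = np.where(train, p - y, 0.0)
        w = np.where(train, p * (1.0 - p), 0.0)
        g0 = r.sum(-1)
        g1 = (r * xs).sum(-1) + lam * b1
        h00 = w.sum(-1) + 1e-10
        h01 = (w * xs).sum(-1)
        h11 = (w * xs**2).sum(-1) + lam
        det = h00 * h11 - h01**2
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        b0 -= db0
        b1 -= db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < 1e-10:
            break
    held_eta = b0 + b1 * X  # diagonal prediction: fold k predicts sample k
    pred = held_eta > 0.0
    return (pred == (y > 0.5)).mean(axis=1)


def logistic_screen(
    lrtf_matrix,
    labels,
    selection: SelectionResult,
    min_accuracy: float = 0.7,
    C: float = 1.0,
) -> SelectionResult:
    """Keep U-retained features whose univariate LOOCV accuracy >= threshold.

    An empty survivor set is returned as empty with a warning; downstream
    models then fall back to the U-retained set (:attr:`SelectionResult.effective`).
    """
    if not selection.u_retained:
        raise ScreeningError("logistic screen called with empty U-retained set")
    m, feature_ids = _as_matrix(lrtf_matrix)
    y = np.asarray(labels).astype(int)
    idx = [feature_ids.index(f) for f in selection.u_retained]
    acc = univariate_logistic_loocv_accuracy(m[:, idx].T, y, C=C)
    accuracy = dict(zip(selection.u_retained, acc.astype(float)))
    survivors = [f for f in selection.u_retained if accuracy[f] >= min_accuracy]
    if not survivors:
        log.warning(
            "logistic screen retained no features at min_accuracy=%.2f; "
            "models will fall back to the %d U-retained features",
            min_accuracy, len(selection.u_retained),
        )
    return SelectionResult(
        feature_ids=selection.feature_ids,
        p_values=selection.p_values,
        alpha=selection.alpha,
        u_retained=selection.u_retained,
        logistic_retained=survivors,
        logistic_accuracy=accuracy,
    )


# -- random-forest model -------------------------------------------------
@dataclass
class RFModelSpec:
    """Random-forest hyperparameters and trained state."""

    n_trees: int = 500
    max_depth: int | None = None
    seed: int = 0
    feature_ids: list[str] | None = None
    model: RandomForestClassifier | None = None


def train_rf(lrtf_matrix, labels, spec: RFModelSpec | None = None) -> RFModelSpec:
    """Train the random forest on selected-feature LRTFs (1 = responder)."""
    spec = spec or RFModelSpec()
    m, feature_ids = _as_matrix(lrtf_matrix)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees, max_depth=spec.max_depth, random_state=spec.seed
    )
    clf.fit(m, y)
    return RFModelSpec(
        n_trees=spec.n_trees,
        max_depth=spec.max_depth,
        seed=spec.seed,
        feature_ids=spec.feature_ids or feature_ids,
        model=clf,
    )


def rf_score(spec: RFModelSpec, patient_lrtf) -> np.ndarray:
    """Predicted responder probability for one or more patients."""
    if spec.model is None:
        raise ValidationError("RF model has not been trained")
    x = np.atleast_2d(np.asarray(patient_lrtf, dtype=float))
    proba = spec.model.predict_proba(x)
    cls = list(spec.model.classes_)
    return proba[:, cls.index(1)]


# -- statistical-weight model --------------------------------------------
@dataclass
class SWModel:
    """p-value-weighted interpretable classifier over retained LRTFs."""

    feature_ids: list[str]
    weights: np.ndarray  # w_i = (alpha - p_i) / alpha, in (0, 1]
    signs: np.ndarray  # orientation s_i in {-1, +1}
    threshold: float = 0.0


def sw_weight(p: float, alpha: float = 0.05) -> float:
    """The p-value weight w = (alpha - p) / alpha (w(0) = 1, w(alpha) = 0)."""
    return (alpha - p) / alpha


def build_sw_model(
    lrtf_matrix, labels, selection: SelectionResult, orient: bool = True
) -> SWModel:
    """Build the SW model from the U-retained features of ``selection``.

    Weights come from the U-test p-values via ``(alpha - p)/alpha``; each
    feature's orientation sign is the sign of (responder mean LRTF -
    non-responder mean LRTF) in the training data, so that oppositely
    trending informative features reinforce instead of cancelling.  Set
    ``orient=False`` for unoriented (all +1) averaging.
    """
    if not selection.u_retained:
        raise ModelDegenerateError("no retained features to build the SW model from")
    m, feature_ids = _as_matrix(lrtf_matrix)
    y = np.asarray(labels).astype(int)
    idx = np.asarray([feature_ids.index(f) for f in selection.u_retained])
    p = selection.p_values[idx]
    w = (selection.alpha - p) / selection.alpha
    if not (w > 0).any():
        raise ModelDegenerateError("all SW weights are zero")
    if orient:
        diff = m[y == 1][:, idx].mean(axis=0) - m[y == 0][:, idx].mean(axis=0)
        signs = np.where(diff >= 0, 1.0, -1.0)
    else:
        signs = np.ones_like(w)
    return SWModel(feature_ids=list(selection.u_retained), weights=w, signs=signs)


def sw_score(model: SWModel, patient_lrtf) -> np.ndarray:
    """Weighted mean of oriented LRTFs; > 0 suggests a good responder."""
    x = patient_lrtf
    if isinstance(x, pd.DataFrame):
        x = x[model.feature_ids].to_numpy(dtype=float)
    elif isinstance(x, pd.Series):
        x = x[model.feature_ids].to_numpy(dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.feature_ids):
        raise ValidationError(
            f"expected {len(model.feature_ids)} feature values, got {x.shape[1]}"
        )
    return (x * model.signs * model.weights).sum(axis=1) / model.weights.sum()
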