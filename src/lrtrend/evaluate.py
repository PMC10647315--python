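"""Per-fraction LOOCV experiments, consistency index, and reports.

A course of M fractions yields M - 1 independent experiments: experiment N
(N = 2..M) uses only fractions 1..N, so that the suite answers "how early
in the course can response be called, and how stably?".  Each experiment
runs leave-one-out cross-validation over patients; within every fold,
feature screening and model training see only the training patients
(per-patient z-normalization depends only on each patient's own series, so
it is leakage-free by construction and computed once).

The per-patient consistency index (CI) is the fraction of experiments in
which the patient was classified correctly; patients whose mean CI over
the late-course window (N >= 15) exceeds 0.8 form the high-consistency
group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import PipelineConfig
from .errors import ScreeningError, ValidationError
from .io import LongitudinalFeatureTable
from .normalize import zscore_normalize
from .selection import (
    RFModelSpec,
    build_sw_model,
    logistic_screen,
    rf_score,
    sw_score,
    train_rf,
    utest_screen,
)
from .trend import fit_course

log = logging.getLogger(__name__)


@dataclass
class ExperimentSuite:
    """Held-out scores and summary metrics of the per-N LOOCV experiments."""

    ns: np.ndarray  # experiment fraction counts, 2..max
    patients: list
    labels: np.ndarray  # 1 = responder, aligned with patients
    rf_scores: np.ndarray  # (n_experiments, n_patients) held-out RF scores
    sw_scores: np.ndarray  # (n_experiments, n_patients) held-out SW scores
    rf_accuracy: np.ndarray  # per experiment
    sw_accuracy: np.ndarray
    rf_auc: np.ndarray  # pooled held-out AUC per experiment
    sw_auc: np.ndarray
    mean_fit_err: np.ndarray  # mean trend-fit error per experiment
    n_retained: np.ndarray  # mean U-retained features per fold, per experiment
    config_hash: str = ""
    seed: int = 0

    @property
    def n_experiments(self) -> int:
        return len(self.ns)

    @property
    def rf_correct(self) -> np.ndarray:
        """(n_experiments, n_patients) correctness indicators for RF calls."""
        return ((self.rf_scores > 0.5).astype(int) == self.labels[None, :])

    @property
    def sw_correct(self) -> np.ndarray:
        return ((self.sw_scores > 0.0).astype(int) == self.labels[None, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_fractions": self.ns,
                "rf_accuracy": self.rf_accuracy,
                "sw_accuracy": self.sw_accuracy,
                "rf_auc": self.rf_auc,
                "sw_auc": self.sw_auc,
                "mean_fit_err": self.mean_fit_err,
                "n_retained": self.n_retained,
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "ns": self.ns.tolist(),
            "patients": list(self.patients),
            "labels": self.labels.tolist(),
            "rf_scores": self.rf_scores.tolist(),
            "sw_scores": self.sw_scores.tolist(),
            "rf_accuracy": self.rf_accuracy.tolist(),
            "sw_accuracy": self.sw_accuracy.tolist(),
            "rf_auc": self.rf_auc.tolist(),
            "sw_auc": self.sw_auc.tolist(),
            "mean_fit_err": self.mean_fit_err.tolist(),
            "n_retained": self.n_retained.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentSuite":
        d = json.loads(Path(path).read_text())
        return cls(
            ns=np.asarray(d["ns"]),
            patients=d["patients"],
            labels=np.asarray(d["labels"]),
            rf_scores=np.asarray(d["rf_scores"]),
            sw_scores=np.asarray(d["sw_scores"]),
            rf_accuracy=np.asarray(d["rf_accuracy"]),
            sw_accuracy=np.asarray(d["sw_accuracy"]),
            rf_auc=np.asarray(d["rf_auc"]),
            sw_auc=np.asarray(d["sw_auc"]),
            mean_fit_err=np.asarray(d["mean_fit_err"]),
            n_retained=np.asarray(d["n_retained"]),
            config_hash=d.get("config_hash", ""),
            seed=d.get("seed", 0),
        )


def run_loocv(
    table: LongitudinalFeatureTable, config: PipelineConfig | None = None
) -> ExperimentSuite:
    """Run the full per-N LOOCV experiment suite on a labelled table."""
    config = config or PipelineConfig()
    config.validate()
    if table.labels is None:
        raise ValidationError("table must have labels attached")
    y_all = table.label_vector()
    if y_all.sum() < 2 or (1 - y_all).sum() < 2:
        raise ScreeningError("need at least 2 patients per response class")

    norm = zscore_normalize(table, bound=config.norm_bound)
    max_frac = int(norm.fractions.max())
    ns = np.arange(2, max_frac + 1)
    n_p = len(norm.patients)

    rf_scores = np.full((len(ns), n_p), np.nan)
    sw_scores = np.full((len(ns), n_p), np.nan)
    mean_fit_err = np.zeros(len(ns))
    n_retained = np.zeros(len(ns))

    for e, N in enumerate(ns):
        course = fit_course(norm, int(N), err_kind=config.err_kind)
        lrtf = course.lrtf_matrix()
        mean_fit_err[e] = course.mean_fit_error()
        retained_counts = []
        for k in range(n_p):
            train = np.ones(n_p, dtype=bool)
            train[k] = False
            y_tr = y_all[train]
            if len(np.unique(y_tr)) < 2:
                log.warning("fold %d at N=%d skipped: single-class training set", k, N)
                continue
            X_tr = lrtf.iloc[train]
            sel = utest_screen(X_tr, y_tr, alpha=config.alpha, bh_correct=config.bh_correct)
            if config.logistic_screen and sel.u_retained:
                sel = logistic_screen(
                    X_tr, y_tr, sel,
                    min_accuracy=config.min_accuracy, C=config.logistic_C,
                )
            retained_counts.append(len(sel.u_retained))
            feats = sel.effective
            if not feats:
                # nothing survives screening: fall back to uninformative calls
                rf_scores[e, k] = 0.5
                sw_scores[e, k] = 0.0
                continue
            spec = RFModelSpec(
                n_trees=config.rf_n_trees,
                max_depth=config.rf_max_depth,
                seed=config.seed,
            )
            model = train_rf(X_tr[feats], y_tr, spec)
            rf_scores[e, k] = rf_score(model, lrtf.iloc[[k]][feats])[0]
            swm = build_sw_model(X_tr, y_tr, sel, orient=config.sw_orient)
            sw_scores[e, k] = sw_score(swm, lrtf.iloc[[k]])[0]
        n_retained[e] = float(np.mean(retained_counts)) if retained_counts else 0.0

    scored = ~np.isnan(rf_scores)
    rf_accuracy = np.array(
        [((rf_scores[e] > 0.5).astype(int) == y_all)[scored[e]].mean() for e in range(len(ns))]
    )
    sw_accuracy = np.array(
        [((sw_scores[e] > 0.0).astype(int) == y_all)[scored[e]].mean() for e in range(len(ns))]
    )
    rf_auc = np.array(
        [roc_auc_score(y_all[scored[e]], rf_scores[e][scored[e]]) for e in range(len(ns))]
    )
    sw_auc = np.array(
        [roc_auc_score(y_all[scored[e]], sw_scores[e][scored[e]]) for e in range(len(ns))]
    )
    return ExperimentSuite(
        ns=ns,
        patients=norm.patients,
        labels=y_all,
        rf_scores=rf_scores,
        sw_scores=sw_scores,
        rf_accuracy=rf_accuracy,
        sw_accuracy=sw_accuracy,
        rf_auc=rf_auc,
        sw_auc=sw_auc,
        mean_fit_err=mean_fit_err,
        n_retained=n_retained,
        config_hash=config.hash(),
        seed=config.seed,
    )


def consistency_index(
    suite: ExperimentSuite,
    model: str = "rf",
    window_start: int = 15,
    cut: float = 0.8,
) -> pd.DataFrame:
    """Per-patient consistency index and high/low-consistency grouping.

    CI is the mean of the per-experiment correct/incorrect indicators over
    all experiments; the grouping applies the ``cut`` to the mean indicator
    over the late-course window N >= ``window_start``.
    """
    correct = suite.rf_correct if model == "rf" else suite.sw_correct
    late = suite.ns >= window_start
    if not late.any():  # short course: the window collapses to all experiments
        late = np.ones_like(late)
    ci_all = correct.mean(axis=0)
    ci_late = correct[late].mean(axis=0)
    group = np.where(ci_late > cut, "high", "low")
    return pd.DataFrame(
        {
            "patient_id": suite.patients,
            "label": np.where(suite.labels == 1, "responder", "non-responder"),
            "ci": ci_all,
            "ci_late": ci_late,
            "group": group,
        }
    ).set_index("patient_id")


def accuracy_by_fraction_report(
    suite: ExperimentSuite, bands: tuple[tuple[int, int], ...] = ((2, 14), (15, 20), (21, 28))
) -> pd.DataFrame:
    """Mean per-experiment accuracy grouped into fraction bands."""
    rows = []
    for lo, hi in bands:
        sel = (suite.ns >= lo) & (suite.ns <= hi)
        rows.append(
            {
                "band": f"{lo}-{hi}",
                "n_experiments": int(sel.sum()),
                "rf_accuracy": float(suite.rf_accuracy[sel].mean()) if sel.any() else np.nan,
                "sw_accuracy": float(suite.sw_accuracy[sel].mean()) if sel.any() else np.nan,
                "rf_auc": float(suite.rf_auc[sel].mean()) if sel.any() else np.nan,
                "sw_auc": float(suite.sw_auc[sel].mean()) if sel.any() else np.nan,
                "mean_fit_err": float(suite.mean_fit_err[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("band")


def headline_auc(
    suite: ExperimentSuite,
    model: str = "rf",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Mean AUC over experiments with a percentile bootstrap CI."""
    aucs = suite.rf_auc if model == "rf" else suite.sw_auc
    rng = np.random.default_rng(seed)
    boots = rng.choice(aucs, size=(n_boot, len(aucs)), replace=True).mean(axis=1)
    lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return {"auc_mean": float(aucs.mean()), "ci_low": float(lo), "ci_high": float(hi)}
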