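"""Per-feature linear trend fitting across treatment fractions.

For each patient and feature, the normalized series RF_ij is modelled as a
line in the fraction number X_j,

    RF_ij = LRT_i * X_j + beta_i,

fitted by ordinary least squares.  LRT_i (the longitudinal radiomic trend)
is the slope, beta_i the intercept, and the trend feature used by all
downstream selection and modelling is

    LRTF_i = LRT_i + beta_i,

i.e. the fitted value at the first fraction.  The fit error ERR_i is the
mean absolute residual by default (the signed mean residual of an OLS fit
is identically zero, so it carries no information); a root-mean-square
alternative is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ValidationError
from .normalize import NormalizedTable

log = logging.getLogger(__name__)

ERR_KINDS = ("absolute", "rmse")


@dataclass(frozen=True)
class TrendFit:
    """OLS trend fit of one (patient, feature) series."""

    slope: float  # LRT, z-units per fraction
    intercept: float  # beta, z-units
    err: float  # fit error, z-units
    lrtf: float  # slope + intercept
    n: int
    patient_id: str | None = None
    feature_id: str | None = None


def fit_feature_trend(
    x: np.ndarray, y: np.ndarray, err_kind: str = "absolute"
) -> TrendFit:
    """Fit one feature series by OLS and reduce it to its trend statistics.

    Parameters
    ----------
    x
        Fraction indices (1-based), at least two distinct values.
    y
        Feature values at those fractions (same length).
    err_kind
        ``"absolute"`` for mean absolute residual, ``"rmse"`` for
        root-mean-square residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValidationError("trend fitting needs at least 2 points")
    if err_kind not in ERR_KINDS:
        raise ValidationError(f"err_kind must be one of {ERR_KINDS}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all fraction indices equal; slope undefined")
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    slope = float((x @ y - n * xbar * ybar) / (x @ x - n * xbar**2))
    intercept = float(ybar - slope * xbar)
    resid = y - (slope * x + intercept)
    err = float(np.abs(resid).mean() if err_kind == "absolute" else np.sqrt((resid**2).mean()))
    return TrendFit(slope=slope, intercept=intercept, err=err,
                    lrtf=slope + intercept, n=n)


@dataclass
class TrendCourse:
    """Trend fits of every (patient, feature) pair up to a given fraction.

    Arrays are (n_patients, n_features); NaN marks pairs without a valid fit
    (constant series, or fewer than two observed fractions <= N).
    """

    upto_fraction: int
    slope: np.ndarray
    intercept: np.ndarray
    err: np.ndarray
    lrtf: np.ndarray
    n_points: np.ndarray
    patients: list
    feature_ids: list[str]
    labels: pd.Series | None = None
    err_kind: str = "absolute"

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.lrtf)

    def lrtf_matrix(self, fill: float = 0.0) -> pd.DataFrame:
        """Patients x features LRTF matrix for the classifiers.

        Invalid entries (constant series) are filled with ``fill``; 0 is the
        value an all-zero normalized series would produce.
        """
        m = np.where(self.valid, self.lrtf, fill)
        return pd.DataFrame(m, index=self.patients, columns=self.feature_ids)

    def mean_fit_error(self) -> float:
        """Mean of ERR over all valid (patient, feature) fits."""
        return float(np.nanmean(np.where(self.valid, self.err, np.nan)))

    def to_frame(self) -> pd.DataFrame:
        n_p, n_feat = self.slope.shape
        df = pd.DataFrame(
            {
                "patient_id": np.repeat(self.patients, n_feat),
                "feature_id": np.tile(self.feature_ids, n_p),
                "n": self.n_points.ravel(),
                "slope": self.slope.ravel(),
                "intercept": self.intercept.ravel(),
                "err": self.err.ravel(),
                "lrtf": self.lrtf.ravel(),
            }
        )
        return df[self.valid.ravel()].reset_index(drop=True)


def fit_course(
    norm: NormalizedTable, upto_fraction: int, err_kind: str = "absolute"
) -> TrendCourse:
    """Fit trends for every patient and feature using fractions 1..N.

    Patients with fewer than two observed fractions <= N are skipped with a
    logged warning (all their fits are NaN); features flagged constant are
    omitted per patient.
    """
    if err_kind not in ERR_KINDS:
        raise ValidationError(f"err_kind must be one of {ERR_KINDS}")
    max_frac = int(norm.fractions.max())
    if not 2 <= upto_fraction <= max_frac:
        raise ValidationError(
            f"upto_fraction must be in [2, {max_frac}], got {upto_fraction}"
        )
    keep = norm.fractions <= upto_fraction
    x = norm.fractions[keep].astype(float)  # (n_f,)
    y = norm.values[:, keep, :]  # (n_p, n_f, n_feat)

    m = ~np.isnan(y)
    y0 = np.where(m, y, 0.0)
    xg = x[None, :, None]
    n = m.sum(axis=1).astype(float)  # (n_p, n_feat)
    sx = (m * xg).sum(axis=1)
    sxx = (m * xg**2).sum(axis=1)
    sy = y0.sum(axis=1)
    sxy = (y0 * xg).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx**2
        slope = (n * sxy - sx * sy) / denom
        intercept = sy / n - slope * sx / n
        fitted = slope[:, None, :] * xg + intercept[:, None, :]
        resid = np.where(m, y0 - fitted, 0.0)
        if err_kind == "absolute":
            err = np.abs(resid).sum(axis=1) / n
        else:
            err = np.sqrt((resid**2).sum(axis=1) / n)

    invalid = (n < 2) | (denom <= 0) | norm.constant
    for arr in (slope, intercept, err):
        arr[invalid] = np.nan
    lrtf = slope + intercept

    skipped = [p for p, bad in zip(norm.patients, (n < 2).all(axis=1)) if bad]
    if skipped:
        log.warning(
            "patients skipped at N=%d (fewer than 2 observed fractions): %s",
            upto_fraction, skipped,
        )
    return TrendCourse(
        upto_fraction=upto_fraction,
        slope=slope,
        intercept=intercept,
        err=err,
        lrtf=lrtf,
        n_points=n.astype(int),
        patients=norm.patients,
        feature_ids=norm.feature_ids,
        labels=norm.labels,
        err_kind=err_kind,
    )
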