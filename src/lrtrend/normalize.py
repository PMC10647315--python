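"""Per-patient Z-score standardization of each feature series.

The trend analysis cares about how a feature *changes* across fractions,
not its absolute magnitude, so each (patient, feature) series is
standardized with that patient's own series mean and sample standard
deviation; gross outliers are bounded at |z| = 3 rather than discarded, so
the fraction grid stays intact for trend fitting.  Constant series (sd = 0)
map to all zeros and are flagged; downstream stages skip them per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LongitudinalFeatureTable


@dataclass
class NormalizedTable:
    """Normalized patient x fraction x feature cube plus audit parameters.

    ``values`` holds clipped z-scores (NaN marks missing scans); ``mean``
    and ``sd`` are the per-(patient, feature) statistics used, exportable
    for audit; ``constant`` flags series with zero variance.
    """

    values: np.ndarray  # (n_patients, n_fractions, n_features)
    patients: list
    fractions: np.ndarray  # sorted fraction indices, 1-based
    feature_ids: list[str]
    mean: np.ndarray  # (n_patients, n_features)
    sd: np.ndarray  # (n_patients, n_features), sample (n-1) sd
    constant: np.ndarray  # bool (n_patients, n_features)
    bound: float
    labels: pd.Series | None = None

    def params_frame(self) -> pd.DataFrame:
        """Normalization parameters as a tidy frame for audit export."""
        n_p, n_feat = self.mean.shape
        return pd.DataFrame(
            {
                "patient_id": np.repeat(self.patients, n_feat),
                "feature_id": np.tile(self.feature_ids, n_p),
                "mean": self.mean.ravel(),
                "sd": self.sd.ravel(),
                "constant": self.constant.ravel(),
            }
        )


def zscore_normalize(
    table: LongitudinalFeatureTable, bound: float = 3.0
) -> NormalizedTable:
    """Standardize each (patient, feature) series and clip to ``[-bound, bound]``.

    z = (value - series mean) / series sample sd, computed over the
    fractions actually observed for that patient.  Constant series are set
    to zero and flagged instead of raising.
    """
    if bound <= 0:
        raise ValidationError("bound must be positive")
    cube, patients, fractions, feature_ids = table.to_cube()
    n_obs = np.sum(~np.isnan(cube), axis=1)  # (n_p, n_feat)
    if (n_obs < 2).any():
        n_bad = int((n_obs < 2).sum())
        raise ValidationError(
            f"{n_bad} (patient, feature) series have < 2 observations"
        )
    mean = np.nanmean(cube, axis=1)
    sd = np.nanstd(cube, axis=1, ddof=1)
    # a constant series can yield sd ~ 1 ulp instead of 0 (mean round-off),
    # so flag on the exact range as well as a relative sd tolerance
    rng_zero = np.nanmax(cube, axis=1) == np.nanmin(cube, axis=1)
    constant = rng_zero | (sd <= 1e-13 * (np.abs(mean) + 1.0))
    sd = np.where(constant, 0.0, sd)
    safe_sd = np.where(constant, 1.0, sd)
    z = (cube - mean[:, None, :]) / safe_sd[:, None, :]
    z[np.broadcast_to(constant[:, None, :], z.shape)] = 0.0
    np.clip(z, -bound, bound, out=z)
    return NormalizedTable(
        values=z,
        patients=patients,
        fractions=fractions,
        feature_ids=feature_ids,
        mean=mean,
        sd=sd,
        constant=constant,
        bound=bound,
        labels=table.labels,
    )
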