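"""Synthetic longitudinal cohort simulator.

Emulates a radiotherapy cohort observed with one volumetric scan per daily
treatment fraction: each patient carries a per-feature linear trend across
fractions, responders and non-responders differ in the mean trend of an
informative feature subset, and everything else is noise.  This is exactly
the generative structure the trend-fitting stage assumes (feature value =
intercept + slope x fraction + noise), so every downstream stage of the
framework can be exercised end to end with known ground truth.

Defaults mirror the study conditions: 30 patients x 28 fractions (840 scans)
x 1688 features, with 14/30 responders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import NON_RESPONDER, RESPONDER, LongitudinalFeatureTable
from .schema import FeatureSchema, build_default_schema


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Slopes are in raw feature units per fraction; ``noise_sd`` is the
    per-scan additive Gaussian noise scale in the same units.  Informative
    features carry a mean slope difference of ``effect_slope_mean`` between
    responders and non-responders; all other slopes have zero mean.
    """

    n_patients: int = 30
    n_fractions: int = 28
    n_features: int = 1688
    fraction_responders: float = 14 / 30
    effect_slope_mean: float = 0.1
    effect_slope_sd: float = 0.02
    n_informative: int = 40
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0
    region: str = "PTV"

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.n_fractions < 2:
            raise ConfigurationError("n_fractions must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0.0 <= self.fraction_responders <= 1.0:
            raise ConfigurationError("fraction_responders must be in [0, 1]")
        if not 0 <= self.n_informative <= self.n_features:
            raise ConfigurationError("n_informative must be in [0, n_features]")
        for name in ("noise_sd", "effect_slope_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("missing_rate", "outlier_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """True generative parameters of a simulated cohort."""

    labels: pd.Series  # patient_id -> responder / non-responder
    slopes: np.ndarray  # (n_patients, n_features) true slopes
    intercepts: np.ndarray  # (n_patients, n_features) true intercepts
    informative_idx: np.ndarray  # indices into the feature axis
    feature_ids: list[str] = field(default_factory=list)
    patients: list[str] = field(default_factory=list)

    @property
    def informative_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.informative_idx]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "informative_idx": self.informative_idx.tolist(),
            "feature_ids": self.feature_ids,
            "patients": self.patients,
        }
        Path(path).write_text(json.dumps(payload))


def _feature_ids(config: CohortConfig) -> tuple[list[str], FeatureSchema | None]:
    schema = build_default_schema(config.region)
    if config.n_features == schema.n_features:
        return schema.feature_ids(), schema
    # reduced feature panels (for fast experiments) use generic ids
    return [f"sim_{k:05d}" for k in range(1, config.n_features + 1)], None


def simulate_cohort(config: CohortConfig) -> tuple[LongitudinalFeatureTable, GroundTruth]:
    """Simulate a longitudinal feature table plus its ground truth.

    Fully reproducible given ``config.seed``.  Fractions 1 and 2 are never
    dropped by the missing-scan process so that every patient supports a
    trend fit and has a day-1 reference.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p, n_f, n_feat = config.n_patients, config.n_fractions, config.n_features

    patients = [f"P{k:03d}" for k in range(1, n_p + 1)]
    n_resp = ceil(n_p * config.fraction_responders)
    labels = pd.Series(
        [RESPONDER] * n_resp + [NON_RESPONDER] * (n_p - n_resp),
        index=pd.Index(patients, name="patient_id"),
        name="label",
    )

    informative_idx = np.sort(rng.choice(n_feat, size=config.n_informative, replace=False))
    slopes = rng.normal(0.0, config.effect_slope_sd, size=(n_p, n_feat))
    # responders get the group-mean slope shift on informative features only
    slopes[:n_resp][:, informative_idx] += config.effect_slope_mean
    intercepts = rng.normal(0.0, 1.0, size=(n_p, n_feat))

    fractions = np.arange(1, n_f + 1)
    cube = intercepts[:, None, :] + slopes[:, None, :] * fractions[None, :, None]
    truth_cube = cube.copy()
    cube += rng.normal(0.0, config.noise_sd, size=cube.shape)

    if config.outlier_rate > 0:
        mask = rng.random(cube.shape) < config.outlier_rate
        signs = rng.choice([-1.0, 1.0], size=cube.shape)
        cube[mask] = (truth_cube + signs * 10.0 * config.noise_sd)[mask]

    present = rng.random((n_p, n_f)) >= config.missing_rate
    present[:, :2] = True

    feature_ids, schema = _feature_ids(config)
    p_grid, x_grid = np.nonzero(present)
    records = pd.DataFrame(
        {
            "patient_id": np.repeat([patients[i] for i in p_grid], n_feat),
            "fraction": np.repeat(fractions[x_grid], n_feat),
            "feature_id": np.tile(feature_ids, len(p_grid)),
            "value": cube[p_grid, x_grid, :].ravel(),
        }
    )
    table = LongitudinalFeatureTable(
        data=records, schema=schema, labels=labels
    )
    truth = GroundTruth(
        labels=labels,
        slopes=slopes,
        intercepts=intercepts,
        informative_idx=informative_idx,
        feature_ids=feature_ids,
        patients=patients,
    )
    return table, truth
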