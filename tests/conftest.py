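import numpy as np
import pandas as pd
import pytest

from lrtrend import CohortConfig, LongitudinalFeatureTable, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8 patients x 12 fractions x 40 features, moderate noise."""
    cfg = CohortConfig(
        n_patients=8, n_fractions=12, n_features=40, n_informative=8,
        fraction_responders=0.5, noise_sd=0.2, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise separable cohort: 6 patients x 28 fractions x 20 features."""
    cfg = CohortConfig(
        n_patients=6, n_fractions=28, n_features=20, n_informative=6,
        fraction_responders=0.5, noise_sd=0.0, effect_slope_mean=0.15, seed=5,
    )
    return simulate_cohort(cfg)


def make_table(values: dict, labels: dict | None = None) -> LongitudinalFeatureTable:
    """Build a table from {patient: {feature: series over fractions 1..n}}."""
    rows = []
    for pid, feats in values.items():
        for fid, series in feats.items():
            for j, v in enumerate(series, start=1):
                if v is not None:
                    rows.append((pid, j, fid, float(v)))
    lab = None
    if labels is not None:
        lab = pd.Series(labels, name="label")
        lab.index.name = "patient_id"
    return LongitudinalFeatureTable(
        data=pd.DataFrame(rows, columns=["patient_id", "fraction", "feature_id", "value"]),
        labels=lab,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
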