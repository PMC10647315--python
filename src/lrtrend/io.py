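"""Longitudinal feature-table container and CSV I/O.

The canonical on-disk form is a long (tidy) CSV with columns
``patient_id,fraction,feature_id,value`` — one row per scan feature — plus a
labels CSV ``patient_id,label[,score]``.  Long form is robust to missing
fractions; wide patient x fraction x feature cubes are in-memory views.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError
from .schema import FeatureSchema

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass
class LongitudinalFeatureTable:
    """Per-patient, per-fraction feature values with labels attached.

    ``data`` holds the long-format records; ``labels`` maps patient_id to
    ``"responder"`` / ``"non-responder"``; ``scores`` optionally maps
    patient_id to a 0-3 response score.
    """

    data: pd.DataFrame
    schema: FeatureSchema | None = None
    labels: pd.Series | None = None
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -------------------------------------------------------
    @property
    def patients(self) -> list:
        return sorted(self.data["patient_id"].unique())

    @property
    def feature_ids(self) -> list[str]:
        if self.schema is not None:
            return self.schema.feature_ids()
        return sorted(self.data["feature_id"].unique())

    @property
    def max_fraction(self) -> int:
        return int(self.data["fraction"].max())

    @property
    def n_scans(self) -> int:
        """Number of (patient, fraction) scan records."""
        return len(self.data[["patient_id", "fraction"]].drop_duplicates())

    def label_vector(self, patients: list | None = None) -> np.ndarray:
        """Binary labels (1 = responder) aligned with ``patients``."""
        if self.labels is None:
            raise ValidationError("table has no labels attached")
        patients = self.patients if patients is None else patients
        return np.asarray([1 if self.labels[p] == RESPONDER else 0 for p in patients])

    def validate(self) -> None:
        required = {"patient_id", "fraction", "feature_id", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"feature table missing columns: {sorted(missing)}")
        frac = self.data["fraction"]
        if (frac < 1).any() or (frac != frac.astype(int)).any():
            raise ValidationError("fraction indices must be integers >= 1")
        dup = self.data.duplicated(["patient_id", "fraction", "feature_id"])
        if dup.any():
            rows = self.data.loc[dup, ["patient_id", "fraction", "feature_id"]].head()
            raise IntegrityError(
                f"duplicate (patient, fraction, feature) records, e.g.\n{rows}"
            )
        if self.schema is not None:
            known = set(self.schema.feature_ids())
            unknown = set(self.data["feature_id"].unique()) - known
            if unknown:
                raise SchemaError(
                    f"{len(unknown)} feature_ids not in schema, e.g. "
                    f"{sorted(unknown)[:5]}"
                )
        n_frac = self.data.groupby("patient_id")["fraction"].nunique()
        short = n_frac[n_frac < 2]
        if len(short):
            raise ValidationError(
                "patients with < 2 distinct fractions (trend fitting needs >= 2 "
                f"points): {list(short.index)}"
            )
        if self.labels is not None:
            missing_lab = set(self.patients) - set(self.labels.index)
            if missing_lab:
                raise ValidationError(f"patients without labels: {sorted(missing_lab)}")
            bad = set(self.labels.unique()) - {RESPONDER, NON_RESPONDER}
            if bad:
                raise ValidationError(f"unknown label values: {sorted(bad)}")

    # -- wide views ------------------------------------------------------
    def to_cube(self) -> tuple[np.ndarray, list, np.ndarray, list[str]]:
        """Return ``(values, patients, fractions, feature_ids)``.

        ``values`` has shape (n_patients, n_fractions, n_features) with NaN
        for missing scans; ``fractions`` is the sorted array of fraction
        indices present anywhere in the table.
        """
        patients = self.patients
        fractions = np.sort(self.data["fraction"].unique())
        feature_ids = self.feature_ids
        p_idx = {p: i for i, p in enumerate(patients)}
        x_idx = {x: i for i, x in enumerate(fractions)}
        f_idx = {f: i for i, f in enumerate(feature_ids)}
        cube = np.full((len(patients), len(fractions), len(feature_ids)), np.nan)
        cube[
            self.data["patient_id"].map(p_idx).to_numpy(),
            self.data["fraction"].map(x_idx).to_numpy(),
            self.data["feature_id"].map(f_idx).to_numpy(),
        ] = self.data["value"].to_numpy()
        return cube, patients, fractions.astype(int), feature_ids


def write_table(table: LongitudinalFeatureTable, path: str | Path) -> None:
    """Write the long-format feature CSV (full float precision)."""
    out = table.data[["patient_id", "fraction", "feature_id", "value"]]
    out.to_csv(path, index=False)  # default float repr is shortest round-trip


def read_table(
    path: str | Path,
    schema: FeatureSchema | None = None,
    labels_path: str | Path | None = None,
) -> LongitudinalFeatureTable:
    """Read and validate a long-format feature CSV (optionally with labels)."""
    data = pd.read_csv(path, float_precision="round_trip")
    labels = scores = None
    if labels_path is not None:
        labels, scores = read_labels(labels_path)
    return LongitudinalFeatureTable(data=data, schema=schema, labels=labels, scores=scores)


def write_labels(
    labels: pd.Series, path: str | Path, scores: pd.Series | None = None
) -> None:
    df = pd.DataFrame({"patient_id": labels.index, "label": labels.values})
    if scores is not None:
        df["score"] = scores.reindex(labels.index).values
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    df = pd.read_csv(path)
    if not {"patient_id", "label"} <= set(df.columns):
        raise ValidationError("labels file must have columns patient_id,label[,score]")
    if df["patient_id"].duplicated().any():
        raise IntegrityError("duplicate patient_id in labels file")
    labels = df.set_index("patient_id")["label"]
    scores = df.set_index("patient_id")["score"] if "score" in df.columns else None
    return labels, scores


def map_radiomics_export(
    df: pd.DataFrame, schema: FeatureSchema, name_map: dict[str, str]
) -> pd.DataFrame:
    """Adapter for a standard radiomics-library CSV export.

    ``df`` is a wide per-scan table (one row per (patient_id, fraction), one
    column per extractor feature name); ``name_map`` maps extractor column
    names to schema feature_ids.  Returns long-format records ready for
    :class:`LongitudinalFeatureTable`.  Voxel-level extraction itself is out
    of scope — only the column-name contract is handled here.
    """
    known = set(schema.feature_ids())
    bad = [v for v in name_map.values() if v not in known]
    if bad:
        raise SchemaError(f"name_map targets not in schema: {bad[:5]}")
    keep = df[["patient_id", "fraction", *name_map.keys()]].rename(columns=name_map)
    long = keep.melt(
        id_vars=["patient_id", "fraction"], var_name="feature_id", value_name="value"
    )
    return long.dropna(subset=["value"]).reset_index(drop=True)
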