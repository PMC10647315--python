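"""Consistency QC for per-fraction rigid-registration transforms.

Daily scans are rigidly registered to the planning image; registration
itself is an external, pluggable step (mutual-information rigid registration
is available in established toolkits).  What this module audits is the
*consistency* of the resulting six rigid parameters across the course:
every fraction's transform is compared parameter-wise against the manually
verified day-1 transform, and a fraction whose relative deviation on any
parameter exceeds the threshold (default 5%) is flagged for manual review.

Relative deviation is undefined for a near-zero day-1 parameter, so the
denominator uses ``max(|day-1 value|, floor)`` with floors of 1 mm for
translations and 1 degree for rotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RegistrationReferenceError, ValidationError

PARAMS = ("tx", "ty", "tz", "rx", "ry", "rz")
TRANSLATION_FLOOR_MM = 1.0
ROTATION_FLOOR_DEG = 1.0


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid transform for one fraction's registration."""

    patient_id: str
    fraction: int
    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValidationError("fraction_index must be >= 1")
        vals = [getattr(self, p) for p in PARAMS]
        if not np.all(np.isfinite(vals)):
            raise ValidationError(
                f"non-finite transform parameters for {self.patient_id} "
                f"fraction {self.fraction}"
            )

    def params(self) -> np.ndarray:
        return np.asarray([getattr(self, p) for p in PARAMS], dtype=float)


@dataclass
class QCReport:
    """Per-fraction QC verdicts against the day-1 reference."""

    patient_id: str
    threshold: float
    fractions: list[int]
    deviations: pd.DataFrame  # index fraction, columns PARAMS
    status: dict[int, str] = field(default_factory=dict)  # pass / warn

    @property
    def warned_fractions(self) -> list[int]:
        return [f for f in self.fractions if self.status[f] == "warn"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patient_id": self.patient_id,
            "threshold": self.threshold,
            "status": {str(k): v for k, v in self.status.items()},
            "deviations": {
                str(f): dict(zip(PARAMS, row))
                for f, row in zip(self.deviations.index, self.deviations.values.tolist())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def log_lines(self) -> list[str]:
        lines = [
            f"registration QC for {self.patient_id} (threshold {self.threshold:.0%})"
        ]
        for f in self.fractions:
            worst = self.deviations.loc[f].max()
            lines.append(f"  fraction {f:>3}: {self.status[f]:<4} (max deviation {worst:.3f})")
        return lines


def check_consistency(
    transforms: list[RigidTransform], threshold: float = 0.05
) -> QCReport:
    """Flag fractions whose transform deviates > ``threshold`` from day 1.

    For each fraction j > 1 and each of the six parameters p, the relative
    deviation is ``|p_j - p_1| / max(|p_1|, floor)``; the fraction warns if
    any parameter exceeds the threshold.  Fraction 1 always passes.
    """
    if not transforms:
        raise ValidationError("no transforms supplied")
    transforms = sorted(transforms, key=lambda t: t.fraction)
    if transforms[0].fraction != 1:
        raise RegistrationReferenceError(
            f"day-1 transform missing for {transforms[0].patient_id}"
        )
    ref = transforms[0].params()
    floors = np.asarray([TRANSLATION_FLOOR_MM] * 3 + [ROTATION_FLOOR_DEG] * 3)
    denom = np.maximum(np.abs(ref), floors)

    rows, status = {}, {}
    for t in transforms:
        dev = np.abs(t.params() - ref) / denom
        if t.fraction == 1:
            dev = np.zeros(6)
        rows[t.fraction] = dev
        status[t.fraction] = "warn" if (dev > threshold).any() else "pass"
    deviations = pd.DataFrame.from_dict(rows, orient="index", columns=list(PARAMS))
    deviations.index.name = "fraction"
    return QCReport(
        patient_id=transforms[0].patient_id,
        threshold=threshold,
        fractions=sorted(rows),
        deviations=deviations,
        status=status,
    )


def read_transforms(path: str | Path) -> dict[str, list[RigidTransform]]:
    """Read a transforms CSV (patient_id,fraction,tx,ty,tz,rx,ry,rz)."""
    df = pd.read_csv(path)
    needed = {"patient_id", "fraction", *PARAMS}
    if not needed <= set(df.columns):
        raise ValidationError(f"transforms CSV must have columns {sorted(needed)}")
    out: dict[str, list[RigidTransform]] = {}
    for row in df.itertuples(index=False):
        t = RigidTransform(
            patient_id=str(row.patient_id),
            fraction=int(row.fraction),
            tx=row.tx, ty=row.ty, tz=row.tz, rx=row.rx, ry=row.ry, rz=row.rz,
        )
        out.setdefault(t.patient_id, []).append(t)
    return out
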