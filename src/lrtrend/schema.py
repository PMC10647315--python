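"""Feature schema for longitudinal radiomic feature tables.

The default schema mirrors a standard radiomics layout: 14 shape descriptors
computed once on the untransformed image, plus 93 features (first-order and
five texture families) computed on each of 18 image types — the original
image, four Laplacian-of-Gaussian filtered images (sigma 0.6/1.0/3.0/5.0 mm),
eight wavelet band combinations, and gradient, square-root, logarithm,
exponential and square transforms.  Totals: 18 image types x 93 features
+ 14 shape features = 1688 features per region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError

LOG_SIGMAS = (0.6, 1.0, 3.0, 5.0)

#: High/low-pass band combinations of a 3-D separable wavelet decomposition.
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

SIMPLE_TRANSFORMS = ("gradient", "squareroot", "logarithm", "exponential", "square")

#: Per-image feature families and their sizes (93 features per image type).
FEATURE_FAMILIES = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}

N_SHAPE_FEATURES = 14


def _image_type_names() -> list[str]:
    names = ["original"]
    names += [f"log-sigma-{s:g}" for s in LOG_SIGMAS]
    names += [f"wavelet-{b}" for b in WAVELET_BANDS]
    names += list(SIMPLE_TRANSFORMS)
    return names


@dataclass(frozen=True)
class FeatureSchema:
    """Named layout of the feature vector extracted per scan.

    Parameters
    ----------
    region
        Contoured region the features were computed from, ``"GTV"`` or
        ``"PTV"``.
    image_types
        Names of the image transforms (18 in the default layout).
    families
        Mapping family name -> feature count per transformed image.
    n_shape
        Number of shape descriptors (original image only).
    """

    region: str
    image_types: tuple[str, ...] = field(default_factory=lambda: tuple(_image_type_names()))
    families: dict[str, int] = field(default_factory=lambda: dict(FEATURE_FAMILIES))
    n_shape: int = N_SHAPE_FEATURES

    @property
    def features_per_image(self) -> int:
        return sum(self.families.values())

    @property
    def n_features(self) -> int:
        return len(self.image_types) * self.features_per_image + self.n_shape

    def feature_ids(self) -> list[str]:
        """Stable feature identifiers: ``<imagetype>_<family>_<index>`` and
        ``shape_<index>`` (1-based indices)."""
        ids = []
        for img in self.image_types:
            for fam, count in self.families.items():
                ids.extend(f"{img}_{fam}_{k}" for k in range(1, count + 1))
        ids.extend(f"shape_{k}" for k in range(1, self.n_shape + 1))
        return ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region": self.region,
            "image_types": list(self.image_types),
            "families": self.families,
            "n_shape": self.n_shape,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            region=payload["region"],
            image_types=tuple(payload["image_types"]),
            families=dict(payload["families"]),
            n_shape=int(payload["n_shape"]),
        )


def build_default_schema(region: str = "PTV") -> FeatureSchema:
    """Build the default 1688-feature schema for a region.

    Parameters
    ----------
    region
        ``"GTV"`` or ``"PTV"``.
    """
    if region not in ("GTV", "PTV"):
        raise SchemaError(f"region must be 'GTV' or 'PTV', got {region!r}")
    return FeatureSchema(region=region)
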