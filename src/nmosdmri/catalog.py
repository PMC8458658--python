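"""Registry of MRI lesion types and imaging features.

The differential-diagnosis analysis implemented by this package rests on a
fixed taxonomy of lesion types and imaging criteria: 34 features with a
potential NMOSD association, 19 with a potential MS association, and 25
neutral anatomical counterparts.  Every other module keys patients, scores
and classifiers against the ``feature_id`` tokens defined here.

The default registry ships as a CSV data file so the taxonomy can be audited
and extended without touching code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "REGIONS",
    "MODALITIES",
    "ASSOCIATIONS",
    "LesionFeature",
    "FeatureCatalog",
    "load_default_catalog",
    "validate_feature_refs",
]

REGIONS = ("optic_pathway", "brain_global", "supratentorial", "infratentorial", "spinal_cord")
MODALITIES = ("T2", "Gd", "T1_hypointense", "criterion", "composite")
ASSOCIATIONS = ("NMOSD", "MS", "neutral")

#: Mapping from the anatomical region of a feature to the scan region(s)
#: whose imaging can evaluate it.  Optic-pathway features are visible on
#: dedicated orbital imaging and on standard brain MRI.
SCAN_REGIONS_FOR_FEATURE_REGION = {
    "optic_pathway": ("orbits", "brain"),
    "brain_global": ("brain",),
    "supratentorial": ("brain",),
    "infratentorial": ("brain",),
    "spinal_cord": ("spine",),
}

_COLUMNS = ["feature_id", "name", "region", "modality", "disease_association", "scope", "definition_text"]


@dataclass(frozen=True)
class LesionFeature:
    """One lesion type or imaging criterion in the registry.

    ``scope`` distinguishes features evaluated only on a patient's first
    brain imaging (the normal-brain, Paty and Barkhof criteria) from
    ordinary features assessed on both first and any subsequent imaging.
    """

    feature_id: str
    name: str
    region: str
    modality: str
    disease_association: str
    scope: str = "first_and_ever"
    definition_text: str = ""

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for {self.feature_id}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r} for {self.feature_id}")
        if self.disease_association not in ASSOCIATIONS:
            raise ValueError(
                f"unknown association {self.disease_association!r} for {self.feature_id}"
            )
        if self.scope not in ("first_only", "first_and_ever"):
            raise ValueError(f"unknown scope {self.scope!r} for {self.feature_id}")


class FeatureCatalog:
    """Ordered, unique-keyed collection of :class:`LesionFeature`."""

    def __init__(self, features: Iterable[LesionFeature]):
        self._features: dict[str, LesionFeature] = {}
        for feat in features:
            if feat.feature_id in self._features:
                raise ValueError(f"duplicate feature_id {feat.feature_id!r}")
            self._features[feat.feature_id] = feat

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[LesionFeature]:
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureCatalog):
            return NotImplemented
        return list(self) == list(other)

    def lookup(self, feature_id: str) -> LesionFeature:
        try:
            return self._features[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    @property
    def feature_ids(self) -> list[str]:
        return list(self._features)

    def by_association(self, association: str) -> list[LesionFeature]:
        if association not in ASSOCIATIONS:
            raise ValueError(f"unknown association {association!r}")
        return [f for f in self if f.disease_association == association]

    def by_region(self, region: str) -> list[LesionFeature]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [f for f in self if f.region == region]

    def first_only_ids(self) -> list[str]:
        return [f.feature_id for f in self if f.scope == "first_only"]

    def scan_regions(self, feature_id: str) -> tuple[str, ...]:
        """Scan regions whose imaging can assess ``feature_id``."""
        return SCAN_REGIONS_FOR_FEATURE_REGION[self.lookup(feature_id).region]

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": f.feature_id,
                "name": f.name,
                "region": f.region,
                "modality": f.modality,
                "disease_association": f.disease_association,
                "scope": f.scope,
                "definition_text": f.definition_text,
            }
            for f in self
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureCatalog":
        missing = set(_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"catalog table missing columns: {sorted(missing)}")
        frame = frame.fillna({"definition_text": ""})
        return cls(
            LesionFeature(
                feature_id=row.feature_id,
                name=row.name,
                region=row.region,
                modality=row.modality,
                disease_association=row.disease_association,
                scope=row.scope,
                definition_text=row.definition_text,
            )
            for row in frame.itertuples(index=False)
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureCatalog":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


def load_default_catalog() -> FeatureCatalog:
    """Load the built-in lesion/feature registry.

    The default registry holds 34 features with potential NMOSD association,
    19 with potential MS association, and the neutral anatomical
    counterparts.  Features that a given cohort never exhibits remain in the
    registry: absence is a property of data, not of the taxonomy.
    """
    text = resources.files("nmosdmri.data").joinpath("feature_catalog.csv").read_text()
    return FeatureCatalog.from_frame(pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False))


def validate_feature_refs(catalog: FeatureCatalog, feature_ids: Iterable[str]) -> list[str]:
    """Return the ids absent from ``catalog``, preserving input order."""
    return [fid for fid in feature_ids if fid not in catalog]
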