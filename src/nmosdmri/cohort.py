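"""Per-patient MRI data model: scans, lesions, and first/ever aggregation.

A patient is a diagnosis label plus a dated inventory of brain, spine and
orbital scans.  Each scan carries binary feature observations, lesion
counts, and (for spine scans) explicit cord-lesion spans on a 44-level
hemi-vertebral coordinate system (level 1 = superior half of C1, level 44 =
inferior half of L3).

Analysis happens on a per-patient basis: a feature is "first"-present if it
is seen on the earliest scan of the relevant region, and "ever"-present if
seen on any scan.  When a patient has no imaging of a region, every feature
of that region is *missing* (not absent) and the patient drops out of the
denominators downstream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, SCAN_REGIONS_FOR_FEATURE_REGION

__all__ = [
    "N_CORD_LEVELS",
    "TOTAL_T2_KEY",
    "COUNT_KEYS",
    "CordLesion",
    "ScanRecord",
    "PatientRecord",
    "FeatureMatrix",
    "classify_scan_timing",
    "cord_lesion_length_class",
    "derive_cord_features",
    "resolve_wm_lesion_class",
    "build_feature_matrix",
    "write_cohort",
    "read_cohort",
]

#: Hemi-vertebral levels from the superior half of C1 to the inferior half of L3.
N_CORD_LEVELS = 44

#: Pseudo-feature key under which the total brain T2 lesion count of a scan
#: is recorded in ``ScanRecord.lesion_counts``.  It is a per-scan summary
#: quantity, not a catalog feature.
TOTAL_T2_KEY = "brain_T2_total"

#: Count keys consumed by the rule-based imaging criteria.
COUNT_KEYS = (TOTAL_T2_KEY, "periventricular_T2", "juxtacortical_T2", "infratentorial_T2")

SCAN_REGIONS = ("brain", "spine", "orbits")

#: Precedence order for assigning a white-matter lesion meeting several
#: location definitions to a single class.  Tumefactive takes precedence
#: over everything; among the rest, earlier in this tuple wins.
WM_CLASS_PREFERENCE = ("periventricular", "cortical", "juxtacortical", "subcortical")

AXIAL_CLASSES = ("central", "partial", "whole", "unknown")


@dataclass(frozen=True)
class CordLesion:
    """One contiguous spinal-cord lesion span.

    ``start_level``/``end_level`` are inclusive 1-based hemi-vertebral
    levels; span length in hemi-levels is ``end - start + 1``.  Contiguity
    is part of the definition: separately recorded lesions are never merged,
    even if adjacent (apparent coalescence across serial imaging is the
    upstream reader's call).
    """

    start_level: int
    end_level: int
    axial_class: str = "unknown"
    gd_enhancing: bool = False
    swelling: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start_level <= self.end_level <= N_CORD_LEVELS):
            raise ValueError(
                f"cord lesion span must satisfy 1 <= start <= end <= {N_CORD_LEVELS}, "
                f"got [{self.start_level}, {self.end_level}]"
            )
        if self.axial_class not in AXIAL_CLASSES:
            raise ValueError(f"unknown axial class {self.axial_class!r}")

    @property
    def length(self) -> int:
        return self.end_level - self.start_level + 1


def cord_lesion_length_class(lesion: CordLesion) -> str:
    """Classify a cord lesion as ``"long"`` or ``"short"``.

    A lesion is longitudinally extensive ("long") when it spans three or
    more vertebral bodies, i.e. at least 6 adjacent hemi-vertebral levels;
    anything shorter is "short".  The two classes partition all lesions.
    """
    return "long" if lesion.length >= 6 else "short"


def derive_cord_features(cord_lesions: Sequence[CordLesion]) -> dict[str, bool]:
    """Binary cord features implied by a list of lesion spans.

    A whole (axial) cord lesion involves all eight central and peripheral
    quadrants and therefore also satisfies the central-cord definition.
    """
    any_long = any(cord_lesion_length_class(les) == "long" for les in cord_lesions)
    any_short = any(cord_lesion_length_class(les) == "short" for les in cord_lesions)
    any_whole = any(les.axial_class == "whole" for les in cord_lesions)
    any_central = any(les.axial_class in ("central", "whole") for les in cord_lesions)
    any_partial = any(les.axial_class == "partial" for les in cord_lesions)
    return {
        "longitudinal_cord_T2": any_long,
        "short_cord_T2": any_short,
        "central_cord_T2": any_central,
        "partial_cord_T2": any_partial,
        "whole_cord_T2": any_whole,
        "cord_gd": any(les.gd_enhancing for les in cord_lesions),
        "cord_swelling": any(les.swelling for les in cord_lesions),
    }


def resolve_wm_lesion_class(candidate_classes: Iterable[str]) -> str:
    """Resolve a white-matter lesion meeting several definitions to one class.

    Tumefactive lesions keep that label regardless of location; otherwise the
    preference order periventricular > cortical > juxtacortical > subcortical
    applies.
    """
    classes = set(candidate_classes)
    if not classes:
        raise ValueError("candidate class set must be non-empty")
    unknown = classes - set(WM_CLASS_PREFERENCE) - {"tumefactive"}
    if unknown:
        raise ValueError(f"unknown white-matter lesion classes: {sorted(unknown)}")
    if "tumefactive" in classes:
        return "tumefactive"
    for cls in WM_CLASS_PREFERENCE:
        if cls in classes:
            return cls
    raise AssertionError("unreachable")


@dataclass
class ScanRecord:
    """One MRI examination of one region on one date."""

    scan_id: str
    region_imaged: str
    scan_date: _dt.date
    gadolinium_given: bool = False
    feature_presence: dict[str, bool] = field(default_factory=dict)
    lesion_counts: dict[str, int] = field(default_factory=dict)
    cord_lesions: list[CordLesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_imaged not in SCAN_REGIONS:
            raise ValueError(f"unknown scan region {self.region_imaged!r}")
        if self.cord_lesions and self.region_imaged != "spine":
            raise ValueError("cord lesions recorded on a non-spine scan")
        for fid, count in self.lesion_counts.items():
            if count < 0:
                raise ValueError(f"negative lesion count for {fid!r}")
            # A recorded count implies the lesion type is present.
            if count > 0 and fid != TOTAL_T2_KEY:
                self.feature_presence.setdefault(fid, True)
                if not self.feature_presence[fid]:
                    raise ValueError(f"count > 0 but presence False for {fid!r}")

    def effective_presence(self) -> dict[str, bool]:
        """Feature presence including features implied by cord-lesion spans."""
        presence = dict(self.feature_presence)
        if self.region_imaged == "spine" and self.cord_lesions:
            for fid, val in derive_cord_features(self.cord_lesions).items():
                presence[fid] = presence.get(fid, False) or val
        return presence


@dataclass
class PatientRecord:
    """One subject: diagnosis, relapse history and scan inventory."""

    patient_id: str
    diagnosis: str
    symptom_onset_date: _dt.date | None = None
    relapse_dates: list[_dt.date] = field(default_factory=list)
    scans: list[ScanRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diagnosis not in ("NMOSD", "MS"):
            raise ValueError(f"diagnosis must be NMOSD or MS, got {self.diagnosis!r}")
        self.scans = sorted(self.scans, key=lambda s: (s.scan_date, s.scan_id))

    def scans_of(self, *regions: str) -> list[ScanRecord]:
        return [s for s in self.scans if s.region_imaged in regions]


def classify_scan_timing(scan_date, relapse_dates) -> str:
    """Label a scan as relapse-related or remission imaging.

    A scan is relapse imaging when a documented relapse falls in the window
    from 90 days before to 30 days after the scan (both ends inclusive).
    Dates may be calendar dates or plain day numbers.
    """
    for relapse in relapse_dates:
        delta = scan_date - relapse
        days = delta.days if isinstance(delta, _dt.timedelta) else delta
        if -30 <= days <= 90:
            return "relapse"
    return "remission"


@dataclass
class FeatureMatrix:
    """Patient x feature aggregation of a cohort.

    ``first`` and ``ever`` hold presence as 1.0/0.0 with NaN marking
    "no imaging of the relevant region"; ``max_count`` holds the per-patient
    maximum lesion count over all scans and ``first_count`` the counts on
    the first scan of the relevant region (count columns exist only for the
    count-bearing keys).  ``diagnosis`` maps patient_id to its class label.
    """

    first: pd.DataFrame
    ever: pd.DataFrame
    max_count: pd.DataFrame
    first_count: pd.DataFrame
    diagnosis: pd.Series

    @property
    def patient_ids(self) -> list[str]:
        return list(self.first.index)

    def features_of(self, patient_id: str, which: str = "ever") -> dict[str, float]:
        """One patient's feature vector (values 0.0/1.0/NaN) plus counts.

        Count keys are exposed under ``n_<key>`` names so rule-based
        criteria can read lesion counts alongside binary presences.
        """
        if which not in ("first", "ever"):
            raise ValueError("which must be 'first' or 'ever'")
        presence = getattr(self, which)
        feats = presence.loc[patient_id].to_dict()
        counts = self.first_count if which == "first" else self.max_count
        for key in counts.columns:
            feats[f"n_{key}"] = counts.at[patient_id, key]
        return feats


def _first_scan(scans: list[ScanRecord]) -> ScanRecord:
    return min(scans, key=lambda s: (s.scan_date, s.scan_id))


def build_feature_matrix(
    patients: Sequence[PatientRecord],
    catalog: FeatureCatalog,
    *,
    optic_from_brain: bool = True,
) -> FeatureMatrix:
    """Aggregate per-scan observations into per-patient first/ever calls.

    "First" is resolved per region: the first brain scan for brain features,
    the first spine scan for cord features (brain and spine imaging occur on
    different dates).  Features restricted to first imaging (normal brain,
    Paty, Barkhof) carry their first-scan value as their "ever" value too.
    With ``optic_from_brain`` (default), optic-pathway features are assessed
    on orbital or brain imaging, whichever exists; otherwise orbital imaging
    is required.
    """
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")

    feature_ids = catalog.feature_ids
    first_only = set(catalog.first_only_ids())
    eligible: dict[str, tuple[str, ...]] = {}
    for fid in feature_ids:
        regions = SCAN_REGIONS_FOR_FEATURE_REGION[catalog.lookup(fid).region]
        if not optic_from_brain and catalog.lookup(fid).region == "optic_pathway":
            regions = ("orbits",)
        eligible[fid] = regions

    count_keys = list(COUNT_KEYS)
    first_rows, ever_rows = [], []
    maxc_rows, firstc_rows = [], []
    for patient in patients:
        by_region: dict[str, list[ScanRecord]] = {r: patient.scans_of(r) for r in SCAN_REGIONS}
        presence_cache = {s.scan_id: s.effective_presence() for s in patient.scans}
        first_row: dict[str, float] = {}
        ever_row: dict[str, float] = {}
        for fid in feature_ids:
            scans = [s for region in eligible[fid] for s in by_region[region]]
            if not scans:
                first_row[fid] = np.nan
                ever_row[fid] = np.nan
                continue
            first = _first_scan(scans)
            first_val = float(presence_cache[first.scan_id].get(fid, False))
            first_row[fid] = first_val
            if fid in first_only:
                ever_row[fid] = first_val
            else:
                ever_row[fid] = float(
                    any(presence_cache[s.scan_id].get(fid, False) for s in scans)
                )
        brain_scans = by_region["brain"]
        maxc_row: dict[str, float] = {}
        firstc_row: dict[str, float] = {}
        for key in count_keys:
            if not brain_scans:
                maxc_row[key] = np.nan
                firstc_row[key] = np.nan
            else:
                maxc_row[key] = float(max(s.lesion_counts.get(key, 0) for s in brain_scans))
                firstc_row[key] = float(_first_scan(brain_scans).lesion_counts.get(key, 0))
        first_rows.append(first_row)
        ever_rows.append(ever_row)
        maxc_rows.append(maxc_row)
        firstc_rows.append(firstc_row)

    index = pd.Index(ids, name="patient_id")
    return FeatureMatrix(
        first=pd.DataFrame(first_rows, index=index, columns=feature_ids),
        ever=pd.DataFrame(ever_rows, index=index, columns=feature_ids),
        max_count=pd.DataFrame(maxc_rows, index=index, columns=count_keys),
        first_count=pd.DataFrame(firstc_rows, index=index, columns=count_keys),
        diagnosis=pd.Series([p.diagnosis for p in patients], index=index, name="diagnosis"),
    )


# --------------------------------------------------------------------------
# Cohort table I/O (three RFC-4180 CSV tables: patients, scans, cord lesions)

_DATE_FMT = "%Y-%m-%d"


def _fmt_date(d: _dt.date | None) -> str:
    return "" if d is None else d.strftime(_DATE_FMT)


def _parse_date(s: str) -> _dt.date | None:
    return None if not s else _dt.datetime.strptime(s, _DATE_FMT).date()


def write_cohort(patients: Sequence[PatientRecord], directory: str | Path) -> None:
    """Write a cohort as patients/scans/cord_lesions CSV tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pat_rows = [
        {
            "patient_id": p.patient_id,
            "diagnosis": p.diagnosis,
            "onset_date": _fmt_date(p.symptom_onset_date),
            "relapse_dates": ";".join(_fmt_date(d) for d in p.relapse_dates),
        }
        for p in patients
    ]
    pd.DataFrame(pat_rows, columns=["patient_id", "diagnosis", "onset_date", "relapse_dates"]).to_csv(
        directory / "patients.csv", index=False
    )

    presence_cols: list[str] = []
    count_cols: list[str] = []
    for p in patients:
        for s in p.scans:
            for fid in s.feature_presence:
                if fid not in presence_cols:
                    presence_cols.append(fid)
            for fid in s.lesion_counts:
                if f"n_{fid}" not in count_cols:
                    count_cols.append(f"n_{fid}")
    feature_cols = presence_cols + count_cols
    scan_rows = []
    cord_rows = []
    for p in patients:
        for s in p.scans:
            row: dict[str, object] = {
                "scan_id": s.scan_id,
                "patient_id": p.patient_id,
                "region": s.region_imaged,
                "date": _fmt_date(s.scan_date),
                "gd": int(s.gadolinium_given),
            }
            for fid in presence_cols:
                row[fid] = "" if fid not in s.feature_presence else int(s.feature_presence[fid])
            for col in count_cols:
                fid = col[2:]
                row[col] = "" if fid not in s.lesion_counts else s.lesion_counts[fid]
            scan_rows.append(row)
            for les in s.cord_lesions:
                cord_rows.append(
                    {
                        "scan_id": s.scan_id,
                        "start_level": les.start_level,
                        "end_level": les.end_level,
                        "axial_class": les.axial_class,
                        "gd": int(les.gd_enhancing),
                        "swelling": int(les.swelling),
                    }
                )
    pd.DataFrame(
        scan_rows, columns=["scan_id", "patient_id", "region", "date", "gd"] + feature_cols
    ).to_csv(directory / "scans.csv", index=False)
    pd.DataFrame(
        cord_rows,
        columns=["scan_id", "start_level", "end_level", "axial_class", "gd", "swelling"],
    ).to_csv(directory / "cord_lesions.csv", index=False)


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    pats = pd.read_csv(directory / "patients.csv", dtype=str, keep_default_na=False)
    scans = pd.read_csv(directory / "scans.csv", dtype=str, keep_default_na=False)
    cord_path = directory / "cord_lesions.csv"
    cords = (
        pd.read_csv(cord_path, dtype=str, keep_default_na=False)
        if cord_path.exists()
        else pd.DataFrame(columns=["scan_id", "start_level", "end_level", "axial_class", "gd", "swelling"])
    )

    cords_by_scan: dict[str, list[CordLesion]] = {}
    for row in cords.itertuples(index=False):
        cords_by_scan.setdefault(row.scan_id, []).append(
            CordLesion(
                start_level=int(row.start_level),
                end_level=int(row.end_level),
                axial_class=row.axial_class,
                gd_enhancing=bool(int(row.gd)),
                swelling=bool(int(row.swelling)),
            )
        )

    meta_cols = {"scan_id", "patient_id", "region", "date", "gd"}
    feature_cols = [c for c in scans.columns if c not in meta_cols]
    col_index = {c: i for i, c in enumerate(scans.columns)}
    scans_by_patient: dict[str, list[ScanRecord]] = {}
    for row in scans.itertuples(index=False, name=None):
        presence: dict[str, bool] = {}
        counts: dict[str, int] = {}
        for col in feature_cols:
            raw = row[col_index[col]]
            if raw == "":
                continue
            value = int(raw)
            if col.startswith("n_"):
                counts[col[2:]] = value
            else:
                presence[col] = bool(value)
        scan_id = row[col_index["scan_id"]]
        scans_by_patient.setdefault(row[col_index["patient_id"]], []).append(
            ScanRecord(
                scan_id=scan_id,
                region_imaged=row[col_index["region"]],
                scan_date=_parse_date(row[col_index["date"]]),
                gadolinium_given=bool(int(row[col_index["gd"]])),
                feature_presence=presence,
                lesion_counts=counts,
                cord_lesions=cords_by_scan.get(scan_id, []),
            )
        )

    patients = []
    for row in pats.itertuples(index=False):
        relapses = [_parse_date(tok) for tok in row.relapse_dates.split(";") if tok]
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                diagnosis=row.diagnosis,
                symptom_onset_date=_parse_date(row.onset_date),
                relapse_dates=relapses,
                scans=scans_by_patient.get(row.patient_id, []),
            )
        )
    return patients
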