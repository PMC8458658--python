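import datetime as dt

import pytest

from nmosdmri.catalog import load_default_catalog
from nmosdmri.cohort import CordLesion, PatientRecord, ScanRecord, build_feature_matrix
from nmosdmri.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def default_cohort(catalog):
    """Default-condition synthetic cohort (66 NMOSD / 100 MS), fixed seed."""
    return generate_cohort(CohortSpec(seed=42), catalog)


@pytest.fixture(scope="session")
def default_matrix(catalog, default_cohort):
    return build_feature_matrix(default_cohort, catalog)


def make_patient(patient_id, diagnosis, scans, **kwargs):
    return PatientRecord(patient_id=patient_id, diagnosis=diagnosis, scans=scans, **kwargs)


def brain_scan(scan_id, day, presence=None, counts=None, gd=False):
    return ScanRecord(
        scan_id=scan_id,
        region_imaged="brain",
        scan_date=dt.date(2015, 1, 1) + dt.timedelta(days=day),
        gadolinium_given=gd,
        feature_presence=dict(presence or {}),
        lesion_counts=dict(counts or {}),
    )


def spine_scan(scan_id, day, lesions=(), presence=None):
    return ScanRecord(
        scan_id=scan_id,
        region_imaged="spine",
        scan_date=dt.date(2015, 1, 1) + dt.timedelta(days=day),
        feature_presence=dict(presence or {}),
        cord_lesions=list(lesions),
    )


def lesion(start, end, axial="unknown", gd=False, swelling=False):
    return CordLesion(
        start_level=start, end_level=end, axial_class=axial, gd_enhancing=gd, swelling=swelling
    )
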