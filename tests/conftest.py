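from datetime import date, timedelta

import pytest

from psmaresp.cohort_model import (
    LesionMeasurement,
    PatientRecord,
    ScanRecord,
    Site,
    SurvivalRecord,
    Timepoint,
)

BASELINE_DATE = date(2016, 1, 1)
FOLLOWUP_DATE = date(2016, 7, 1)


def make_lesion(lesion_id="L1", volume=10.0, suv_mean=5.0, suv_max=8.0,
                site=Site.BONE, match_id=None):
    return LesionMeasurement(lesion_id=lesion_id, volume=volume,
                             suv_mean=suv_mean, suv_max=suv_max,
                             site=site, match_id=match_id)


def make_scan(lesions, timepoint=Timepoint.BASELINE, patient_id="P1",
              liver_ref=6.0, scan_date=None):
    if scan_date is None:
        scan_date = BASELINE_DATE if timepoint is Timepoint.BASELINE else FOLLOWUP_DATE
    return ScanRecord(patient_id=patient_id, timepoint=timepoint,
                      scan_date=scan_date, lesions=tuple(lesions),
                      liver_ref_suv=liver_ref)


def make_patient(baseline_lesions, followup_lesions, patient_id="P1",
                 survival=None, treatments=frozenset(), psa=()):
    return PatientRecord(
        patient_id=patient_id,
        baseline=make_scan(baseline_lesions, Timepoint.BASELINE, patient_id),
        followup=make_scan(followup_lesions, Timepoint.FOLLOWUP, patient_id),
        treatments=treatments,
        survival=survival or SurvivalRecord(time=24.0, event=False),
        psa_series=tuple(psa),
    )


def volume_change_patient(baseline_total, followup_matched_total, n_new=0,
                          new_volume_each=1.0):
    """Patient with a single matched lesion plus optional new lesions,
    engineered to hit an exact whole-body volume change."""
    base = [make_lesion("B1", volume=baseline_total)] if baseline_total > 0 else []
    follow = []
    if followup_matched_total > 0:
        follow.append(make_lesion("F1", volume=followup_matched_total, match_id="B1"))
    for i in range(n_new):
        follow.append(make_lesion(f"N{i}", volume=new_volume_each))
    return make_patient(base, follow)


@pytest.fixture
def monthly_psa_series():
    """PSA values at monthly cadence from a fixed scan date."""

    def build(values, start=FOLLOWUP_DATE):
        return [
            (start + timedelta(days=30 * i), float(v)) for i, v in enumerate(values)
        ]

    return build
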