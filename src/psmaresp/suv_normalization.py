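"""Liver-reference SUV normalisation.

Body-weight SUVs overestimate uptake in larger patients.  Dividing every
lesion SUV by the mean SUV of a fixed reference volume in the right liver
lobe of the *same scan* removes a per-scan global scale factor, so the
SUV-based progression criteria downstream become invariant to patient-size
effects.  Volumes are never touched; each timepoint uses its own liver
reference.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal

from .cohort_model import PatientRecord, ScanRecord

__all__ = ["NormalizationError", "liver_normalize", "normalize_patient"]


class NormalizationError(ValueError):
    pass


def liver_normalize(scan: ScanRecord) -> ScanRecord:
    """Divide every lesion's ``suv_mean``/``suv_max`` by the scan's liver
    reference SUV.

    Lesion count, volumes, sites and matching are preserved exactly.  The
    returned scan is marked ``suv_normalized``; normalising an already
    normalised scan is refused to prevent accidental double application.
    """
    if scan.suv_normalized:
        raise NormalizationError(
            f"{scan.patient_id}/{scan.timepoint.value}: scan already normalised"
        )
    if not scan.liver_ref_suv > 0:
        raise NormalizationError(
            f"{scan.patient_id}/{scan.timepoint.value}: invalid liver reference SUV"
        )
    ref = scan.liver_ref_suv
    lesions = tuple(
        replace(lesion, suv_mean=lesion.suv_mean / ref, suv_max=lesion.suv_max / ref)
        for lesion in scan.lesions
    )
    return replace(scan, lesions=lesions, suv_normalized=True)


def normalize_patient(
    patient: PatientRecord, mode: Literal["liver", "none"] = "liver"
) -> PatientRecord:
    """Apply per-scan liver normalisation to both timepoints of a patient.

    ``mode='none'`` returns the patient unchanged (sensitivity analysis on
    raw body-weight SUVs).
    """
    if mode == "none":
        return patient
    if mode != "liver":
        raise NormalizationError(f"unknown normalisation mode: {mode!r}")
    return replace(
        patient,
        baseline=liver_normalize(patient.baseline),
        followup=liver_normalize(patient.followup),
    )
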