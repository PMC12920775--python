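"""Response classification: PPP variants and RECIP 1.0.

Two families of two-timepoint progression criteria are implemented.

**PPP (PSMA PET Progression)** works per lesion: a patient has progressive
disease if at least one new lesion appears at follow-up, or any matched
(existing) lesion grows by at least 30% in the chosen metric.  Three
variants differ only in the metric — lesion volume, SUVmean or SUVmax (the
SUV variants are normally run on liver-normalised uptake).

**RECIP 1.0** works at the patient level on whole-body PSMA-positive tumour
volume (sum of lesion volumes per scan):

====  =======================================================================
CR    complete resolution of uptake (zero follow-up volume, no new lesions)
PD    >= 1 new lesion AND >= 20% increase in total volume
PR    no new lesions AND > 30% reduction in total volume
SD    everything else (including new lesions with >= 30% reduction, and a
      >= 20% increase without new lesions)
====  =======================================================================

Boundary conventions: PPP progression and RECIP-PD use inclusive thresholds
(>= +30%, >= +20%); RECIP-PR requires a strict > 30% reduction, so a change
of exactly -30% is SD.

Patients with zero baseline volume are handled explicitly: any follow-up
lesion is new, the relative volume change is undefined, and growth from
nothing counts as an unbounded increase (so new lesions imply PD).  A
patient with no lesions on either scan has no natural RECIP category and is
reported SD with ``degenerate=True``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from .cohort_model import CriteriaThresholds, PatientRecord, ScanRecord

__all__ = [
    "Metric",
    "Trigger",
    "PPPStatus",
    "RECIP",
    "RECIPCategory",
    "percent_change",
    "detect_new_lesions",
    "classify_ppp",
    "classify_recip",
    "classify_patient",
]


class Metric(str, enum.Enum):
    VOLUME = "volume"
    SUV_MEAN = "suv_mean"
    SUV_MAX = "suv_max"


class Trigger(str, enum.Enum):
    NEW_LESION = "new_lesion"
    LESION_INCREASE = "lesion_increase"
    NONE = "none"


class RECIP(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class PPPStatus:
    metric: Metric
    progressed: bool
    trigger: Trigger
    triggering_lesion_id: str | None = None

    def __post_init__(self) -> None:
        if not self.progressed and self.trigger is not Trigger.NONE:
            raise ValueError("non-progressed status cannot carry a trigger")


@dataclass(frozen=True)
class RECIPCategory:
    category: RECIP
    total_volume_baseline: float
    total_volume_followup: float
    volume_change: float | None  # None when baseline volume is zero
    new_lesion_count: int
    degenerate: bool = False  # no lesions on either scan


def percent_change(baseline_value: float, followup_value: float) -> float | None:
    """Signed fractional change ``(followup - baseline) / baseline``.

    Returns ``None`` (undefined) for growth from a zero baseline — that case
    is disease appearance, not a ratio — and ``0.0`` when both values are 0.
    """
    if not (math.isfinite(baseline_value) and math.isfinite(followup_value)):
        raise ValueError("values must be finite")
    if baseline_value < 0 or followup_value < 0:
        raise ValueError("values must be non-negative")
    if baseline_value == 0:
        return 0.0 if followup_value == 0 else None
    return (followup_value - baseline_value) / baseline_value


def detect_new_lesions(
    baseline: ScanRecord, followup: ScanRecord, strict: bool = True
) -> list[str]:
    """Identify new lesions at follow-up.

    A follow-up lesion is *new* iff it has no ``match_id`` or its
    ``match_id`` does not name a baseline lesion.  In strict mode a dangling
    ``match_id`` is an error; in lenient mode it is counted as new with a
    warning.
    """
    if baseline.patient_id != followup.patient_id:
        raise ValueError("scans belong to different patients")
    baseline_ids = {lesion.lesion_id for lesion in baseline.lesions}
    new: list[str] = []
    for lesion in followup.lesions:
        if lesion.match_id is None:
            new.append(lesion.lesion_id)
        elif lesion.match_id not in baseline_ids:
            if strict:
                raise ValueError(
                    f"{followup.patient_id}: lesion {lesion.lesion_id} matches "
                    f"nonexistent baseline lesion {lesion.match_id}"
                )
            warnings.warn(
                f"{followup.patient_id}: dangling match_id {lesion.match_id}; "
                f"counting lesion {lesion.lesion_id} as new"
            )
            new.append(lesion.lesion_id)
    return new


def _metric_value(lesion, metric: Metric) -> float:
    return getattr(lesion, metric.value)


def classify_ppp(
    patient: PatientRecord,
    metric: Metric | str,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    strict: bool = True,
) -> PPPStatus:
    """Classify one patient under a PPP variant.

    Progression iff >= 1 new lesion, or any matched lesion shows a relative
    increase of at least ``thresholds.ppp_increase`` in ``metric``.  Lesions
    present only at baseline (resolved disease) never trigger progression.
    When both clauses hold, the new-lesion trigger is reported.
    """
    metric = Metric(metric)
    new = detect_new_lesions(patient.baseline, patient.followup, strict=strict)
    if new:
        return PPPStatus(metric, True, Trigger.NEW_LESION, new[0])
    baseline_by_id = {lesion.lesion_id: lesion for lesion in patient.baseline.lesions}
    for lesion in patient.followup.lesions:
        ref = baseline_by_id.get(lesion.match_id)
        if ref is None:
            continue
        change = percent_change(_metric_value(ref, metric), _metric_value(lesion, metric))
        if change is not None and change >= thresholds.ppp_increase:
            return PPPStatus(metric, True, Trigger.LESION_INCREASE, lesion.lesion_id)
    return PPPStatus(metric, False, Trigger.NONE)


def classify_recip(
    patient: PatientRecord,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    strict: bool = True,
) -> RECIPCategory:
    """Classify one patient under RECIP 1.0 (always returns a category)."""
    new = detect_new_lesions(patient.baseline, patient.followup, strict=strict)
    vol_base = patient.baseline.total_volume
    vol_follow = patient.followup.total_volume
    change = percent_change(vol_base, vol_follow)

    if vol_follow == 0 and not new:
        if vol_base == 0:
            # lesion-free at both timepoints: no natural category
            category, degenerate = RECIP.SD, True
        else:
            category, degenerate = RECIP.CR, False
        return RECIPCategory(category, vol_base, vol_follow, change, len(new), degenerate)

    # growth from zero baseline is an unbounded increase
    increase_20 = (change is not None and change >= thresholds.recip_increase) or (
        change is None and vol_follow > 0
    )
    if new and increase_20:
        category = RECIP.PD
    elif not new and change is not None and change < -thresholds.recip_pr_reduction:
        category = RECIP.PR
    else:
        category = RECIP.SD
    return RECIPCategory(category, vol_base, vol_follow, change, len(new))


@dataclass(frozen=True)
class PatientClassification:
    """All two-timepoint classifications of one patient."""

    patient_id: str
    ppp_volume: PPPStatus
    ppp_mean_suv: PPPStatus
    ppp_max_suv: PPPStatus
    recip: RECIPCategory

    @property
    def pd_frameworks(self) -> frozenset[str]:
        """Names of frameworks calling progressive disease (UpSet counting)."""
        called = set()
        if self.ppp_volume.progressed:
            called.add("PPP-Volume")
        if self.ppp_mean_suv.progressed:
            called.add("PPP-Mean SUV")
        if self.ppp_max_suv.progressed:
            called.add("PPP-Max SUV")
        if self.recip.category is RECIP.PD:
            called.add("RECIP-PD")
        return frozenset(called)


def classify_patient(
    raw: PatientRecord,
    normalized: PatientRecord | None = None,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    strict: bool = True,
) -> PatientClassification:
    """Run every two-timepoint framework on one patient.

    ``raw`` carries body-weight SUVs and volumes; ``normalized`` (if given)
    carries liver-normalised SUVs used for the SUV-based PPP variants.
    Volume-based criteria always use ``raw``.
    """
    suv_source = normalized if normalized is not None else raw
    return PatientClassification(
        patient_id=raw.patient_id,
        ppp_volume=classify_ppp(raw, Metric.VOLUME, thresholds, strict),
        ppp_mean_suv=classify_ppp(suv_source, Metric.SUV_MEAN, thresholds, strict),
        ppp_max_suv=classify_ppp(suv_source, Metric.SUV_MAX, thresholds, strict),
        recip=classify_recip(raw, thresholds, strict),
    )
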