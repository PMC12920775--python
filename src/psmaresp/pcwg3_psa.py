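"""PCWG3 PSA-progression endpoint derivation.

PSA progression-free survival is clocked from the follow-up PET scan.  Per
the Prostate Cancer Working Group 3 convention, progression is the first
post-scan PSA value rising at least 25% *and* at least 2 ng/mL above the
running post-scan nadir, confirmed by a later value exceeding the same
bounds at least three weeks after.  Death from any cause counts as an event
whenever it precedes confirmed PSA progression.  Patients with fewer than
three post-scan measurements are marked ineligible and excluded from the
PSA-PFS analysis rather than censored.

All four rule constants (relative rise, absolute rise, confirmation window,
whether confirmation is required at all) are configurable because published
operationalisations vary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date

from .cohort_model import PatientRecord, SurvivalRecord, months_between

__all__ = ["Pcwg3Rules", "PsaCause", "PsaEndpoint", "psa_progression", "patient_psa_endpoint"]

MIN_MEASUREMENTS = 3


class PsaCause(str, enum.Enum):
    PSA_PROGRESSION = "psa_progression"
    DEATH = "death"
    CENSORED = "censored"


@dataclass(frozen=True)
class Pcwg3Rules:
    relative_rise: float = 0.25  # fraction above nadir
    absolute_rise: float = 2.0  # ng/mL above nadir
    confirmation_required: bool = True
    confirmation_weeks: float = 3.0


@dataclass(frozen=True)
class PsaEndpoint:
    time: float  # months from follow-up scan
    event: bool
    cause: PsaCause
    nadir: float  # lowest post-scan PSA seen up to the event/censoring
    eligible: bool

    def __post_init__(self) -> None:
        if self.event and self.cause is PsaCause.CENSORED:
            raise ValueError("event=True is incompatible with cause=censored")


def _exceeds(value: float, nadir: float, rules: Pcwg3Rules) -> bool:
    return value >= nadir * (1.0 + rules.relative_rise) and value >= nadir + rules.absolute_rise


def psa_progression(
    series: list[tuple[date, float]],
    survival: SurvivalRecord,
    scan_date: date,
    rules: Pcwg3Rules = Pcwg3Rules(),
) -> PsaEndpoint:
    """Derive the PSA-PFS endpoint for one patient.

    ``series`` is the date-sorted PSA history; only measurements on or after
    ``scan_date`` enter the rule.  The first post-scan value initialises the
    nadir.  A candidate progression at index i is tested against the nadir
    of all *earlier* post-scan values; with confirmation enabled it must be
    seconded by a later value exceeding the same bounds at least
    ``confirmation_weeks`` weeks after.
    """
    if any(v < 0 for _, v in series):
        raise ValueError("negative PSA value")
    post = [(d, v) for d, v in series if d >= scan_date]
    if len(post) < MIN_MEASUREMENTS:
        return PsaEndpoint(
            time=survival.time,
            event=False,
            cause=PsaCause.CENSORED,
            nadir=min((v for _, v in post), default=float("nan")),
            eligible=False,
        )

    progression_time: float | None = None
    nadir = post[0][1]
    nadir_at_event = nadir
    for i in range(1, len(post)):
        d_i, v_i = post[i]
        if _exceeds(v_i, nadir, rules):
            confirmed = not rules.confirmation_required
            if not confirmed:
                window = rules.confirmation_weeks * 7.0
                for d_j, v_j in post[i + 1 :]:
                    if (d_j - d_i).days >= window and _exceeds(v_j, nadir, rules):
                        confirmed = True
                        break
            if confirmed:
                progression_time = months_between(scan_date, d_i)
                nadir_at_event = nadir
                break
        nadir = min(nadir, v_i)

    if progression_time is not None and (
        not survival.event or survival.time >= progression_time
    ):
        return PsaEndpoint(progression_time, True, PsaCause.PSA_PROGRESSION,
                           nadir_at_event, eligible=True)
    if survival.event:
        return PsaEndpoint(survival.time, True, PsaCause.DEATH, nadir, eligible=True)
    last_psa_time = months_between(scan_date, post[-1][0])
    return PsaEndpoint(max(last_psa_time, 1e-9), False, PsaCause.CENSORED,
                       nadir, eligible=True)


def patient_psa_endpoint(
    patient: PatientRecord, rules: Pcwg3Rules = Pcwg3Rules()
) -> PsaEndpoint:
    """Convenience wrapper clocking the rule from the patient's follow-up scan."""
    return psa_progression(
        list(patient.psa_series), patient.survival, patient.followup.scan_date, rules
    )
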