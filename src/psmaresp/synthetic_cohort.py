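"""Seeded synthetic-cohort generator.

Real lesion-level PSMA PET data of this kind are private, so every pipeline
stage is exercised on simulated cohorts that reproduce the published
structure of a biochemically recurrent prostate-cancer population:

* lesion counts with median 2 and range 0-34 (zero-inflated negative
  binomial, ~14% of patients lesion-free at baseline);
* two scans per patient, interval centred on 6.2 months (range 3.2-8.8);
* a four-way response-profile mixture — resolver / responder / stable /
  grower — whose default weights equal the published RECIP category
  distribution (CR 23, PR 43, SD 69, PD 19 of 154).  Lesion-level change
  multipliers are sampled with a safety margin away from the +-30%/+20%
  decision thresholds so every patient's intended class is unambiguous;
* overall survival with an exponential hazard multiplied for the planted
  progressive-disease group (default hazard ratio 4.62, PD median 53.2
  months), with administrative censoring;
* monthly PSA series (10 measurements) with a nadir-then-exponential
  regrowth trajectory for planted PSA progressors.

The generator returns both the cohort and a *ground-truth ledger* of what
was planted per patient (profile, new-lesion count, intended classification,
hazard group), which downstream tests use as an oracle.

A single global seed fans out to per-patient substreams, so the first k
patients are identical whatever the total cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_model import (
    DAYS_PER_MONTH,
    LesionMeasurement,
    PatientRecord,
    ScanRecord,
    Site,
    SurvivalRecord,
    Timepoint,
    Treatment,
)
from .survival_stats import SurvivalSample

__all__ = ["SimulationParams", "SimulatedCohort", "simulate_cohort", "simulate_survival"]

_PROFILES = ("resolver", "responder", "stable", "grower")
_SITES = (Site.LOCAL, Site.PELVIC_NODE, Site.EXTRAPELVIC_NODE, Site.BONE, Site.ORGAN)


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level generating conditions (defaults = the study population)."""

    n_patients: int = 154
    #: patients with a baseline scan only (never imaged at follow-up); they
    #: appear in the scan/clinical tables but not as PatientRecords
    n_baseline_only: int = 0
    #: resolver/responder/stable/grower mixture; defaults are the published
    #: CR/PR/SD/PD proportions 23:43:69:19
    profile_probs: tuple[float, float, float, float] = (
        23 / 154, 43 / 154, 69 / 154, 19 / 154,
    )
    #: probability of a lesion-free baseline among patients whose response
    #: profile permits one (stable/grower); 21/92 makes the cohort-wide
    #: lesion-free fraction match the published 21/154
    p_zero_lesions: float = 21 / 92
    #: negative-binomial (r, p) for the nonzero lesion-count part (shifted +1)
    lesion_nb_r: float = 1.2
    lesion_nb_p: float = 0.4
    max_lesions: int = 34
    #: baseline lesion volume: log-normal (log-median, log-sd), cm^3
    volume_log_median: float = math.log(1.5)
    volume_log_sd: float = 0.9
    #: baseline lesion SUVmean (body weight): log-normal
    suv_log_median: float = math.log(6.0)
    suv_log_sd: float = 0.5
    #: liver reference SUV: normal, clipped >= 3
    liver_ref_mean: float = 6.2
    liver_ref_sd: float = 0.8
    #: extra new lesions for growers beyond the guaranteed one: Poisson mean
    extra_new_lesion_rate: float = 0.7
    #: scan interval, months: normal clipped to the published range
    interval_mean: float = 6.2
    interval_sd: float = 1.1
    interval_range: tuple[float, float] = (3.2, 8.8)
    #: survival: exponential, PD-group median 53.2 months, HR vs non-PD 4.62
    os_hazard_ratio: float = 4.62
    pd_median_os: float = 53.2
    #: administrative censoring window, months after follow-up scan
    censor_window: tuple[float, float] = (55.0, 90.0)
    #: fraction of patients planted as PCWG3 PSA progressors
    psa_progressor_rate: float = 64 / 98
    psa_measurements: int = 10
    #: treatment pattern weights: ADT only, RT only, ADT+RT, other
    treatment_probs: tuple[float, float, float, float] = (
        65 / 154, 36 / 154, 34 / 154, 19 / 154,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.profile_probs) - 1.0) > 1e-9:
            raise ValueError("profile_probs must sum to 1")
        if abs(sum(self.treatment_probs) - 1.0) > 1e-9:
            raise ValueError("treatment_probs must sum to 1")
        if not 0 <= self.p_zero_lesions < 1:
            raise ValueError("p_zero_lesions must be in [0, 1)")
        if self.os_hazard_ratio <= 0 or self.pd_median_os <= 0:
            raise ValueError("survival parameters must be positive")


@dataclass
class SimulatedCohort:
    patients: list[PatientRecord]
    #: all scans, including those of baseline-only patients
    scans: list[ScanRecord]
    clinical: pd.DataFrame
    psa: pd.DataFrame
    ledger: pd.DataFrame = field(repr=False)


def _lesion_count(rng: np.random.Generator, params: SimulationParams,
                  allow_zero: bool) -> int:
    if allow_zero and rng.random() < params.p_zero_lesions:
        return 0
    count = 1 + rng.negative_binomial(params.lesion_nb_r, params.lesion_nb_p)
    return int(min(count, params.max_lesions))


def _baseline_lesion(rng: np.random.Generator, params: SimulationParams,
                     idx: int) -> LesionMeasurement:
    volume = float(np.exp(rng.normal(params.volume_log_median, params.volume_log_sd)))
    suv_mean = float(np.exp(rng.normal(params.suv_log_median, params.suv_log_sd)))
    suv_max = suv_mean * float(1.3 + 1.2 * rng.random())
    site = _SITES[rng.choice(5, p=[0.15, 0.25, 0.20, 0.30, 0.10])]
    return LesionMeasurement(
        lesion_id=f"B{idx}", volume=volume, suv_mean=suv_mean,
        suv_max=suv_max, site=site,
    )


# per-lesion change-multiplier ranges per profile, with margin away from the
# +-30%/+20% thresholds so intended classes are unambiguous
_VOLUME_MULT = {"responder": (0.35, 0.55), "stable": (0.85, 1.10), "grower": (1.35, 1.70)}
_SUV_MULT = {"responder": (0.40, 0.80), "stable": (0.80, 1.15), "grower": (1.35, 1.70)}


def _followup_lesions(
    rng: np.random.Generator,
    params: SimulationParams,
    baseline: tuple[LesionMeasurement, ...],
    profile: str,
    suv_ref_ratio: float,
) -> tuple[tuple[LesionMeasurement, ...], int]:
    """Follow-up lesion list plus the planted new-lesion count.

    ``suv_ref_ratio`` = follow-up liver ref / baseline liver ref: the planted
    change multipliers act on *liver-normalised* uptake, so body-weight SUVs
    at follow-up carry the ratio as an extra factor (which the normalisation
    step removes again).
    """
    lesions: list[LesionMeasurement] = []
    if profile in ("responder", "stable", "grower"):
        v_lo, v_hi = _VOLUME_MULT[profile]
        s_lo, s_hi = _SUV_MULT[profile]
        for i, lesion in enumerate(baseline):
            vm = float(rng.uniform(v_lo, v_hi))
            sm = float(rng.uniform(s_lo, s_hi)) * suv_ref_ratio
            lesions.append(
                LesionMeasurement(
                    lesion_id=f"F{i}",
                    match_id=lesion.lesion_id,
                    volume=lesion.volume * vm,
                    suv_mean=lesion.suv_mean * sm,
                    suv_max=lesion.suv_max * sm,
                    site=lesion.site,
                )
            )
    n_new = 0
    if profile == "grower":
        n_new = 1 + int(rng.poisson(params.extra_new_lesion_rate))
        for j in range(n_new):
            volume = float(np.exp(rng.normal(params.volume_log_median - 0.4,
                                             params.volume_log_sd * 0.7)))
            suv_mean = float(np.exp(rng.normal(params.suv_log_median, params.suv_log_sd)))
            lesions.append(
                LesionMeasurement(
                    lesion_id=f"N{j}",
                    volume=volume,
                    suv_mean=suv_mean,
                    suv_max=suv_mean * float(1.3 + 1.2 * rng.random()),
                    site=_SITES[rng.choice(5, p=[0.05, 0.15, 0.25, 0.40, 0.15])],
                )
            )
    return tuple(lesions), n_new


def _psa_series(
    rng: np.random.Generator,
    params: SimulationParams,
    start: date,
    progressor: bool,
    max_months: float,
) -> tuple[tuple[date, float], ...]:
    """Monthly PSA values from the follow-up scan, truncated at death."""
    months = np.arange(params.psa_measurements, dtype=float)
    nadir = float(rng.uniform(0.2, 1.5))
    if progressor:
        start_val = nadir * float(rng.uniform(2.0, 4.0))
        growth = float(rng.uniform(0.5, 0.9))
        amp = float(rng.uniform(1.0, 2.0))
        values = np.where(
            months <= 2,
            start_val + (nadir - start_val) * months / 2.0,
            nadir + amp * (np.exp(growth * (months - 2.0)) - 1.0),
        )
    else:
        start_val = nadir * float(rng.uniform(1.2, 2.0))
        decline = start_val + (nadir - start_val) * np.minimum(months, 4.0) / 4.0
        values = decline * (1.0 + rng.normal(0.0, 0.03, size=months.size))
    values = np.maximum(values, 0.01)
    series = []
    for m, v in zip(months, values):
        if m >= max_months and m > 0:
            break
        series.append((start + timedelta(days=round(m * DAYS_PER_MONTH)), float(v)))
    return tuple(series)


def _treatments(rng: np.random.Generator, params: SimulationParams) -> frozenset[Treatment]:
    pattern = rng.choice(4, p=list(params.treatment_probs))
    if pattern == 0:
        return frozenset({Treatment.ADT})
    if pattern == 1:
        return frozenset({Treatment.RADIOTHERAPY})
    if pattern == 2:
        return frozenset({Treatment.ADT, Treatment.RADIOTHERAPY})
    other = [
        frozenset({Treatment.CHEMOTHERAPY}),
        frozenset({Treatment.SURGERY}),
        frozenset({Treatment.ADT, Treatment.CHEMOTHERAPY}),
        frozenset(),
    ]
    return other[rng.choice(4)]


def simulate_cohort(params: SimulationParams = SimulationParams()) -> SimulatedCohort:
    """Generate a full synthetic cohort plus its ground-truth ledger."""
    streams = np.random.SeedSequence(params.seed).spawn(
        params.n_patients + params.n_baseline_only
    )
    lam_pd = math.log(2.0) / params.pd_median_os
    lam_base = lam_pd / params.os_hazard_ratio

    patients: list[PatientRecord] = []
    scans: list[ScanRecord] = []
    ledger_rows = []
    clin_rows = []
    psa_rows = []
    study_start = date(2015, 6, 1)

    for i in range(params.n_patients + params.n_baseline_only):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:04d}"
        baseline_only = i >= params.n_patients

        profile = _PROFILES[rng.choice(4, p=list(params.profile_probs))]
        allow_zero = profile in ("stable", "grower")
        n_lesions = _lesion_count(rng, params, allow_zero)
        base_lesions = tuple(
            _baseline_lesion(rng, params, j) for j in range(n_lesions)
        )
        liver_base = max(3.0, float(rng.normal(params.liver_ref_mean, params.liver_ref_sd)))
        base_date = study_start + timedelta(days=int(rng.integers(0, 400)))
        baseline = ScanRecord(
            patient_id=pid, timepoint=Timepoint.BASELINE, scan_date=base_date,
            lesions=base_lesions, liver_ref_suv=liver_base,
        )
        scans.append(baseline)
        # interval sampled for every patient to keep substreams aligned
        interval = float(np.clip(rng.normal(params.interval_mean, params.interval_sd),
                                 *params.interval_range))
        if baseline_only:
            continue

        liver_follow = max(3.0, float(rng.normal(params.liver_ref_mean, params.liver_ref_sd)))
        follow_lesions, n_new = _followup_lesions(
            rng, params, base_lesions, profile, liver_follow / liver_base
        )
        follow_date = base_date + timedelta(days=round(interval * DAYS_PER_MONTH))
        followup = ScanRecord(
            patient_id=pid, timepoint=Timepoint.FOLLOWUP, scan_date=follow_date,
            lesions=follow_lesions, liver_ref_suv=liver_follow,
        )
        scans.append(followup)

        # intended classes from the planted construction
        if profile == "grower":
            intended_recip = "PD"
        elif profile == "resolver":
            intended_recip = "CR" if n_lesions > 0 else "SD"
        elif profile == "responder":
            intended_recip = "PR" if n_lesions > 0 else "SD"
        else:
            intended_recip = "SD"
        intended_ppp = profile == "grower"
        hazard_group = intended_recip == "PD"

        lam = lam_pd if hazard_group else lam_base
        event_time = float(rng.exponential(1.0 / lam))
        censor_time = float(rng.uniform(*params.censor_window))
        time = max(min(event_time, censor_time), 0.1)
        event = event_time <= censor_time
        survival = SurvivalRecord(time=time, event=event)

        psa_progressor = bool(rng.random() < params.psa_progressor_rate)
        psa = _psa_series(rng, params, follow_date, psa_progressor, time)

        treatments = _treatments(rng, params)
        patients.append(
            PatientRecord(
                patient_id=pid, baseline=baseline, followup=followup,
                treatments=treatments, survival=survival, psa_series=psa,
            )
        )
        ledger_rows.append(
            {
                "patient_id": pid,
                "profile": profile,
                "n_baseline_lesions": n_lesions,
                "n_new_lesions": n_new,
                "intended_recip": intended_recip,
                "intended_ppp": intended_ppp,
                "hazard_group": hazard_group,
                "psa_progressor": psa_progressor,
                "scan_interval_months": interval,
            }
        )
        clin_rows.append(
            {
                "patient_id": pid,
                "adt": int(Treatment.ADT in treatments),
                "radiotherapy": int(Treatment.RADIOTHERAPY in treatments),
                "chemotherapy": int(Treatment.CHEMOTHERAPY in treatments),
                "surgery": int(Treatment.SURGERY in treatments),
                "death": int(event),
                "last_contact_date": (
                    follow_date + timedelta(days=round(time * DAYS_PER_MONTH))
                ).isoformat(),
            }
        )
        for d, v in psa:
            psa_rows.append({"patient_id": pid, "date": d.isoformat(), "psa": v})

    return SimulatedCohort(
        patients=patients,
        scans=scans,
        clinical=pd.DataFrame(clin_rows),
        psa=pd.DataFrame(psa_rows, columns=["patient_id", "date", "psa"]),
        ledger=pd.DataFrame(ledger_rows),
    )


def simulate_survival(
    groups: np.ndarray,
    true_hr: float,
    baseline_hazard: float = math.log(2.0) / 53.2 / 4.62,
    censor_rate: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> SurvivalSample:
    """Two-group exponential survival data with a known hazard ratio.

    Event times are exponential with hazard ``baseline_hazard`` in group 0
    and ``baseline_hazard * true_hr`` in group 1.  Independent exponential
    censoring is calibrated so the expected overall censoring fraction
    equals ``censor_rate`` (0 disables censoring).  This is the
    parameter-recovery harness: a Cox fit on the output should recover
    ``true_hr`` up to sampling error.
    """
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    groups = np.asarray(groups, dtype=int)
    rng = np.random.default_rng(seed)
    lam = baseline_hazard * np.where(groups == 1, true_hr, 1.0)
    event_times = rng.exponential(1.0 / lam)
    if censor_rate == 0:
        return SurvivalSample(event_times, np.ones_like(event_times, dtype=bool), groups)

    prevalence = groups.mean()
    lam0, lam1 = baseline_hazard, baseline_hazard * true_hr

    def expected_event_fraction(lam_c: float) -> float:
        return (1 - prevalence) * lam0 / (lam0 + lam_c) + prevalence * lam1 / (lam1 + lam_c)

    lam_c = brentq(
        lambda x: expected_event_fraction(x) - (1.0 - censor_rate),
        1e-12, 1e6 * baseline_hazard * max(true_hr, 1.0),
    )
    censor_times = rng.exponential(1.0 / lam_c, size=groups.size)
    times = np.minimum(event_times, censor_times)
    events = event_times <= censor_times
    return SurvivalSample(times, events, groups)
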