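"""End-to-end analysis pipeline.

Wires the pieces together the way the study design does: liver-normalise
SUVs, classify every patient under each progression framework (three PPP
variants, RECIP 1.0, and optionally one or two PROMISE-style nomograms on
the follow-up scan), derive the overall-survival and PCWG3 PSA-progression
endpoints, then quantify the prognostic value of each framework with
Kaplan-Meier medians, log-rank tests, univariate Cox models and Harrell's
C — on the full cohort and within treatment subgroups (ADT only,
radiotherapy only, ADT + radiotherapy).

Outputs are machine-readable DataFrames shaped like the study's summary
tables: a per-framework survival report, a RECIP category tabulation, a
four-category pairwise log-rank table, and an UpSet-style co-classification
count table.  Nomogram risk groups are analysed for overall survival only
(a single-scan stratification has no response-to-treatment reading).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort_model import CriteriaThresholds, PatientRecord, Treatment
from .pcwg3_psa import Pcwg3Rules, patient_psa_endpoint
from .promise_nomogram import (
    NomogramModel,
    RiskGroup,
    extract_promise_features,
    score_nomogram,
)
from .response_criteria import RECIP, PatientClassification, classify_patient
from .survival_stats import (
    NOT_REACHED,
    SurvivalSample,
    cox_univariate,
    km_estimate,
    logrank_test,
)
from .suv_normalization import normalize_patient

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "run_analysis",
    "classification_frame",
    "recip_category_table",
    "upset_counts",
    "percent",
]

PPP_FRAMEWORKS = ("PPP-Volume", "PPP-Mean SUV", "PPP-Max SUV")
TWO_TIMEPOINT_FRAMEWORKS = PPP_FRAMEWORKS + ("RECIP-PD",)

#: exclusive treatment subgroups analysed in addition to the full cohort
DEFAULT_SUBGROUPS: Mapping[str, frozenset[Treatment]] = {
    "ADT only": frozenset({Treatment.ADT}),
    "Radiotherapy only": frozenset({Treatment.RADIOTHERAPY}),
    "ADT + radiotherapy": frozenset({Treatment.ADT, Treatment.RADIOTHERAPY}),
}


@dataclass(frozen=True)
class AnalysisConfig:
    thresholds: CriteriaThresholds = CriteriaThresholds()
    suv_normalisation: str = "liver"  # 'liver' | 'none'
    pcwg3: Pcwg3Rules = Pcwg3Rules()
    endpoints: tuple[str, ...] = ("OS", "PSA-PFS")
    #: nomogram name -> model; analysed for OS only
    nomograms: Mapping[str, NomogramModel] = field(default_factory=dict)
    #: subgroup name -> exact treatment set (exclusive membership); None
    #: disables subgroup analysis
    subgroups: Mapping[str, frozenset[Treatment]] | None = None
    #: membership is exact-set equality when True, superset when False
    exclusive_subgroups: bool = True
    #: smallest subgroup worth fitting (the study skipped groups of <= 6)
    min_subgroup_size: int = 7

    def config_hash(self) -> str:
        payload = {
            "thresholds": vars(self.thresholds),
            "suv_normalisation": self.suv_normalisation,
            "pcwg3": vars(self.pcwg3),
            "endpoints": self.endpoints,
            "nomograms": sorted(self.nomograms),
            "subgroups": sorted(self.subgroups) if self.subgroups else None,
            "exclusive_subgroups": self.exclusive_subgroups,
            "min_subgroup_size": self.min_subgroup_size,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisResult:
    report: pd.DataFrame  # framework x endpoint x cohort survival rows
    classifications: pd.DataFrame  # per-patient calls under every framework
    recip_table: pd.DataFrame  # four-category tabulation with percentages
    recip_pairwise: pd.DataFrame  # pairwise log-rank across RECIP categories
    upset: pd.DataFrame  # co-classification counts of PD calls
    log: list[str]
    config_hash: str


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage as printed in clinical tables (one decimal by default)."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, ndigits)


def classify_cohort(
    patients: Sequence[PatientRecord], config: AnalysisConfig
) -> list[PatientClassification]:
    out = []
    for p in patients:
        normalized = (
            normalize_patient(p) if config.suv_normalisation == "liver" else None
        )
        out.append(classify_patient(p, normalized, config.thresholds))
    return out


def classification_frame(
    classifications: Sequence[PatientClassification],
) -> pd.DataFrame:
    """Per-patient classification table (the classify CSV output)."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "patient_id": c.patient_id,
                "ppp_volume": c.ppp_volume.progressed,
                "ppp_mean_suv": c.ppp_mean_suv.progressed,
                "ppp_max_suv": c.ppp_max_suv.progressed,
                "recip_category": c.recip.category.value,
                "new_lesion_count": c.recip.new_lesion_count,
                "volume_change": (
                    np.nan if c.recip.volume_change is None else c.recip.volume_change
                ),
            }
        )
    return pd.DataFrame(rows)


def recip_category_table(categories: Sequence[RECIP | str]) -> pd.DataFrame:
    """Count and percentage per RECIP category (the category-tabulation
    report shape)."""
    values = [c.value if isinstance(c, RECIP) else str(c) for c in categories]
    total = len(values)
    rows = []
    for cat in ("CR", "PR", "SD", "PD"):
        count = values.count(cat)
        rows.append(
            {"category": f"RECIP-{cat}", "count": count, "pct": percent(count, total)}
        )
    return pd.DataFrame(rows)


def upset_counts(classifications: Sequence[PatientClassification]) -> pd.DataFrame:
    """Co-classification counts: how many patients each exact combination of
    frameworks calls progressive (UpSet-plot input)."""
    combos: dict[str, int] = {}
    for c in classifications:
        key = " & ".join(sorted(c.pd_frameworks)) or "(none)"
        combos[key] = combos.get(key, 0) + 1
    frame = pd.DataFrame(
        [{"frameworks": k, "count": v} for k, v in combos.items()]
    ).sort_values("count", ascending=False, ignore_index=True)
    return frame


def _pd_indicator(
    c: PatientClassification, framework: str
) -> bool:
    if framework == "PPP-Volume":
        return c.ppp_volume.progressed
    if framework == "PPP-Mean SUV":
        return c.ppp_mean_suv.progressed
    if framework == "PPP-Max SUV":
        return c.ppp_max_suv.progressed
    if framework == "RECIP-PD":
        return c.recip.category is RECIP.PD
    raise KeyError(framework)


def _endpoint_arrays(
    patients: Sequence[PatientRecord], endpoint: str, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, events, keep-mask) for an endpoint over the cohort order."""
    if endpoint == "OS":
        times = np.array([p.survival.time for p in patients])
        events = np.array([p.survival.event for p in patients])
        keep = np.ones(len(patients), dtype=bool)
    elif endpoint == "PSA-PFS":
        eps = [patient_psa_endpoint(p, config.pcwg3) for p in patients]
        times = np.array([e.time for e in eps])
        events = np.array([e.event for e in eps])
        keep = np.array([e.eligible for e in eps])
    else:
        raise KeyError(f"unknown endpoint: {endpoint}")
    return times, events, keep


def _median_label(median: float) -> str:
    return NOT_REACHED if np.isinf(median) else f"{median:.1f}"


def _framework_row(
    times: np.ndarray, events: np.ndarray, indicator: np.ndarray
) -> dict:
    """One survival-report row: KM medians, log-rank, Cox, C-index."""
    sample = SurvivalSample(times, events)
    row: dict = {
        "n": sample.n,
        "n_pd": int(indicator.sum()),
        "median_non_pd": None,
        "median_pd": None,
        "logrank_p": None,
        "hr": None, "ci_low": None, "ci_high": None, "cox_p": None,
        "c_index": None,
        "converged": False,
        "note": "",
    }
    if indicator.all() or not indicator.any():
        row["note"] = "degenerate_design"
        only = km_estimate(sample)
        which = "median_pd" if indicator.all() else "median_non_pd"
        row[which] = _median_label(only.median)
        return row
    non_pd = sample.subset(indicator == 0)
    is_pd = sample.subset(indicator == 1)
    row["median_non_pd"] = _median_label(km_estimate(non_pd).median)
    row["median_pd"] = _median_label(km_estimate(is_pd).median)
    if events.any():
        _, p = logrank_test(non_pd, is_pd)
        row["logrank_p"] = p
        cox = cox_univariate(sample, indicator)
        row.update(
            hr=cox.hr, ci_low=cox.ci_low, ci_high=cox.ci_high, cox_p=cox.p,
            c_index=cox.c_index, converged=cox.converged,
        )
        if not cox.converged:
            row["note"] = cox.diagnostics.get("reason", "not_converged")
    else:
        row["note"] = "no_events"
    return row


def _subgroup_mask(
    patients: Sequence[PatientRecord],
    treatments: frozenset[Treatment],
    exclusive: bool,
) -> np.ndarray:
    if exclusive:
        return np.array([p.treatments == treatments for p in patients])
    return np.array([treatments <= p.treatments for p in patients])


def _recip_pairwise(
    patients: Sequence[PatientRecord],
    classifications: Sequence[PatientClassification],
) -> pd.DataFrame:
    """Pairwise log-rank tests between RECIP categories on overall survival.

    Raw p-values match the study's unadjusted pairwise reporting; a
    Holm-adjusted column is added as a clearly-labelled extension.
    """
    cats = np.array([c.recip.category.value for c in classifications])
    times = np.array([p.survival.time for p in patients])
    events = np.array([p.survival.event for p in patients])
    rows = []
    order = ("CR", "PR", "SD", "PD")
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            mask_a, mask_b = cats == a, cats == b
            if not (mask_a.any() and mask_b.any()):
                continue
            sa = SurvivalSample(times[mask_a], events[mask_a])
            sb = SurvivalSample(times[mask_b], events[mask_b])
            try:
                stat, p = logrank_test(sa, sb)
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append({"group_a": a, "group_b": b, "n_a": int(mask_a.sum()),
                         "n_b": int(mask_b.sum()), "statistic": stat, "p": p})
    frame = pd.DataFrame(rows)
    if len(frame):
        valid = frame["p"].notna()
        adjusted = np.full(len(frame), np.nan)
        if valid.any():
            adjusted[valid.to_numpy()] = multipletests(
                frame.loc[valid, "p"], method="holm"
            )[1]
        frame["p_holm_adjusted"] = adjusted
    return frame


def run_analysis(
    patients: Sequence[PatientRecord], config: AnalysisConfig = AnalysisConfig()
) -> AnalysisResult:
    """Classify a validated cohort and produce the full survival report."""
    log: list[str] = [f"config_hash={config.config_hash()}", f"n_patients={len(patients)}"]
    classifications = classify_cohort(patients, config)

    # nomogram risk groups on the follow-up scan (single-timepoint)
    nomogram_risk: dict[str, np.ndarray] = {}
    for name, model in config.nomograms.items():
        risk = np.array(
            [
                score_nomogram(extract_promise_features(p.followup), model)[1]
                is RiskGroup.HIGH
                for p in patients
            ]
        )
        nomogram_risk[name] = risk

    subgroups = (
        config.subgroups if config.subgroups is not None else DEFAULT_SUBGROUPS
    )
    cohorts: list[tuple[str, np.ndarray]] = [
        ("Full cohort", np.ones(len(patients), dtype=bool))
    ]
    for name, treatments in subgroups.items():
        mask = _subgroup_mask(patients, treatments, config.exclusive_subgroups)
        if mask.sum() < config.min_subgroup_size:
            log.append(f"subgroup '{name}' skipped: n={int(mask.sum())} below minimum")
            continue
        cohorts.append((name, mask))

    rows = []
    for endpoint in config.endpoints:
        times, events, keep = _endpoint_arrays(patients, endpoint, config)
        if endpoint == "PSA-PFS":
            log.append(f"PSA-PFS eligible patients: {int(keep.sum())}/{len(patients)}")
        frameworks: list[tuple[str, np.ndarray]] = [
            (fw, np.array([_pd_indicator(c, fw) for c in classifications]))
            for fw in TWO_TIMEPOINT_FRAMEWORKS
        ]
        if endpoint == "OS":  # nomograms are prognostic single-scan tools
            frameworks += [
                (f"{name} nomogram", risk) for name, risk in nomogram_risk.items()
            ]
        for cohort_name, cohort_mask in cohorts:
            mask = cohort_mask & keep
            if mask.sum() < 2 or not events[mask].any():
                log.append(
                    f"{endpoint}/{cohort_name}: skipped (n={int(mask.sum())}, "
                    f"events={int(events[mask].sum())})"
                )
                continue
            for fw_name, indicator in frameworks:
                row = _framework_row(times[mask], events[mask], indicator[mask])
                rows.append(
                    {"endpoint": endpoint, "cohort": cohort_name,
                     "framework": fw_name, **row}
                )

    report = pd.DataFrame(rows)
    result = AnalysisResult(
        report=report,
        classifications=classification_frame(classifications),
        recip_table=recip_category_table([c.recip.category for c in classifications]),
        recip_pairwise=_recip_pairwise(patients, classifications),
        upset=upset_counts(classifications),
        log=log,
        config_hash=config.config_hash(),
    )
    log.append(f"report_rows={len(report)}")
    return result
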