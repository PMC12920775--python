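"""Domain types and table I/O for PSMA PET/CT response cohorts.

The analysis operates on lesion-level measurements from paired
[68Ga]Ga-PSMA-11 PET/CT scans (one baseline, one follow-up per patient),
plus per-patient clinical records: administered treatments, overall-survival
follow-up, and a longitudinal PSA series.  This module defines the validated
in-memory representation of that data and CSV readers/writers for the two
table layouts the pipeline consumes:

* a *lesion table* — one row per lesion per scan, plus one metadata row per
  scan so that scans with zero lesions are representable;
* a *clinical table* — one row per patient with treatment flags and survival
  data, and a companion long-format PSA table.

All durations are expressed in months, converted from day differences with
30.44 days per month.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

DAYS_PER_MONTH = 30.44

__all__ = [
    "Site",
    "Timepoint",
    "Treatment",
    "LesionMeasurement",
    "ScanRecord",
    "SurvivalRecord",
    "PatientRecord",
    "CriteriaThresholds",
    "CohortBuildResult",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "months_between",
    "read_lesion_table",
    "write_lesion_table",
    "read_clinical_table",
    "write_clinical_table",
    "build_cohort",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (duplicates, ordering, ...)."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class Site(str, enum.Enum):
    """Anatomical site class of a lesion, as used by nomogram features."""

    LOCAL = "local"
    PELVIC_NODE = "pelvic_node"
    EXTRAPELVIC_NODE = "extrapelvic_node"
    BONE = "bone"
    ORGAN = "organ"
    UNKNOWN = "unknown"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


class Treatment(str, enum.Enum):
    ADT = "ADT"
    RADIOTHERAPY = "radiotherapy"
    CHEMOTHERAPY = "chemotherapy"
    SURGERY = "surgery"


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion on one scan.

    ``match_id`` links a follow-up lesion to the baseline lesion it
    corresponds to; matching is consumed as input (done by expert readers),
    never computed.  A follow-up lesion without a valid ``match_id`` is a
    *new* lesion.  SUVs are body-weight standardised uptake values unless a
    liver normalisation has been applied upstream.
    """

    lesion_id: str
    volume: float  # cm^3
    suv_mean: float
    suv_max: float
    site: Site = Site.UNKNOWN
    match_id: str | None = None

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise IntegrityError(
                f"lesion {self.lesion_id}: volume must be > 0, got {self.volume}"
            )
        if self.suv_mean < 0 or self.suv_max < 0:
            raise IntegrityError(f"lesion {self.lesion_id}: SUV must be >= 0")
        if self.suv_max < self.suv_mean - 1e-9:
            raise IntegrityError(
                f"lesion {self.lesion_id}: suv_max ({self.suv_max}) < "
                f"suv_mean ({self.suv_mean})"
            )


@dataclass(frozen=True)
class ScanRecord:
    """All lesions of one patient at one timepoint.

    ``liver_ref_suv`` is the mean SUV of a reference volume placed in the
    right liver lobe, used to re-normalise lesion SUVs.  An empty lesion
    list is legal: patients can be lesion-free at either timepoint.
    """

    patient_id: str
    timepoint: Timepoint
    scan_date: date
    lesions: tuple[LesionMeasurement, ...]
    liver_ref_suv: float
    suv_normalized: bool = False

    def __post_init__(self) -> None:
        if not self.liver_ref_suv > 0:
            raise IntegrityError(
                f"{self.patient_id}/{self.timepoint.value}: liver_ref_suv must be > 0"
            )
        ids = [lesion.lesion_id for lesion in self.lesions]
        if len(ids) != len(set(ids)):
            raise IntegrityError(
                f"{self.patient_id}/{self.timepoint.value}: duplicate lesion ids"
            )

    @property
    def total_volume(self) -> float:
        return sum(lesion.volume for lesion in self.lesions)

    @property
    def lesion_count(self) -> int:
        return len(self.lesions)


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall-survival follow-up, clocked from the follow-up scan."""

    time: float  # months from follow-up scan to death or last contact
    event: bool  # death from any cause observed

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise IntegrityError(f"survival time must be > 0, got {self.time}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    baseline: ScanRecord
    followup: ScanRecord
    treatments: frozenset[Treatment]
    survival: SurvivalRecord
    psa_series: tuple[tuple[date, float], ...] = ()

    def __post_init__(self) -> None:
        if self.followup.scan_date <= self.baseline.scan_date:
            raise IntegrityError(
                f"{self.patient_id}: follow-up scan not after baseline"
            )
        dates = [d for d, _ in self.psa_series]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise IntegrityError(f"{self.patient_id}: PSA dates not strictly increasing")
        if any(v < 0 for _, v in self.psa_series):
            raise IntegrityError(f"{self.patient_id}: negative PSA value")

    @property
    def scan_interval_months(self) -> float:
        return months_between(self.baseline.scan_date, self.followup.scan_date)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Thresholds of the response frameworks.

    ``ppp_increase``: per-lesion relative increase (volume or uptake) that
    defines PSMA PET Progression; ``recip_increase`` / ``recip_pr_reduction``
    bound the whole-body tumour-volume change for RECIP-PD and RECIP-PR.
    ``segmentation_suv_cutoff`` documents the SUV threshold the upstream
    segmentation used; it plays no computational role here.
    """

    ppp_increase: float = 0.30
    recip_increase: float = 0.20
    recip_pr_reduction: float = 0.30
    recip_sd_lower: float = -0.30
    segmentation_suv_cutoff: float = 3.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.recip_sd_lower < 0 < self.recip_increase):
            raise ValueError("need recip_sd_lower < 0 < recip_increase")
        if not self.ppp_increase > 0:
            raise ValueError("ppp_increase must be > 0")


def months_between(start: date, end: date) -> float:
    """Signed duration in months (days / 30.44)."""
    return (end - start).days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# Lesion table I/O
# ---------------------------------------------------------------------------

#: canonical column names of the lesion table
LESION_COLUMNS = (
    "patient_id",
    "timepoint",
    "scan_date",
    "liver_ref_suv",
    "lesion_id",
    "match_id",
    "volume",
    "suv_mean",
    "suv_max",
    "site",
)

_REQUIRED = (
    "patient_id",
    "timepoint",
    "scan_date",
    "liver_ref_suv",
    "lesion_id",
    "volume",
    "suv_mean",
    "suv_max",
)


def load_dialect(path: str | Path) -> dict[str, str]:
    """Read a column-name remapping (``{file column -> canonical name}``)
    from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"dialect file {path} must contain a mapping")
    return dict(mapping)


def _parse_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from exc


def read_lesion_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[ScanRecord]:
    """Read a lesion CSV/TSV into validated :class:`ScanRecord` objects.

    One row per lesion; a row with an empty ``lesion_id`` is a scan-metadata
    row representing a scan with zero lesions.  ``dialect`` maps file column
    names to the canonical names in :data:`LESION_COLUMNS`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"lesion table missing column(s): {', '.join(missing)}")
    return scan_records_from_frame(frame)


def scan_records_from_frame(frame: pd.DataFrame) -> list[ScanRecord]:
    """Group a canonical-column lesion frame into ScanRecords."""
    records: list[ScanRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for (pid, tp), group in frame.groupby(["patient_id", "timepoint"], sort=True):
        lesions = []
        scan_date = None
        liver_ref = None
        for row in group.itertuples():
            idx = int(row.Index) + 2  # header is line 1
            scan_date = date.fromisoformat(str(row.scan_date))
            liver_ref = _parse_float(row.liver_ref_suv, "liver_ref_suv", idx)
            lesion_id = str(row.lesion_id).strip()
            if not lesion_id:  # scan-metadata row: zero-lesion scan
                continue
            key = (str(pid), str(tp), lesion_id)
            if key in seen:
                raise IntegrityError(
                    f"duplicate lesion {lesion_id} for patient {pid}/{tp}"
                )
            seen.add(key)
            volume = _parse_float(row.volume, "volume", idx)
            if volume <= 0:
                continue  # reject non-positive-volume rows
            match_id = str(getattr(row, "match_id", "")).strip() or None
            site_raw = str(getattr(row, "site", "")).strip()
            site = Site(site_raw) if site_raw else Site.UNKNOWN
            lesions.append(
                LesionMeasurement(
                    lesion_id=lesion_id,
                    match_id=match_id,
                    volume=volume,
                    suv_mean=_parse_float(row.suv_mean, "suv_mean", idx),
                    suv_max=_parse_float(row.suv_max, "suv_max", idx),
                    site=site,
                )
            )
        records.append(
            ScanRecord(
                patient_id=str(pid),
                timepoint=Timepoint(str(tp)),
                scan_date=scan_date,
                lesions=tuple(lesions),
                liver_ref_suv=liver_ref,
            )
        )
    return records


def scans_to_frame(scans: Iterable[ScanRecord]) -> pd.DataFrame:
    rows = []
    for scan in scans:
        base = {
            "patient_id": scan.patient_id,
            "timepoint": scan.timepoint.value,
            "scan_date": scan.scan_date.isoformat(),
            "liver_ref_suv": scan.liver_ref_suv,
        }
        if not scan.lesions:
            rows.append({**base, "lesion_id": "", "match_id": "", "volume": "",
                         "suv_mean": "", "suv_max": "", "site": ""})
        for lesion in scan.lesions:
            rows.append(
                {
                    **base,
                    "lesion_id": lesion.lesion_id,
                    "match_id": lesion.match_id or "",
                    "volume": repr(lesion.volume),
                    "suv_mean": repr(lesion.suv_mean),
                    "suv_max": repr(lesion.suv_max),
                    "site": lesion.site.value,
                }
            )
    return pd.DataFrame(rows, columns=list(LESION_COLUMNS))


def write_lesion_table(scans: Iterable[ScanRecord], path: str | Path) -> None:
    """Write scans as a canonical lesion CSV (round-trips with the reader)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    scans_to_frame(scans).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_REQUIRED = ("patient_id", "death", "last_contact_date")
_TREATMENT_COLS = {
    "adt": Treatment.ADT,
    "radiotherapy": Treatment.RADIOTHERAPY,
    "chemotherapy": Treatment.CHEMOTHERAPY,
    "surgery": Treatment.SURGERY,
}


def read_clinical_table(
    path: str | Path, psa_path: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the per-patient clinical CSV and optional long-format PSA CSV.

    Returns ``(clinical, psa)`` frames; ``psa`` is empty when no path given.
    """
    clinical = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _CLINICAL_REQUIRED if c not in clinical.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {', '.join(missing)}")
    if psa_path is not None:
        psa = pd.read_csv(psa_path, dtype={"patient_id": str})
        for col in ("patient_id", "date", "psa"):
            if col not in psa.columns:
                raise SchemaError(f"PSA table missing column: {col}")
    else:
        psa = pd.DataFrame(columns=["patient_id", "date", "psa"])
    return clinical, psa


def write_clinical_table(
    patients: Sequence[PatientRecord],
    clinical_path: str | Path,
    psa_path: str | Path | None = None,
) -> None:
    rows, psa_rows = [], []
    for p in patients:
        death_days = int(round(p.survival.time * DAYS_PER_MONTH))
        rows.append(
            {
                "patient_id": p.patient_id,
                "adt": int(Treatment.ADT in p.treatments),
                "radiotherapy": int(Treatment.RADIOTHERAPY in p.treatments),
                "chemotherapy": int(Treatment.CHEMOTHERAPY in p.treatments),
                "surgery": int(Treatment.SURGERY in p.treatments),
                "death": int(p.survival.event),
                "last_contact_date": (
                    p.followup.scan_date + timedelta(days=death_days)
                ).isoformat(),
            }
        )
        for d, v in p.psa_series:
            psa_rows.append({"patient_id": p.patient_id, "date": d.isoformat(), "psa": v})
    pd.DataFrame(rows).to_csv(clinical_path, index=False)
    if psa_path is not None:
        pd.DataFrame(psa_rows, columns=["patient_id", "date", "psa"]).to_csv(
            psa_path, index=False
        )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortBuildResult:
    patients: list[PatientRecord]
    excluded: list[str] = field(default_factory=list)  # patient ids lacking follow-up

    @property
    def followup_rate(self) -> float:
        total = len(self.patients) + len(self.excluded)
        return len(self.patients) / total if total else float("nan")


def build_cohort(
    scans: Sequence[ScanRecord],
    clinical: pd.DataFrame,
    psa: pd.DataFrame | None = None,
) -> CohortBuildResult:
    """Assemble validated :class:`PatientRecord` objects from scans plus
    clinical data.

    Patients with a baseline scan but no follow-up scan are excluded and
    listed in the result's exclusion log (the study analogue: of 238 baseline
    patients, only those with follow-up imaging enter response assessment).
    A patient with two scans at the same timepoint is an error.
    """
    by_patient: dict[str, dict[Timepoint, ScanRecord]] = {}
    for scan in scans:
        slot = by_patient.setdefault(scan.patient_id, {})
        if scan.timepoint in slot:
            raise IntegrityError(
                f"patient {scan.patient_id}: duplicate {scan.timepoint.value} scan"
            )
        slot[scan.timepoint] = scan

    clin = clinical.set_index("patient_id")
    psa_groups: dict[str, list[tuple[date, float]]] = {}
    if psa is not None and len(psa):
        for pid, grp in psa.groupby("patient_id"):
            series = sorted(
                (date.fromisoformat(str(r.date)), float(r.psa))
                for r in grp.itertuples()
            )
            psa_groups[str(pid)] = series

    patients: list[PatientRecord] = []
    excluded: list[str] = []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        if Timepoint.BASELINE not in slot:
            raise IntegrityError(f"patient {pid}: no baseline scan")
        if Timepoint.FOLLOWUP not in slot:
            excluded.append(pid)
            continue
        if pid not in clin.index:
            warnings.warn(f"patient {pid}: no clinical record; excluded")
            excluded.append(pid)
            continue
        row = clin.loc[pid]
        followup = slot[Timepoint.FOLLOWUP]
        last_contact = date.fromisoformat(str(row["last_contact_date"]))
        time_months = months_between(followup.scan_date, last_contact)
        treatments = frozenset(
            treatment
            for col, treatment in _TREATMENT_COLS.items()
            if col in row.index and int(row[col]) == 1
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                baseline=slot[Timepoint.BASELINE],
                followup=followup,
                treatments=treatments,
                survival=SurvivalRecord(time=time_months, event=bool(int(row["death"]))),
                psa_series=tuple(psa_groups.get(pid, ())),
            )
        )
    return CohortBuildResult(patients=patients, excluded=excluded)
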