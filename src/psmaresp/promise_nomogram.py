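"""PROMISE-style single-scan nomogram risk stratification.

A nomogram converts scan-level features — tumour count, presence of
locoregional-node / extrapelvic-node / bone / organ metastases, total
PSMA-positive tumour volume and mean uptake — into additive points; a
cut-off on the total splits patients into high- and low-risk groups from a
single scan, with no baseline comparison.

The published point tables and cut-offs of the visual and quantitative
PROMISE nomograms live in their source publication's appendices and are
deliberately NOT bundled: the engine is generic and loads any additive
points model from YAML.  The YAML files shipped under ``psmaresp/data`` are
synthetic placeholders for testing the machinery, clearly labelled as such;
users must supply the published tables to reproduce published risk groups.

Model YAML layout::

    variant: visual            # or quantitative
    cutoff: 100.0              # total points; high risk iff total >= cutoff
    points:
      tumour_count:            # piecewise-linear in the feature value
        - [0, 0.0]
        - [5, 40.0]
        - [20, 80.0]
      has_bone_mets: 35.0      # boolean feature: points added when true
      total_volume:
        - [0, 0.0]
        - [50, 60.0]

Piecewise maps interpolate linearly between knots and clamp outside the
knot range; boolean features contribute a fixed score when present.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .cohort_model import ScanRecord, Site

__all__ = [
    "RiskGroup",
    "PromiseFeatures",
    "NomogramModel",
    "ScoringError",
    "extract_promise_features",
    "score_nomogram",
    "load_nomogram",
]


class RiskGroup(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PromiseFeatures:
    tumour_count: int
    has_locoregional_nodes: bool
    has_extrapelvic_nodes: bool
    has_bone_mets: bool
    has_organ_mets: bool
    total_volume: float
    suv_mean: float  # volume-weighted mean lesion SUVmean

    def as_dict(self) -> dict[str, float | int | bool]:
        return {
            "tumour_count": self.tumour_count,
            "has_locoregional_nodes": self.has_locoregional_nodes,
            "has_extrapelvic_nodes": self.has_extrapelvic_nodes,
            "has_bone_mets": self.has_bone_mets,
            "has_organ_mets": self.has_organ_mets,
            "total_volume": self.total_volume,
            "suv_mean": self.suv_mean,
        }


_FEATURE_NAMES = frozenset(
    (
        "tumour_count",
        "has_locoregional_nodes",
        "has_extrapelvic_nodes",
        "has_bone_mets",
        "has_organ_mets",
        "total_volume",
        "suv_mean",
    )
)

#: site classes feeding the locoregional-node flag
_LOCOREGIONAL = {Site.LOCAL, Site.PELVIC_NODE}


def extract_promise_features(scan: ScanRecord) -> PromiseFeatures:
    """Deterministic feature extraction from a single scan.

    An empty scan yields the zero feature vector.  Lesions with unknown site
    still count toward tumour count and volume but contribute to no site
    flag (with a warning).
    """
    sites = [lesion.site for lesion in scan.lesions]
    if any(site is Site.UNKNOWN for site in sites):
        warnings.warn(
            f"{scan.patient_id}: lesion(s) with unknown site excluded from site flags"
        )
    total_volume = scan.total_volume
    if total_volume > 0:
        suv_mean = (
            sum(lesion.suv_mean * lesion.volume for lesion in scan.lesions)
            / total_volume
        )
    else:
        suv_mean = 0.0
    return PromiseFeatures(
        tumour_count=len(scan.lesions),
        has_locoregional_nodes=any(site in _LOCOREGIONAL for site in sites),
        has_extrapelvic_nodes=Site.EXTRAPELVIC_NODE in sites,
        has_bone_mets=Site.BONE in sites,
        has_organ_mets=Site.ORGAN in sites,
        total_volume=total_volume,
        suv_mean=suv_mean,
    )


@dataclass(frozen=True)
class NomogramModel:
    variant: str
    cutoff: float
    # feature -> fixed points (bool features) or knot table (continuous)
    points: Mapping[str, float | tuple[tuple[float, float], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        unknown = set(self.points) - _FEATURE_NAMES
        if unknown:
            raise ScoringError(f"unknown nomogram feature(s): {sorted(unknown)}")
        for name, spec in self.points.items():
            if isinstance(spec, tuple):
                xs = [x for x, _ in spec]
                if len(xs) < 2 or sorted(xs) != xs:
                    raise ScoringError(
                        f"feature {name}: knot x-values must be sorted, >= 2 knots"
                    )


def _contribution(name: str, value, spec) -> float:
    if isinstance(spec, tuple):
        value = float(value)
        xs = np.array([x for x, _ in spec], dtype=float)
        ys = np.array([y for _, y in spec], dtype=float)
        return float(np.interp(value, xs, ys))  # clamps outside knot range
    if isinstance(value, bool) or value in (0, 1):
        return float(spec) if value else 0.0
    raise ScoringError(f"feature {name}: fixed points require a boolean value")


def score_nomogram(
    features: PromiseFeatures, model: NomogramModel
) -> tuple[float, RiskGroup]:
    """Total points and risk group: high iff total >= model cutoff."""
    values = features.as_dict()
    total = 0.0
    for name, spec in model.points.items():
        total += _contribution(name, values[name], spec)
    risk = RiskGroup.HIGH if total >= model.cutoff else RiskGroup.LOW
    return total, risk


def load_nomogram(path: str | Path) -> NomogramModel:
    """Load an additive points model from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    points: dict[str, float | tuple[tuple[float, float], ...]] = {}
    for name, spec in (raw.get("points") or {}).items():
        if isinstance(spec, list):
            points[name] = tuple((float(x), float(y)) for x, y in spec)
        else:
            points[name] = float(spec)
    return NomogramModel(
        variant=str(raw.get("variant", "visual")),
        cutoff=float(raw["cutoff"]),
        points=points,
    )
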