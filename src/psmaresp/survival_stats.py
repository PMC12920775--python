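"""Survival endpoints analysis: Kaplan-Meier, log-rank, Cox PH, Harrell's C.

Thin, validated wrappers around lifelines, returning plain result objects
shaped like the per-framework report rows of the analysis (median time to
event per group, log-rank p, HR with Wald 95% CI and p, concordance index).

Two behaviours the raw library does not provide are added here:

* medians that the Kaplan-Meier curve never reaches are reported as a
  distinguished "not reached" value rather than infinity leaking into
  reports;
* quasi-complete separation — events concentrated entirely in one covariate
  group, which makes the Cox partial likelihood monotone in the coefficient
  — is detected up front and reported as a flagged non-converged row with
  diagnostics instead of a meaningless huge hazard ratio.

Cox fits use Efron's tie correction; month-scale data routinely contain
tied event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index

__all__ = [
    "NOT_REACHED",
    "SurvivalSample",
    "KMEstimate",
    "CoxResult",
    "km_estimate",
    "km_median",
    "logrank_test",
    "cox_univariate",
    "harrell_c",
]

#: sentinel serialised for medians the survival curve never crosses
NOT_REACHED = "NR"

# |beta| beyond this on a binary covariate means the partial likelihood is
# effectively monotone (HR > e^10 ~ 2e4): treat as failed convergence.
_BETA_DIVERGENCE_BOUND = 10.0


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data with an optional binary group label."""

    times: np.ndarray
    events: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if times.shape != events.shape:
            raise ValueError("times and events must have equal length")
        if times.size == 0:
            raise ValueError("empty survival sample")
        if np.any(times <= 0):
            raise ValueError("survival times must be positive")
        if self.group is not None:
            group = np.asarray(self.group, dtype=int)
            object.__setattr__(self, "group", group)
            if group.shape != times.shape:
                raise ValueError("group labels must match sample length")

    def subset(self, mask: np.ndarray) -> "SurvivalSample":
        return SurvivalSample(
            self.times[mask],
            self.events[mask],
            None if self.group is None else self.group[mask],
        )

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray  # event/censoring times of the step function
    survival: np.ndarray  # S(t) at those times
    median: float  # np.inf when never reached
    n: int
    n_events: int

    @property
    def median_label(self) -> str:
        return NOT_REACHED if np.isinf(self.median) else f"{self.median:.1f}"

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def at_risk(self, times: np.ndarray, sample_times: np.ndarray) -> np.ndarray:
        """Number still at risk at each requested time."""
        return np.array([(sample_times >= t).sum() for t in np.asarray(times)])


def km_estimate(sample: SurvivalSample) -> KMEstimate:
    """Product-limit survival estimate with median.

    The median is the smallest time where S(t) <= 0.5, infinite ("not
    reached") when the curve stays above 0.5.
    """
    fitter = KaplanMeierFitter()
    fitter.fit(sample.times, sample.events)
    sf = fitter.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(fitter.median_survival_time_),
        n=sample.n,
        n_events=int(sample.events.sum()),
    )


def km_median(sample: SurvivalSample) -> float:
    return km_estimate(sample).median


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    if not (a.events.any() or b.events.any()):
        raise ValueError("log-rank test undefined: no events in either group")
    res = _ll_logrank(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    beta: float | None
    se: float | None
    c_index: float | None
    converged: bool
    n: int
    n_events: int
    diagnostics: dict = field(default_factory=dict)

    def hr_label(self) -> str:
        if not self.converged:
            return "NA"
        return f"{self.hr:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def _separation_diagnostics(events: np.ndarray, indicator: np.ndarray) -> dict | None:
    """Detect quasi-complete separation for a binary covariate.

    With all observed events in one covariate group the partial likelihood
    is monotone in beta and the MLE diverges.
    """
    e1 = int(events[indicator == 1].sum())
    e0 = int(events[indicator == 0].sum())
    if (e1 == 0) != (e0 == 0):  # events, but only in one group
        return {
            "reason": "quasi_complete_separation",
            "events_group0": e0,
            "events_group1": e1,
        }
    return None


def cox_univariate(sample: SurvivalSample, indicator: np.ndarray) -> CoxResult:
    """Univariate Cox proportional-hazards fit on a binary covariate.

    Efron tie handling; Wald 95% CI and p-value.  Returns a flagged
    non-converged result (no numeric HR) under quasi-complete separation or
    a diverging coefficient, mirroring how such rows are reported as NA in
    clinical tables.
    """
    indicator = np.asarray(indicator, dtype=int)
    if indicator.shape != sample.times.shape:
        raise ValueError("indicator must match sample length")
    if len(np.unique(indicator)) < 2:
        raise ValueError("degenerate design: indicator is constant")
    n_events = int(sample.events.sum())
    if n_events == 0:
        raise ValueError("no events in sample")

    sep = _separation_diagnostics(sample.events, indicator)
    if sep is not None:
        return CoxResult(None, None, None, None, None, None, None,
                         converged=False, n=sample.n, n_events=n_events,
                         diagnostics=sep)

    frame = pd.DataFrame(
        {"time": sample.times, "event": sample.events.astype(int), "x": indicator}
    )
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tight precision: small-sample fits must agree with the exact
            # partial-likelihood maximiser to ~1e-4
            fitter.fit(
                frame, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except ConvergenceError as exc:
        return CoxResult(None, None, None, None, None, None, None,
                         converged=False, n=sample.n, n_events=n_events,
                         diagnostics={"reason": "convergence_error", "detail": str(exc)})
    beta = float(fitter.params_["x"])
    se = float(fitter.standard_errors_["x"])
    if abs(beta) > _BETA_DIVERGENCE_BOUND:
        return CoxResult(None, None, None, None, beta, se, None,
                         converged=False, n=sample.n, n_events=n_events,
                         diagnostics={"reason": "monotone_likelihood", "beta": beta})
    z = 1.959963984540054  # Phi^-1(0.975)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(fitter.summary.loc["x", "p"]),
        beta=beta,
        se=se,
        c_index=float(fitter.concordance_index_),
        converged=True,
        n=sample.n,
        n_events=n_events,
    )


def harrell_c(sample: SurvivalSample, scores: np.ndarray) -> float:
    """Harrell's concordance index of risk scores against event times.

    Higher score is read as higher risk (earlier expected event); tied
    scores count 0.5; pairs unusable under censoring are excluded.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != sample.times.shape:
        raise ValueError("scores must match sample length")
    if not sample.events.any():
        raise ValueError("concordance undefined: no usable pairs (no events)")
    # lifelines' convention: higher prediction = longer survival, hence -scores
    return float(concordance_index(sample.times, -scores, sample.events))
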