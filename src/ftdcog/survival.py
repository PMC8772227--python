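"""Time-to-event analysis of progression from prodromal to symptomatic FTD.

Builds survival records for carriers observed at CDR global 0.5 at baseline
with at least one follow-up visit: the event is the first visit with
cdr_global >= 1 (conversion assigned to the visit time at which it is first
observed); otherwise the record is censored at the last follow-up.  The
Kaplan-Meier product-limit estimator with Greenwood variance and
log(-log)-transformed confidence bounds summarizes cumulative conversion;
a k-group log-rank test compares progression across genetic groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import VisitHistory

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalRecord:
    id: str
    group: str
    time: float  # years from the first CDR-0.5 visit
    event: bool  # True = observed progression to cdr_global >= 1

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise SurvivalError(f"{self.id}: event/censoring time must be > 0")


@dataclass
class KMCurve:
    """Kaplan-Meier estimate over distinct event times with Greenwood SE."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    se: np.ndarray  # Greenwood standard error of S(t)
    ci_lower: np.ndarray  # 95% log(-log) bounds
    ci_upper: np.ndarray
    n_subjects: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_incidence_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def build_survival_records(
    histories: Sequence[VisitHistory],
    groups: Mapping[str, str] | None = None,
    return_report: bool = False,
):
    """Survival records for histories starting at CDR 0.5 with follow-up.

    ``groups`` maps participant id to genetic group (default: unlabelled).
    Histories whose baseline is not CDR 0.5, or with no follow-up visit, are
    excluded and counted in the exclusion report (returned when
    ``return_report`` is true, otherwise logged).
    """
    records: list[SurvivalRecord] = []
    report = {"baseline_not_05": 0, "no_followup": 0, "included": 0}
    for h in histories:
        if not h.visits or h.visits[0][1] != 0.5:
            report["baseline_not_05"] += 1
            continue
        followup = h.visits[1:]
        if not followup:
            report["no_followup"] += 1
            continue
        group = groups.get(h.id, "all") if groups else "all"
        event_visits = [(t, c) for t, c in followup if c >= 1.0]
        if event_visits:
            records.append(SurvivalRecord(h.id, group, event_visits[0][0], True))
        else:
            records.append(SurvivalRecord(h.id, group, followup[-1][0], False))
        report["included"] += 1
    if report["baseline_not_05"] or report["no_followup"]:
        logger.info("survival exclusions: %s", report)
    return (records, report) if return_report else records


def km_estimate(records: Sequence[SurvivalRecord], group: str = "all") -> KMCurve:
    """Product-limit estimator with Greenwood variance and log(-log) 95% CI."""
    if not records:
        raise SurvivalError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    if not events.any():
        logger.warning("km_estimate: all records censored; survival curve is flat at 1")
        return KMCurve(
            group=group,
            times=np.array([]),
            at_risk=np.array([], dtype=int),
            events=np.array([], dtype=int),
            survival=np.array([]),
            se=np.array([]),
            ci_lower=np.array([]),
            ci_upper=np.array([]),
            n_subjects=len(records),
        )
    ev_times = np.unique(times[events])
    n_at_risk = np.array([(times >= t).sum() for t in ev_times])
    d = np.array([((times == t) & events).sum() for t in ev_times])
    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf))
        se = surv * np.sqrt(gw)
        se = np.where(surv == 0.0, 0.0, se)
        # log(-log) transformed bounds stay inside [0, 1]
        zq = stats.norm.ppf(0.975)
        logs = np.log(surv, where=surv > 0, out=np.full_like(surv, -np.inf))
        theta = np.where(
            (surv > 0) & (surv < 1) & np.isfinite(gw),
            zq * np.sqrt(gw) / np.abs(logs),
            0.0,
        )
        lower = np.where(surv > 0, surv ** np.exp(theta), surv)
        upper = np.where(surv > 0, surv ** np.exp(-theta), surv)
    lower = np.clip(lower, 0.0, 1.0)
    upper = np.clip(upper, 0.0, 1.0)
    return KMCurve(
        group=group,
        times=ev_times,
        at_risk=n_at_risk,
        events=d,
        survival=surv,
        se=np.nan_to_num(se, nan=0.0, posinf=0.0),
        ci_lower=lower,
        ci_upper=upper,
        n_subjects=len(records),
    )


def km_by_group(records: Sequence[SurvivalRecord]) -> dict[str, KMCurve]:
    out: dict[str, KMCurve] = {}
    for g in sorted({r.group for r in records}):
        out[g] = km_estimate([r for r in records if r.group == g], group=g)
    return out


def logrank_test(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """k-group log-rank test (hypergeometric variance at tied event times)."""
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise SurvivalError(f"log-rank test needs >= 2 groups, got {groups}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=int)
    labels = np.array([r.group for r in records])
    res = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "group": r.group, "time": r.time, "event": r.event} for r in records]
    )
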