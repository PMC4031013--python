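"""Risk stratification on the wave-intensity compression peak.

The decompensation threshold is derived from a reference group of truly
decompensated patients as mean + SD of their W1 values; ambulatory patients
with W1 below the threshold are classified high-risk.  Prognostic value is
quantified with a 2x2 contingency table and Woolf log-normal odds-ratio
confidence interval (Haldane–Anscombe corrected when cells are empty),
event-free Kaplan–Meier curves per risk stratum, and Welch group
comparisons computed from summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import (
    DegenerateTableError,
    DomainError,
    InputError,
    InsufficientDataError,
    JoinError,
)
from .wi import WIPatientResult

__all__ = [
    "ReferenceCutoff",
    "ContingencyTable",
    "OddsRatioResult",
    "SurvivalCurve",
    "WelchResult",
    "StratificationReport",
    "derive_cutoff",
    "derive_cutoff_from_summary",
    "classify",
    "build_contingency",
    "odds_ratio",
    "km_event_free",
    "compare_groups_from_summary",
    "event_summary",
    "stratify_cohort",
]

EVENT_TYPES = ("death", "vad", "htx")


@dataclass(frozen=True)
class ReferenceCutoff:
    """Reference-group mean, SD and the mean+SD decision threshold."""

    reference_mean: float
    reference_sd: float
    cutoff: float
    n_reference: int

    def __post_init__(self) -> None:
        if self.reference_sd < 0:
            raise DomainError("reference SD must be non-negative")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 risk-class vs event cross-tabulation.

    a: low-risk event-free, b: high-risk event-free,
    c: low-risk with event, d: high-risk with event.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"cell {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    corrected: bool = False


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier event-free survival at the distinct event times."""

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12):
            raise InputError("survival must be non-increasing and start <= 1")

    def at(self, t: float) -> float:
        """Survival probability S(t) (right-continuous step function)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float


def derive_cutoff(reference_w1_values: Sequence[float]) -> ReferenceCutoff:
    """Mean + sample SD (n−1) of the reference group's W1 values."""
    values = np.asarray(list(reference_w1_values), dtype=float)
    if len(values) < 2:
        raise InsufficientDataError("need at least 2 reference values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ReferenceCutoff(reference_mean=mean, reference_sd=sd,
                           cutoff=mean + sd, n_reference=len(values))


def derive_cutoff_from_summary(mean: float, sd: float,
                               n_reference: int = 0) -> ReferenceCutoff:
    """Cutoff from a published mean ± SD summary rather than raw values."""
    if sd < 0:
        raise DomainError("SD must be non-negative")
    return ReferenceCutoff(reference_mean=mean, reference_sd=sd,
                           cutoff=mean + sd, n_reference=n_reference)


def classify(w1: float, cutoff: Union[ReferenceCutoff, float]) -> str:
    """'high_risk' iff w1 < cutoff; exactly at the cutoff is low-risk."""
    if not np.isfinite(w1):
        raise DomainError("w1 must be finite")
    if w1 < 0:
        raise DomainError("w1 must be non-negative")
    threshold = cutoff.cutoff if isinstance(cutoff, ReferenceCutoff) else float(cutoff)
    return "high_risk" if w1 < threshold else "low_risk"


def build_contingency(classifications: Sequence[str],
                      events: Sequence[bool]) -> ContingencyTable:
    """Cross-tabulate risk classes against event flags."""
    if len(classifications) != len(events):
        raise InputError("classifications and events lengths differ")
    if len(classifications) == 0:
        raise InputError("need at least one patient")
    a = b = c = d = 0
    for cls, ev in zip(classifications, events):
        if cls not in ("low_risk", "high_risk"):
            raise InputError(f"unknown class {cls!r}")
        if cls == "low_risk":
            c, a = (c + 1, a) if ev else (c, a + 1)
        else:
            d, b = (d + 1, b) if ev else (d, b + 1)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(table: ContingencyTable, level: float = 0.95,
               correction: bool = True) -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with Woolf log-normal confidence interval.

    When any cell is zero, the Haldane–Anscombe +0.5 correction is applied
    to all four cells (flagged); with ``correction=False`` an empty b or c
    cell raises instead.  The two-sided p-value comes from the log-OR
    z-statistic.
    """
    if not 0 < level < 1:
        raise InputError("level must lie in (0, 1)")
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    corrected = False
    if np.any(cells == 0):
        if not correction:
            raise DegenerateTableError("zero cell without correction enabled")
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(or_value)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=or_value,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p), level=level, corrected=corrected)


def km_event_free(followup_months: Sequence[float],
                  event_flags: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier product-limit event-free survival.

    Any composite event counts as the endpoint; event-free patients are
    right-censored at their follow-up time.  Ties are handled with the
    standard convention (events before censorings at the same time).
    """
    times = np.asarray(list(followup_months), dtype=float)
    events = np.asarray(list(event_flags), dtype=bool)
    if len(times) != len(events):
        raise InputError("followup and event lengths differ")
    if len(times) == 0:
        raise InputError("need at least one patient")
    if np.any(times < 0):
        raise DomainError("follow-up times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    return SurvivalCurve(
        times=event_times,
        n_at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        n_events=event_rows["observed"].to_numpy(dtype=int),
        survival=surv)


def compare_groups_from_summary(mean1: float, sd1: float, n1: int,
                                mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch unequal-variance t-test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise DomainError("SDs must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return WelchResult(t_statistic=float(res.statistic),
                       degrees_of_freedom=float(df),
                       p_two_sided=float(res.pvalue))


def event_summary(event_types: Sequence[str]) -> dict:
    """Counts and one-decimal percentages of the composite-event mix."""
    types = list(event_types)
    n = len(types)
    counts = {t: types.count(t) for t in EVENT_TYPES}
    total = sum(counts.values())
    return {
        "n_patients": n,
        "counts": counts,
        "percentages": {t: round(100.0 * c / n, 1) for t, c in counts.items()},
        "total_events": total,
        "total_event_pct": round(100.0 * total / n, 1) if n else 0.0,
        "event_free_n": n - total,
    }


@dataclass
class StratificationReport:
    """End-to-end prognostic report for one cohort."""

    n_patients: int
    cutoff: ReferenceCutoff
    classifications: pd.Series
    table: ContingencyTable
    odds_ratio: OddsRatioResult
    events: dict
    km_all: SurvivalCurve
    km_low_risk: Optional[SurvivalCurve]
    km_high_risk: Optional[SurvivalCurve]
    n_low_risk: int = 0
    n_high_risk: int = 0


def _as_results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = pd.DataFrame(
            [{"patient_id": r.patient_id, "w1": r.w1} for r in results])
    if "patient_id" not in frame.columns or "w1" not in frame.columns:
        raise InputError("results need patient_id and w1 columns")
    return frame


def stratify_cohort(results, outcomes: pd.DataFrame,
                    cutoff: Union[ReferenceCutoff, float],
                    level: float = 0.95) -> StratificationReport:
    """Classify, cross-tabulate, estimate the OR and per-stratum KM curves.

    ``results`` is a list of :class:`WIPatientResult` or a frame with
    ``patient_id``/``w1`` columns; ``outcomes`` needs ``patient_id``,
    ``event``, ``event_type`` and ``followup_months``.  Patient identifiers
    must match one-to-one.
    """
    res = _as_results_frame(results)
    required = {"patient_id", "event", "event_type", "followup_months"}
    missing = required - set(outcomes.columns)
    if missing:
        raise InputError(f"outcomes table missing columns: {sorted(missing)}")
    res_ids = set(res["patient_id"])
    out_ids = set(outcomes["patient_id"])
    if res_ids != out_ids:
        offenders = sorted(res_ids.symmetric_difference(out_ids))
        raise JoinError(f"unmatched patient ids: {offenders[:10]}"
                        f"{'...' if len(offenders) > 10 else ''}")
    merged = res.merge(outcomes, on="patient_id", validate="one_to_one")
    if not isinstance(cutoff, ReferenceCutoff):
        cutoff = ReferenceCutoff(reference_mean=float(cutoff), reference_sd=0.0,
                                 cutoff=float(cutoff), n_reference=0)
    classes = merged["w1"].map(lambda w: classify(w, cutoff))
    events = merged["event"].astype(bool)
    table = build_contingency(list(classes), list(events))
    or_result = odds_ratio(table, level=level)
    km_all = km_event_free(merged["followup_months"], events)
    low = classes == "low_risk"
    high = ~low
    km_low = km_event_free(merged.loc[low, "followup_months"],
                           events[low]) if low.any() else None
    km_high = km_event_free(merged.loc[high, "followup_months"],
                            events[high]) if high.any() else None
    return StratificationReport(
        n_patients=len(merged), cutoff=cutoff,
        classifications=pd.Series(classes.values, index=merged["patient_id"].values),
        table=table, odds_ratio=or_result,
        events=event_summary(list(merged["event_type"])),
        km_all=km_all, km_low_risk=km_low, km_high_risk=km_high,
        n_low_risk=int(low.sum()), n_high_risk=int(high.sum()))
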