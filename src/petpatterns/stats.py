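"""Association, diagnostic-performance and survival statistics.

Chi-square tests use the Pearson statistic without continuity correction
(scipy); diagnostic measures come with Wilson-score 95% confidence
intervals (statsmodels), configurable to exact binomial; Kaplan-Meier and
log-rank computations go through lifelines. Adjusted standardized
residuals, the crosstab inclusion logic, and greedy exact-stratum matching
are implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .scoring import PatientRecord

__all__ = [
    "ContingencyTable",
    "DiagnosticMeasure",
    "DiagnosticPerformance",
    "SurvivalCurve",
    "crosstab",
    "pearson_chi_square",
    "adjusted_residuals",
    "diagnostic_performance",
    "km_estimator",
    "os_at",
    "logrank",
    "match_controls",
]


@dataclass
class ContingencyTable:
    """An r x c table of observed counts with labeled margins."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("contingency counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("contingency counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count grid")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def crosstab(
    patients: list[PatientRecord],
    row_var,
    col_var,
    *,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> ContingencyTable:
    """Cross-classify patients by two variables.

    ``row_var`` / ``col_var`` are either attribute names of
    :class:`PatientRecord` or callables ``patient -> label``; a callable may
    return ``None`` to exclude the patient (the exclusion is recorded with a
    reason rather than silently dropped).
    """
    if not patients:
        raise ValueError("empty cohort")

    def resolve(var):
        if callable(var):
            return var
        return lambda p: getattr(p, var)

    rf, cf = resolve(row_var), resolve(col_var)
    rows, cols, excluded = [], [], []
    for p in patients:
        r, c = rf(p), cf(p)
        if r is None or c is None:
            which = "row" if r is None else "col"
            excluded.append((p.patient_id, f"{which} variable undefined"))
            continue
        rows.append(str(r))
        cols.append(str(c))
    if not rows:
        raise ValueError("no classifiable patients")
    frame = pd.crosstab(pd.Series(rows, name="row"), pd.Series(cols, name="col"))
    if row_labels is not None:
        frame = frame.reindex(index=row_labels, fill_value=0)
    if col_labels is not None:
        frame = frame.reindex(columns=col_labels, fill_value=0)
    return ContingencyTable(
        frame.to_numpy(dtype=float),
        list(frame.index),
        list(frame.columns),
        excluded=excluded,
    )


def _check_margins(table: ContingencyTable) -> None:
    row_sums = table.counts.sum(axis=1)
    col_sums = table.counts.sum(axis=0)
    if np.any(row_sums == 0):
        bad = [table.row_labels[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"degenerate contingency table: zero row margin for {bad}")
    if np.any(col_sums == 0):
        bad = [table.col_labels[i] for i in np.flatnonzero(col_sums == 0)]
        raise ValueError(f"degenerate contingency table: zero column margin for {bad}")


def pearson_chi_square(
    table: ContingencyTable, *, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p).

    No Yates continuity correction by default.
    """
    if min(table.counts.shape) < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    _check_margins(table)
    res = sps.chi2_contingency(table.counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def adjusted_residuals(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell adjusted standardized residuals and two-sided normal p-values.

    Residual = (O - E) / sqrt(E (1 - row_frac)(1 - col_frac)); under
    independence each is approximately standard normal, giving a post-hoc
    cell-wise read-out of which cells drive a significant chi-square.
    """
    _check_margins(table)
    obs = table.counts
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    z = (obs - expected) / denom
    p = 2 * sps.norm.sf(np.abs(z))
    return z, p


@dataclass
class DiagnosticMeasure:
    """A percentage with its two-sided 95% confidence interval."""

    estimate_pct: float
    ci_low_pct: float
    ci_high_pct: float

    def __post_init__(self) -> None:
        if not self.ci_low_pct - 1e-9 <= self.estimate_pct <= self.ci_high_pct + 1e-9:
            raise ValueError("point estimate outside its confidence interval")


@dataclass
class DiagnosticPerformance:
    """Sensitivity, specificity, PPV and NPV of a binary test vs an outcome.

    A measure with a zero denominator is ``None`` (undefined), not 0.
    """

    sensitivity: DiagnosticMeasure | None
    specificity: DiagnosticMeasure | None
    ppv: DiagnosticMeasure | None
    npv: DiagnosticMeasure | None


def _measure(successes: int, total: int, method: str) -> DiagnosticMeasure | None:
    if total == 0:
        return None
    lo, hi = proportion_confint(successes, total, alpha=0.05, method=method)
    return DiagnosticMeasure(
        estimate_pct=100.0 * successes / total,
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
    )


def diagnostic_performance(
    tp: int, fn: int, fp: int, tn: int, *, ci_method: str = "wilson"
) -> DiagnosticPerformance:
    """Diagnostic measures from a 2x2 test-vs-outcome table.

    ``ci_method`` is "wilson" (default) or "beta" (Clopper-Pearson exact),
    passed through to statsmodels.
    """
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative, got {v}")
    return DiagnosticPerformance(
        sensitivity=_measure(tp, tp + fn, ci_method),
        specificity=_measure(tn, tn + fp, ci_method),
        ppv=_measure(tp, tp + fp, ci_method),
        npv=_measure(tn, tn + fn, ci_method),
    )


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier step function: S(0) = 1, non-increasing."""

    event_times: np.ndarray  # days, sorted, times with at least one event
    survival_probs: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray  # at-risk count just before each event time
    max_follow_up: float

    def survival_at(self, t: float) -> float:
        """S(t): step value after the last event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def km_estimator(times, events) -> SurvivalCurve:
    """Product-limit survival estimate.

    Ties between deaths and censorings at the same time are handled
    events-first (the censored subject is still at risk at that time), the
    standard convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    probs = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=event_times,
        survival_probs=probs,
        n_at_risk=n_at_risk,
        max_follow_up=float(times.max()),
    )


def os_at(curve: SurvivalCurve, horizon_days: float) -> tuple[float, bool]:
    """Survival probability at ``horizon_days``: (S(horizon), extrapolated).

    ``extrapolated`` is True when the horizon exceeds the last follow-up, in
    which case the last step value is carried forward.
    """
    if horizon_days < 0:
        raise ValueError("horizon must be non-negative")
    return curve.survival_at(horizon_days), horizon_days > curve.max_follow_up


def logrank(groups: list[tuple]) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups: (chi-square statistic, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, events, labels = [], [], []
    for gi, (times, evts) in enumerate(groups):
        times = np.asarray(times, dtype=float)
        evts = np.asarray(evts, dtype=bool)
        if times.size == 0:
            raise ValueError(f"log-rank group {gi} has no subjects")
        durations.append(times)
        events.append(evts)
        labels.append(np.full(times.size, gi))
    res = multivariate_logrank_test(
        np.concatenate(durations), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def match_controls(
    cases: list[PatientRecord],
    controls: list[PatientRecord],
    *,
    strata_vars: tuple[str, ...] = ("ipi", "ann_arbor_stage", "extranodal_count"),
    k: int = 1,
    seed: int = 0,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Greedy 1:k exact-stratum matching without replacement.

    Controls are drawn in a seeded random order within each case's exact
    stratum (equal values on every stratum variable). Returns
    ``(matched_controls, unmatched_cases)``; a case is unmatched when its
    stratum has no remaining control (partial matches below ``k`` count as
    matched with fewer controls).
    """
    if not controls:
        raise ValueError("empty control pool")

    def stratum(p: PatientRecord):
        vals = tuple(getattr(p, v) for v in strata_vars)
        if any(v is None for v in vals):
            raise ValueError(f"patient {p.patient_id} lacks stratum variables {strata_vars}")
        return vals

    rng = np.random.default_rng(seed)
    pool: dict[tuple, list[PatientRecord]] = {}
    for c in controls:
        pool.setdefault(stratum(c), []).append(c)
    for members in pool.values():
        rng.shuffle(members)  # type: ignore[arg-type]

    matched: list[PatientRecord] = []
    unmatched: list[PatientRecord] = []
    case_order = list(cases)
    rng.shuffle(case_order)  # type: ignore[arg-type]
    for case in case_order:
        members = pool.get(stratum(case), [])
        if not members:
            unmatched.append(case)
            continue
        take = min(k, len(members))
        matched.extend(members[:take])
        del members[:take]
    return matched, unmatched
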