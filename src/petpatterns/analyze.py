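"""Cohort-level analysis reports.

Assembles the statistics the pipeline reports — response-positivity and
conversion rates, the MYC x response-pattern chi-square with cell-wise
adjusted residuals, lesional SUV/MTV increase proportions, new-site
proportions, Kaplan-Meier 2-year overall survival, log-rank comparisons and
diagnostic performance — either from the packaged reference tallies
(:func:`fixture_report`) or from a cohort of patient records
(:func:`cohort_report`). Every rate in a report carries its numerator and
denominator; percentages are rounded half-up to one decimal at this
reporting layer only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from . import fixtures
from .scoring import (
    PatientRecord,
    ResponsePattern,
    UnclassifiablePatientError,
    classify_pattern,
)
from .stats import (
    ContingencyTable,
    adjusted_residuals,
    crosstab,
    diagnostic_performance,
    km_estimator,
    logrank,
    os_at,
    pearson_chi_square,
)
from .synthetic import DAYS_PER_YEAR

__all__ = ["round_half_up", "rate", "fixture_report", "cohort_report"]

COMPLETE = [p.value for p in (
    ResponsePattern.INEG_ENEG,
    ResponsePattern.INEG_EPOS,
    ResponsePattern.IPOS_ENEG,
    ResponsePattern.IPOS_EPOS,
)]


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate(numerator: int, denominator: int) -> dict:
    """A reported proportion: counts plus the display percentage."""
    if denominator == 0:
        return {"n": numerator, "of": denominator, "pct": None}
    return {
        "n": int(numerator),
        "of": int(denominator),
        "pct": round_half_up(100.0 * numerator / denominator, 1),
    }


def _scan_status(p: PatientRecord, timepoint: str, cutoff: str) -> str | None:
    scan = p.scan(timepoint)
    if scan is None or scan.patient_ds is None:
        return None
    from .scoring import binarize_response

    return "positive" if binarize_response(scan.patient_ds, cutoff) else "negative"


def _group_rates(patients: list[PatientRecord], cutoff: str) -> dict:
    """Positivity and conversion rates for one MYC group.

    Denominators are pairwise per analysis: a patient enters the I-PET rate
    only with a reviewed I-PET, the conversion rate only when I-PET-negative
    with a reviewed EoT scan.
    """
    out: dict = {}
    for tp, key in (("I-PET", "ipet"), ("EoT-PET", "eot")):
        statuses = [_scan_status(p, tp, cutoff) for p in patients]
        reviewed = [s for s in statuses if s is not None]
        out[f"{key}_positivity"] = rate(
            sum(s == "positive" for s in reviewed), len(reviewed)
        )
    converters = denom = 0
    for p in patients:
        if _scan_status(p, "I-PET", cutoff) != "negative":
            continue
        e = _scan_status(p, "EoT-PET", cutoff)
        if e is None:
            continue
        denom += 1
        converters += e == "positive"
    out["conversion_ineg_to_epos"] = rate(converters, denom)
    return out


def _pattern_table(
    myc_pos: list[PatientRecord], myc_neg: list[PatientRecord], cutoff: str
) -> ContingencyTable:
    """2 x 4 complete-pattern table (patients with both scans reviewed)."""

    def pattern_or_none(p: PatientRecord):
        try:
            pat = classify_pattern(p, cutoff)
        except UnclassifiablePatientError:
            return None
        return pat.value if pat.value in COMPLETE else None

    group = {id(p): "MYC+" for p in myc_pos}
    return crosstab(
        myc_pos + myc_neg,
        lambda p: group.get(id(p), "MYC-"),
        pattern_or_none,
        row_labels=["MYC+", "MYC-"],
        col_labels=COMPLETE,
    )


def fixture_report(cutoff: str = "DS1-3 vs 4-5") -> dict:
    """Run the scoring + statistics pipeline on the packaged reference tallies."""
    pos = fixtures.expand_response_patterns(("positive",))
    neg = fixtures.expand_response_patterns(("negative",))
    matched = fixtures.expand_response_patterns(("matched_negative",))

    report: dict = {
        "cutoff": cutoff,
        "myc_positive": _group_rates(pos, cutoff),
        "myc_negative": _group_rates(neg, cutoff),
        "myc_negative_matched": _group_rates(matched, cutoff),
    }

    table = _pattern_table(pos, neg, cutoff)
    stat, df, p = pearson_chi_square(table)
    z, cell_p = adjusted_residuals(table)
    report["pattern_association"] = {
        "table": table.to_frame().astype(int).to_dict(),
        "n": table.n,
        "chi_square": stat,
        "df": df,
        "p": p,
        "adjusted_residuals": z.tolist(),
        "cell_p": cell_p.tolist(),
    }

    changes = fixtures.load_lesion_changes()
    change_rates: dict = {}
    for _, row in changes.iterrows():
        key = f"{row.myc_group}_{row.measure}_{row.comparison}"
        change_rates[key] = rate(row.increase, row.increase + row.no_increase)
    # joint SUV-and-MTV increase at EoT vs I-PET: the tallies record equal
    # increase counts for the two measures in the same patients, so the
    # shared marginal is the joint rate; fall back to the inclusion-
    # exclusion lower bound if a reconfigured fixture breaks the equality
    for grp in ("positive", "negative"):
        suv = change_rates[f"{grp}_suv_ipet_vs_eot"]
        mtv = change_rates[f"{grp}_mtv_ipet_vs_eot"]
        if suv["n"] == mtv["n"]:
            change_rates[f"{grp}_both_ipet_vs_eot"] = suv
        else:
            change_rates[f"{grp}_both_ipet_vs_eot"] = rate(
                max(0, suv["n"] + mtv["n"] - suv["of"]), suv["of"]
            )
    report["lesion_changes"] = change_rates

    new_sites = fixtures.load_new_sites()
    eot_pos = {
        grp: report[f"myc_{label}"]["eot_positivity"]["n"]
        for grp, label in (("positive", "positive"), ("negative", "negative"))
    }
    report["new_sites_vs_baseline"] = {
        grp: rate(int((new_sites.myc_group == grp).sum()), eot_pos[grp])
        for grp in ("positive", "negative")
    }
    return report


def cohort_report(
    patients: list[PatientRecord],
    cutoff: str = "DS1-3 vs 4-5",
    *,
    os_horizon_years: float = 2.0,
) -> dict:
    """Full statistical report for a cohort of patient records."""
    if not patients:
        raise ValueError("empty cohort")
    pos = [p for p in patients if p.myc_positive]
    neg = [p for p in patients if not p.myc_positive]

    unclassifiable = []
    for p in patients:
        try:
            classify_pattern(p, cutoff)
        except UnclassifiablePatientError as exc:
            unclassifiable.append({"patient_id": p.patient_id, "reason": str(exc)})

    report: dict = {
        "cutoff": cutoff,
        "n_patients": len(patients),
        "unclassifiable": unclassifiable,
        "myc_positive": _group_rates(pos, cutoff) if pos else None,
        "myc_negative": _group_rates(neg, cutoff) if neg else None,
    }

    if pos and neg:
        table = _pattern_table(pos, neg, cutoff)
        try:
            stat, df, p = pearson_chi_square(table)
            report["pattern_association"] = {
                "n": table.n, "chi_square": stat, "df": df, "p": p,
            }
        except ValueError as exc:
            report["pattern_association"] = {"undefined": str(exc)}

    horizon_days = os_horizon_years * DAYS_PER_YEAR
    survival: dict = {}
    for label, group in (("myc_positive", pos), ("myc_negative", neg)):
        with_fu = [
            p for p in group if p.os_time_days is not None and p.os_event is not None
        ]
        if not with_fu:
            continue
        entry: dict = {}
        by_eot: dict[str, list[PatientRecord]] = {"negative": [], "positive": []}
        for p in with_fu:
            s = _scan_status(p, "EoT-PET", cutoff)
            if s is not None:
                by_eot[s].append(p)
        for status, members in by_eot.items():
            if not members:
                continue
            curve = km_estimator(
                [p.os_time_days for p in members], [p.os_event for p in members]
            )
            s_h, extrapolated = os_at(curve, horizon_days)
            entry[f"os{os_horizon_years:g}y_eot_{status}"] = {
                "pct": round_half_up(100 * s_h, 1),
                "n": len(members),
                "extrapolated": extrapolated,
            }
        if all(by_eot.values()):
            lr_stat, lr_df, lr_p = logrank(
                [
                    (
                        [p.os_time_days for p in members],
                        [p.os_event for p in members],
                    )
                    for members in by_eot.values()
                ]
            )
            entry["logrank_eot"] = {"chi_square": lr_stat, "df": lr_df, "p": lr_p}
        # diagnostic performance of each scan against the survival outcome;
        # patients censored before the horizon have unknown outcome status
        for tp, key in (("I-PET", "ipet"), ("EoT-PET", "eot")):
            counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
            for p in with_fu:
                s = _scan_status(p, tp, cutoff)
                if s is None:
                    continue
                died = p.os_event and p.os_time_days <= horizon_days
                alive = p.os_time_days >= horizon_days and not (
                    p.os_event and p.os_time_days <= horizon_days
                )
                if not died and not alive:
                    continue  # censored before horizon: outcome unknown
                test_pos = s == "positive"
                if test_pos and died:
                    counts["tp"] += 1
                elif test_pos:
                    counts["fp"] += 1
                elif died:
                    counts["fn"] += 1
                else:
                    counts["tn"] += 1
            if sum(counts.values()):
                perf = diagnostic_performance(**counts)
                entry[f"diagnostic_{key}"] = {
                    "counts": counts,
                    **{
                        name: (
                            None
                            if m is None
                            else {
                                "pct": round_half_up(m.estimate_pct, 1),
                                "ci": [
                                    round_half_up(m.ci_low_pct, 1),
                                    round_half_up(m.ci_high_pct, 1),
                                ],
                            }
                        )
                        for name, m in (
                            ("sensitivity", perf.sensitivity),
                            ("specificity", perf.specificity),
                            ("ppv", perf.ppv),
                            ("npv", perf.npv),
                        )
                    },
                }
        survival[label] = entry
    report["survival"] = survival
    return report
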