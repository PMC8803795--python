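"""Deauville scoring, QC verdicts, change flags and response patterns.

Maps quantitative lesion observations to the Deauville 5-point scale (DS),
aggregates lesion scores to a patient score, binarizes response at three DS
cut-offs, applies smallest-detectable-change rules to longitudinal SUVmax
and MTV, detects newly involved anatomical sites, and combines interim
(I-PET) and end-of-treatment (EoT-PET) responses into the six-way response
pattern used for cohort cross-classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "NODAL_SITES",
    "EXTRANODAL_SITES",
    "Site",
    "site_from_text",
    "LesionObservation",
    "ScanAssessment",
    "PatientRecord",
    "ResponsePattern",
    "QcVerdict",
    "QcRanges",
    "CUTOFFS",
    "assign_lesion_ds",
    "patient_ds",
    "resolve_reviews",
    "binarize_response",
    "qc_scan",
    "flag_suv_increase",
    "flag_mtv_increase",
    "suv_increase_cutoff",
    "detect_new_sites",
    "classify_pattern",
    "delta_suv_response",
    "UnresolvedDiscrepancyError",
    "UnclassifiablePatientError",
]

# Prespecified case-record-form localizations; free text maps to the "other"
# bucket of its category with the text kept as an annotation.
NODAL_SITES = (
    "waldeyers_ring",
    "cervical",
    "supraclavicular",
    "axillary",
    "mediastinum",
    "hilar",
    "paraaortic",
    "mesenteric",
    "spleen",
    "iliac",
    "inguinal",
    "other_nodal",
)
EXTRANODAL_SITES = (
    "gastrointestinal",
    "central_nervous_system",
    "skin",
    "liver",
    "lung",
    "pleural",
    "skeletal",
    "other_extranodal",
)


@dataclass(frozen=True)
class Site:
    """One prespecified nodal or extranodal localization.

    Free-text localizations (e.g. "thyroid") live in the matching "other"
    bucket with the original text preserved in ``annotation``; the annotation
    participates in equality so distinct free-text sites stay distinct.
    """

    name: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.name not in NODAL_SITES + EXTRANODAL_SITES:
            raise ValueError(f"unknown site {self.name!r}")

    @property
    def category(self) -> str:
        return "nodal" if self.name in NODAL_SITES else "extranodal"


def site_from_text(text: str, *, category: str = "extranodal") -> Site:
    """Resolve a localization string to a :class:`Site`.

    Known names resolve directly; anything else falls into the "other" bucket
    of ``category`` with the text kept as annotation.
    """
    key = text.strip().lower().replace(" ", "_").replace("'", "")
    if key in NODAL_SITES + EXTRANODAL_SITES:
        return Site(key)
    if category not in ("nodal", "extranodal"):
        raise ValueError(f"category must be nodal or extranodal, got {category!r}")
    return Site(f"other_{category}", annotation=text.strip())


@dataclass
class LesionObservation:
    """One lesion at one timepoint."""

    site: Site
    suv_max: float | None = None  # None = no residual uptake
    suv_peak: float | None = None
    mtv_ml: float | None = None
    method: str = "SUV4.0"
    is_new: bool = False
    lesion_id: str = "lesion"


class QcVerdict(str, Enum):
    PASS = "pass"
    PASS_BY_ACTIVITY = "pass-by-activity"
    FAIL = "fail"


@dataclass
class ScanAssessment:
    """One patient-scan: references, QC inputs, lesions and the patient DS."""

    timepoint: str  # "baseline" | "I-PET" | "EoT-PET"
    lesions: list[LesionObservation] = field(default_factory=list)
    liver_suv_max: float | None = None
    liver_suv_mean: float | None = None
    mediastinum_suv_max: float | None = None
    plasma_glucose: float | None = None  # mmol/L
    activity_fraction: float | None = None
    patient_ds: int | None = None
    qc: QcVerdict | None = None

    @property
    def involved_sites(self) -> set[Site]:
        return {obs.site for obs in self.lesions}


@dataclass
class PatientRecord:
    """A patient with MYC status, baseline covariates, scans and survival."""

    patient_id: str
    myc_status: str  # "negative" | "single-hit" | "double/triple-hit" | "myc+unknown"
    ipi: int | None = None
    ann_arbor_stage: int | None = None
    extranodal_count: int | None = None
    scans: dict[str, ScanAssessment] = field(default_factory=dict)
    os_time_days: float | None = None
    os_event: bool | None = None

    @property
    def myc_positive(self) -> bool:
        return self.myc_status != "negative"

    def scan(self, timepoint: str) -> ScanAssessment | None:
        return self.scans.get(timepoint)


class ResponsePattern(str, Enum):
    """Joint I-PET x EoT-PET response category."""

    INEG_ENEG = "Ineg/Eneg"
    INEG_EPOS = "Ineg/Epos"
    IPOS_ENEG = "Ipos/Eneg"
    IPOS_EPOS = "Ipos/Epos"
    MISSING_I = "missing-I"
    MISSING_E = "missing-E"


COMPLETE_PATTERNS = (
    ResponsePattern.INEG_ENEG,
    ResponsePattern.INEG_EPOS,
    ResponsePattern.IPOS_ENEG,
    ResponsePattern.IPOS_EPOS,
)


class UnresolvedDiscrepancyError(ValueError):
    """Two readers disagree and no adjudicator score is available."""


class UnclassifiablePatientError(ValueError):
    """Neither I-PET nor EoT-PET is available for pattern classification."""


# --------------------------------------------------------------------- DS
def assign_lesion_ds(
    lesion_suv_max: float | None,
    liver_reference: float,
    mediastinum_suv_max: float,
    *,
    is_new: bool = False,
) -> int:
    """Quantitative Deauville score for a single lesion.

    DS5 when the lesion SUVmax is at least 3x the hepatic reference or the
    lesion is new; DS4 above liver; DS3 above mediastinal blood pool; DS2 for
    residual uptake at or below mediastinum; DS1 when no residual uptake
    remains (``lesion_suv_max`` is None or 0). ``liver_reference`` is the
    hepatic SUVmax by default convention, but callers may pass the liver
    SUVmean instead (configuration switch upstream).
    """
    if liver_reference <= 0 or mediastinum_suv_max <= 0:
        raise ValueError(
            f"reference SUVs must be positive (liver={liver_reference}, "
            f"mediastinum={mediastinum_suv_max})"
        )
    if is_new:
        return 5
    if lesion_suv_max is None or lesion_suv_max == 0:
        return 1
    if lesion_suv_max < 0:
        raise ValueError(f"negative lesion SUVmax {lesion_suv_max}")
    if lesion_suv_max >= 3.0 * liver_reference:
        return 5
    if lesion_suv_max > liver_reference:
        return 4
    if lesion_suv_max > mediastinum_suv_max:
        return 3
    return 2


def patient_ds(scan: ScanAssessment, *, liver_reference: str = "suv_max") -> int:
    """Patient-level DS: worst (maximum) lesion DS; DS1 with no residual lesions."""
    if not scan.lesions:
        return 1
    if liver_reference == "suv_max":
        liver = scan.liver_suv_max
    elif liver_reference == "suv_mean":
        liver = scan.liver_suv_mean
    else:
        raise ValueError(f"liver_reference must be suv_max or suv_mean, got {liver_reference!r}")
    if liver is None or scan.mediastinum_suv_max is None:
        raise ValueError(f"scan {scan.timepoint} lacks reference SUVs for DS assignment")
    return max(
        assign_lesion_ds(
            obs.suv_max, liver, scan.mediastinum_suv_max, is_new=obs.is_new
        )
        for obs in scan.lesions
    )


def resolve_reviews(
    ds_reader1: int, ds_reader2: int, ds_adjudicator: int | None = None
) -> int:
    """Merge two independent reader scores; an adjudicator resolves discrepancies."""
    for ds in (ds_reader1, ds_reader2):
        if not 1 <= ds <= 5:
            raise ValueError(f"reader DS {ds} outside 1-5")
    if ds_reader1 == ds_reader2:
        return ds_reader1
    if ds_adjudicator is None:
        raise UnresolvedDiscrepancyError(
            f"readers disagree ({ds_reader1} vs {ds_reader2}) and no adjudicator score given"
        )
    if not 1 <= ds_adjudicator <= 5:
        raise ValueError(f"adjudicator DS {ds_adjudicator} outside 1-5")
    return ds_adjudicator


CUTOFFS = {
    "DS1-2 vs 3-5": 2,
    "DS1-3 vs 4-5": 3,  # main analysis cut-off
    "DS1-4 vs 5": 4,
}


def binarize_response(ds: int, cutoff: str = "DS1-3 vs 4-5") -> bool:
    """True (PET-positive) when the DS exceeds the cut-off boundary."""
    if not 1 <= ds <= 5:
        raise ValueError(f"DS {ds} outside 1-5")
    if cutoff not in CUTOFFS:
        raise ValueError(f"unknown cutoff {cutoff!r}; choose from {sorted(CUTOFFS)}")
    return ds > CUTOFFS[cutoff]


# --------------------------------------------------------------------- QC
@dataclass(frozen=True)
class QcRanges:
    """Scan-inclusion ranges.

    Defaults follow common EANM-style plausibility bounds: liver SUVmean in
    [1.3, 3.0] and plasma glucose at most 11 mmol/L; both configurable. A
    scan whose liver SUVmean is out of range is still usable when the total
    image activity lies between 50 and 80% of the injected activity.
    """

    liver_suv_mean_min: float = 1.3
    liver_suv_mean_max: float = 3.0
    glucose_max_mmol_l: float = 11.0
    activity_fraction_min: float = 0.50
    activity_fraction_max: float = 0.80


def qc_scan(
    liver_suv_mean: float,
    glucose: float,
    activity_fraction: float,
    ranges: QcRanges = QcRanges(),
) -> QcVerdict:
    """Scan quality verdict: pass, pass-by-activity, or fail."""
    if liver_suv_mean < 0 or glucose < 0 or activity_fraction < 0:
        raise ValueError("QC inputs must be non-negative")
    if glucose > ranges.glucose_max_mmol_l:
        return QcVerdict.FAIL
    if ranges.liver_suv_mean_min <= liver_suv_mean <= ranges.liver_suv_mean_max:
        return QcVerdict.PASS
    if ranges.activity_fraction_min <= activity_fraction <= ranges.activity_fraction_max:
        return QcVerdict.PASS_BY_ACTIVITY
    return QcVerdict.FAIL


# ------------------------------------------------------------ change flags
def suv_increase_cutoff(reference_suv_max: float) -> float:
    """Smallest detectable SUVmax change: 30% of the reference or 1.3 units,
    whichever is largest."""
    if reference_suv_max <= 0:
        raise ValueError(f"reference SUVmax must be positive, got {reference_suv_max}")
    return max(0.30 * reference_suv_max, 1.3)


def flag_suv_increase(reference_suv_max: float, new_suv_max: float) -> bool:
    """True when the SUVmax increase reaches the smallest detectable change.

    A change exactly equal to the cutoff counts as detected; comparison is
    tolerance-aware so decimal inputs sit on the intended side of the
    boundary.
    """
    diff = new_suv_max - reference_suv_max
    cutoff = suv_increase_cutoff(reference_suv_max)
    return diff >= cutoff or math.isclose(diff, cutoff, rel_tol=1e-9, abs_tol=1e-12)


def flag_mtv_increase(reference_mtv: float, new_mtv: float) -> bool:
    """True when MTV grows by at least 30% of the reference (boundary included)."""
    if reference_mtv <= 0:
        raise ValueError(f"reference MTV must be positive, got {reference_mtv}")
    bar = 1.30 * reference_mtv
    return new_mtv >= bar or math.isclose(new_mtv, bar, rel_tol=1e-9)


def detect_new_sites(
    current: ScanAssessment, reference: ScanAssessment
) -> set[Site]:
    """Sites involved on ``current`` but not on ``reference``.

    ``reference`` may be the baseline scan ("not initially involved") or the
    interim scan.
    """
    return current.involved_sites - reference.involved_sites


# ----------------------------------------------------------------- pattern
def classify_pattern(
    patient: PatientRecord, cutoff: str = "DS1-3 vs 4-5"
) -> ResponsePattern:
    """Six-way I-PET x EoT-PET response pattern for one patient.

    Missing scans (or scans without a recorded DS) map to the missing-I /
    missing-E categories; a patient with neither response is unclassifiable.
    """
    ipet = patient.scan("I-PET")
    eot = patient.scan("EoT-PET")
    i_ds = ipet.patient_ds if ipet is not None else None
    e_ds = eot.patient_ds if eot is not None else None
    if i_ds is None and e_ds is None:
        raise UnclassifiablePatientError(
            f"patient {patient.patient_id}: neither I-PET nor EoT-PET response available"
        )
    if i_ds is None:
        return ResponsePattern.MISSING_I
    if e_ds is None:
        return ResponsePattern.MISSING_E
    i_pos = binarize_response(i_ds, cutoff)
    e_pos = binarize_response(e_ds, cutoff)
    return {
        (False, False): ResponsePattern.INEG_ENEG,
        (False, True): ResponsePattern.INEG_EPOS,
        (True, False): ResponsePattern.IPOS_ENEG,
        (True, True): ResponsePattern.IPOS_EPOS,
    }[(i_pos, e_pos)]


def delta_suv_response(
    baseline_suv_max: float,
    interim_suv_max: float,
    reduction_threshold: float = 0.66,
) -> bool:
    """Percent-reduction interim response: True (positive) when the relative
    SUVmax reduction from baseline falls short of ``reduction_threshold``."""
    if baseline_suv_max <= 0:
        raise ValueError(f"baseline SUVmax must be positive, got {baseline_suv_max}")
    reduction = (baseline_suv_max - interim_suv_max) / baseline_suv_max
    return reduction < reduction_threshold
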