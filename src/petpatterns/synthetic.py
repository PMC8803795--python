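"""Synthetic phantoms and cohorts for exercising the full pipeline.

Two generators:

* :func:`generate_phantom` builds a 3-D SUV volume containing spherical
  lesions on a uniform background plus liver / mediastinum reference
  regions, together with exact ground-truth voxel masks — the substrate for
  validating the segmentation operators.
* :func:`generate_cohort` draws patient records whose response-pattern
  frequencies, lesion SUV/MTV trajectories, new-site events and 2-year
  overall survival match configurable targets. The defaults are calibrated
  to a published two-trial DLBCL cohort (81 MYC-rearranged and 129
  MYC-negative patients): pattern probabilities reproduce the observed
  interim x end-of-treatment response cross-classification, lesion-level
  increase probabilities the observed SUV/MTV change rates, and survival is
  exponential per (MYC status, EoT positivity) group calibrated to the
  observed 2-year OS.

Sphere discretization is by voxel-center inclusion; noise is independent
Gaussian truncated at zero. Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import (
    COMPLETE_PATTERNS,
    LesionObservation,
    PatientRecord,
    ResponsePattern,
    ScanAssessment,
    Site,
    flag_mtv_increase,
    flag_suv_increase,
    suv_increase_cutoff,
)
from .volume import SuvVolume

__all__ = [
    "SphereRegion",
    "PhantomConfig",
    "CohortConfig",
    "SyntheticPatient",
    "generate_phantom",
    "generate_cohort",
    "trajectory_from_pattern",
    "cohort_to_frame",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25

PATTERN_ORDER = (
    ResponsePattern.INEG_ENEG,
    ResponsePattern.INEG_EPOS,
    ResponsePattern.IPOS_ENEG,
    ResponsePattern.IPOS_EPOS,
    ResponsePattern.MISSING_E,
    ResponsePattern.MISSING_I,
)

COMPARISONS = ("baseline_vs_ipet", "ipet_vs_eot", "baseline_vs_eot")


# ------------------------------------------------------------------ phantom
@dataclass(frozen=True)
class SphereRegion:
    center_mm: tuple[float, float, float]
    radius_mm: float
    value: float  # peak SUV for lesions, target mean for reference regions


@dataclass
class PhantomConfig:
    """Configuration of a spherical-lesion SUV phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_suv: float = 1.0
    background_noise_sd: float = 0.0
    lesions: list[SphereRegion] = field(default_factory=list)
    liver_region: SphereRegion | None = None
    mediastinum_region: SphereRegion | None = None
    injected_activity_fraction: float = 0.65
    seed: int = 0

    def _named_regions(self) -> list[tuple[str, SphereRegion]]:
        regions = [(f"lesion_{i}", r) for i, r in enumerate(self.lesions)]
        if self.liver_region is not None:
            regions.append(("liver", self.liver_region))
        if self.mediastinum_region is not None:
            regions.append(("mediastinum", self.mediastinum_region))
        return regions

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(
            s <= 0 for s in self.voxel_spacing_mm
        ):
            raise ValueError("grid shape and spacing must be positive")
        if self.background_suv <= 0 or self.background_noise_sd < 0:
            raise ValueError("background SUV must be positive, noise sd non-negative")
        if not 0 < self.injected_activity_fraction <= 1.5:
            raise ValueError(
                f"injected_activity_fraction must be in (0, 1.5], got "
                f"{self.injected_activity_fraction}"
            )
        extent = [
            (n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)
        ]
        regions = self._named_regions()
        for name, r in regions:
            if r.radius_mm <= 0:
                raise ValueError(f"region {name}: radius must be positive")
            for c, e in zip(r.center_mm, extent):
                if c - r.radius_mm < 0 or c + r.radius_mm > e:
                    raise ValueError(f"region {name} extends outside the grid")
        for r in self.lesions:
            if r.value <= self.background_suv:
                raise ValueError("lesion peak SUV must exceed the background SUV")
        for i, (ni, ri) in enumerate(regions):
            for nj, rj in regions[i + 1 :]:
                gap = np.linalg.norm(
                    np.asarray(ri.center_mm) - np.asarray(rj.center_mm)
                )
                if gap <= ri.radius_mm + rj.radius_mm:
                    raise ValueError(f"regions {ni} and {nj} overlap")


def _sphere_mask(
    grid_shape, spacing_mm, center_mm, radius_mm: float
) -> np.ndarray:
    """Voxels whose centers lie within the sphere (boundary inclusive)."""
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (
        (xx - center_mm[0]) ** 2
        + (yy - center_mm[1]) ** 2
        + (zz - center_mm[2]) ** 2
    )
    return d2 <= radius_mm**2 + 1e-9


def generate_phantom(config: PhantomConfig):
    """Build the phantom volume.

    Returns ``(volume, masks, summaries)`` where ``masks`` maps region names
    (``lesion_i``, ``liver``, ``mediastinum``) to exact boolean ground-truth
    grids and ``summaries`` carries the scan-level quantities used by QC and
    scoring (liver SUVmean/SUVmax, mediastinal SUVmax, activity bookkeeping).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    values = np.full(config.grid_shape, config.background_suv, dtype=float)
    masks: dict[str, np.ndarray] = {}
    for name, region in config._named_regions():
        m = _sphere_mask(
            config.grid_shape, config.voxel_spacing_mm, region.center_mm, region.radius_mm
        )
        values[m] = region.value
        masks[name] = m
    if config.background_noise_sd > 0:
        values = np.clip(
            values + rng.normal(0.0, config.background_noise_sd, size=values.shape),
            0.0,
            None,
        )
    volume = SuvVolume(values, config.voxel_spacing_mm)

    summaries: dict[str, float] = {
        "activity_fraction": config.injected_activity_fraction,
        "total_image_activity": float(values.sum() * volume.voxel_volume_ml),
    }
    for ref in ("liver", "mediastinum"):
        if ref in masks:
            summaries[f"{ref}_suv_mean"] = float(values[masks[ref]].mean())
            summaries[f"{ref}_suv_max"] = float(values[masks[ref]].max())
    return volume, masks, summaries


# ------------------------------------------------------------------- cohort
def _default_pattern_probs() -> dict[str, np.ndarray]:
    # observed scan-pattern counts over (Ineg/Eneg, Ineg/Epos, Ipos/Eneg,
    # Ipos/Epos, missing-EoT, missing-I) per MYC group
    return {
        "positive": np.array([43, 13, 10, 13, 1, 1], dtype=float) / 81.0,
        "negative": np.array([89, 2, 11, 16, 8, 3], dtype=float) / 129.0,
    }


def _default_os2y() -> dict[tuple[str, str], float]:
    # 2-year OS by (MYC group, EoT positivity)
    return {
        ("positive", "eot_negative"): 0.925,
        ("positive", "eot_positive"): 0.378,
        ("negative", "eot_negative"): 0.941,
        ("negative", "eot_positive"): 0.667,
    }


def _default_increase_probs() -> dict[tuple[str, str, str], float]:
    # P(lesional increase) per (MYC group, measure, comparison); the
    # baseline-vs-interim rows condition on I-PET-positive patients, the
    # EoT rows on EoT-positive patients
    return {
        ("positive", "mtv", "baseline_vs_ipet"): 2 / 23,
        ("positive", "mtv", "ipet_vs_eot"): 21 / 26,
        ("positive", "mtv", "baseline_vs_eot"): 9 / 26,
        ("positive", "suv", "baseline_vs_ipet"): 4 / 23,
        ("positive", "suv", "ipet_vs_eot"): 21 / 26,
        ("positive", "suv", "baseline_vs_eot"): 11 / 26,
        ("negative", "mtv", "baseline_vs_ipet"): 0 / 30,
        ("negative", "mtv", "ipet_vs_eot"): 8 / 19,
        ("negative", "mtv", "baseline_vs_eot"): 1 / 19,
        ("negative", "suv", "baseline_vs_ipet"): 1 / 30,
        ("negative", "suv", "ipet_vs_eot"): 6 / 19,
        ("negative", "suv", "baseline_vs_eot"): 2 / 19,
    }


@dataclass
class CohortConfig:
    """Configuration of a synthetic patient cohort.

    Defaults reproduce the observed frequencies of the reference DLBCL
    cohort: MYC-positive fraction 81/210, the six scan-pattern probabilities
    per MYC group, lesional SUV/MTV increase probabilities, new-site
    probabilities among EoT-positive patients (9/26 MYC+, 1/19 MYC-), and
    group-wise 2-year OS.
    """

    n_patients: int = 210
    myc_positive_fraction: float = 81 / 210
    pattern_probs: dict[str, np.ndarray] = field(default_factory=_default_pattern_probs)
    os2y_by_group: dict[tuple[str, str], float] = field(default_factory=_default_os2y)
    lesion_increase_probs: dict[tuple[str, str, str], float] = field(
        default_factory=_default_increase_probs
    )
    new_site_prob: dict[str, float] = field(
        default_factory=lambda: {"positive": 9 / 26, "negative": 1 / 19}
    )
    missing_i_eot_pos_prob: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.0, "negative": 1 / 3}
    )
    follow_up_horizon_years: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if not 0 <= self.myc_positive_fraction <= 1:
            raise ValueError("myc_positive_fraction must be a probability")
        for group, probs in self.pattern_probs.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (6,):
                raise ValueError(
                    f"pattern_probs[{group!r}] must have 6 entries, got {probs.shape}"
                )
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"pattern_probs[{group!r}] outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"pattern_probs[{group!r}] sums to {probs.sum():.12g}, not 1"
                )
        for mapping in (self.os2y_by_group, self.lesion_increase_probs,
                        self.new_site_prob, self.missing_i_eot_pos_prob):
            for key, p in mapping.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability for {key} outside [0, 1]: {p}")


@dataclass
class SyntheticPatient:
    """A generated patient plus the ground truth it was drawn from."""

    record: PatientRecord
    pattern: ResponsePattern
    increase_flags: dict[tuple[str, str], bool]
    new_site: bool
    trajectory: dict[str, tuple[float, float]]  # timepoint -> (SUVmax, MTV)


def _suv_delta(ref: float) -> float:
    return suv_increase_cutoff(ref)


def _mtv_delta(ref: float) -> float:
    return 0.30 * ref


def _solve_triplet(base: float, f_bi: bool, f_ie: bool, f_be: bool, delta, rng):
    """Emit (baseline, interim, eot) values whose pairwise increase flags,
    under the smallest-detectable-change rule ``new - ref >= delta(ref)``,
    equal the requested flags. (True, True, False) is arithmetically
    infeasible and rejected."""
    b = base
    u = rng.uniform

    def inc(ref):
        return ref + delta(ref) * u(1.0, 1.5)

    if f_bi and f_ie and not f_be:
        raise ValueError(
            "infeasible flags: increases baseline->interim and interim->EoT "
            "entail an increase baseline->EoT"
        )
    if not f_bi:
        if f_ie and not f_be:
            i = 0.3 * b  # low enough that i + delta(i) < b + delta(b)
        elif not f_ie and f_be:
            i = b + 0.9 * delta(b)  # high enough that b + delta(b) < i + delta(i)
        else:
            i = b * u(0.3, 0.9)
    else:
        i = inc(b)

    if f_ie and f_be:
        e = max(inc(i), b + delta(b) * u(1.0, 1.5))
    elif f_ie and not f_be:
        lo, hi = i + delta(i), b + delta(b)
        e = lo + u(0.0, 0.9) * (hi - lo)
    elif not f_ie and f_be:
        lo, hi = b + delta(b), i + delta(i)
        e = lo + u(0.0, 0.9) * (hi - lo)
    else:
        e = min(i, b) * u(0.3, 0.9)
    return b, i, e


def trajectory_from_pattern(
    pattern: ResponsePattern,
    increase_flags: dict[tuple[str, str], bool],
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Per-timepoint (SUVmax, MTV) for the index lesion, consistent with the
    requested increase flags.

    ``increase_flags`` maps ``(measure, comparison)`` — measure in
    {"suv", "mtv"}, comparison in {"baseline_vs_ipet", "ipet_vs_eot",
    "baseline_vs_eot"} — to booleans; omitted keys default to False.
    Re-applying the smallest-detectable-change rules to the emitted values
    reproduces the flags exactly.
    """
    if pattern not in COMPLETE_PATTERNS:
        raise ValueError(f"trajectory requires a complete pattern, got {pattern}")
    flags = {
        (m, c): bool(increase_flags.get((m, c), False))
        for m in ("suv", "mtv")
        for c in COMPARISONS
    }
    suv_b, suv_i, suv_e = _solve_triplet(
        rng.uniform(8.0, 20.0),
        flags[("suv", "baseline_vs_ipet")],
        flags[("suv", "ipet_vs_eot")],
        flags[("suv", "baseline_vs_eot")],
        _suv_delta,
        rng,
    )
    mtv_b, mtv_i, mtv_e = _solve_triplet(
        rng.uniform(50.0, 300.0),
        flags[("mtv", "baseline_vs_ipet")],
        flags[("mtv", "ipet_vs_eot")],
        flags[("mtv", "baseline_vs_eot")],
        _mtv_delta,
        rng,
    )
    return {
        "baseline": (suv_b, mtv_b),
        "I-PET": (suv_i, mtv_i),
        "EoT-PET": (suv_e, mtv_e),
    }


_BASELINE_SITES = (
    Site("cervical"),
    Site("mediastinum"),
    Site("axillary"),
    Site("gastrointestinal"),
)
_NEW_SITES = (Site("iliac"), Site("skeletal"), Site("central_nervous_system"))

# reference SUVs shared by all synthetic scans: liver SUVmax 3.0 puts the
# DS4 band at (3, 9) and DS5 at >= 9
_LIVER_MAX, _LIVER_MEAN, _MEDIASTINUM = 3.0, 2.2, 1.5


def _make_scan(
    timepoint: str,
    positive: bool | None,
    suv: float,
    mtv: float,
    *,
    new_site: bool = False,
    baseline_sites=_BASELINE_SITES[:2],
    rng: np.random.Generator,
) -> ScanAssessment:
    """One synthetic scan; ``positive=None`` means baseline (always involved)."""
    lesions: list[LesionObservation] = []
    if positive is None or positive:
        suv_val = suv if positive is None else max(suv, 3.1)  # DS >= 4 when positive
        for site in baseline_sites:
            lesions.append(
                LesionObservation(site=site, suv_max=suv_val, mtv_ml=mtv, method="MV2")
            )
        if new_site:
            lesions.append(
                LesionObservation(
                    site=_NEW_SITES[int(rng.integers(len(_NEW_SITES)))],
                    suv_max=suv_val,
                    mtv_ml=mtv / 4.0,
                    method="MV2",
                    is_new=True,
                )
            )
    elif rng.random() < 0.5:
        # negative scan with faint residual uptake (DS2) at one site
        lesions.append(
            LesionObservation(
                site=baseline_sites[0], suv_max=float(rng.uniform(0.5, _MEDIASTINUM)),
                mtv_ml=mtv, method="MV2",
            )
        )
    scan = ScanAssessment(
        timepoint=timepoint,
        lesions=lesions,
        liver_suv_max=_LIVER_MAX,
        liver_suv_mean=_LIVER_MEAN,
        mediastinum_suv_max=_MEDIASTINUM,
        plasma_glucose=float(rng.uniform(4.0, 7.0)),
        activity_fraction=0.65,
    )
    from .scoring import patient_ds as _pds

    scan.patient_ds = _pds(scan)
    return scan


_IPI_PROBS = {"positive": np.array([9, 18, 35, 19]) / 81,
              "negative": np.array([27, 29, 40, 33]) / 129}
_STAGE_PROBS = {"positive": np.array([7, 11, 63]) / 81,
                "negative": np.array([20, 35, 74]) / 129}
_EXTRANODAL_PROBS = {"positive": np.array([32, 49]) / 81,
                     "negative": np.array([79, 50]) / 129}
_MYC_SUBTYPE = (("single-hit", 22 / 81), ("double/triple-hit", 52 / 81),
                ("myc+unknown", 7 / 81))


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Draw a cohort of synthetic patients, independently per patient.

    For each patient: MYC group, then the six-way scan pattern, then (for
    PET-positive scans) lesion-trajectory increase flags and new-site
    events, then survival time — exponential with the rate solving
    S(2 years) = configured 2-year OS for the patient's (MYC, EoT) group,
    administratively censored at the follow-up horizon. Patients with a
    missing EoT scan use the EoT-negative group's survival.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients: list[SyntheticPatient] = []
    horizon_days = config.follow_up_horizon_years * DAYS_PER_YEAR

    for idx in range(config.n_patients):
        group = "positive" if rng.random() < config.myc_positive_fraction else "negative"
        if group == "positive":
            r = rng.random()
            acc = 0.0
            myc_status = _MYC_SUBTYPE[-1][0]
            for name, p in _MYC_SUBTYPE:
                acc += p
                if r < acc:
                    myc_status = name
                    break
        else:
            myc_status = "negative"

        pattern = PATTERN_ORDER[
            int(rng.choice(6, p=np.asarray(config.pattern_probs[group], dtype=float)))
        ]

        # response availability/positivity implied by the pattern
        i_pos: bool | None
        e_pos: bool | None
        if pattern is ResponsePattern.MISSING_I:
            i_pos = None
            e_pos = rng.random() < config.missing_i_eot_pos_prob[group]
        elif pattern is ResponsePattern.MISSING_E:
            # I-PET status among missing-EoT patients: proportional to the
            # group's marginal I-PET positivity over complete patterns
            probs = np.asarray(config.pattern_probs[group], dtype=float)
            complete = probs[:4].sum()
            i_pos = rng.random() < (probs[2] + probs[3]) / complete if complete > 0 else False
            e_pos = None
        else:
            i_pos = pattern in (ResponsePattern.IPOS_ENEG, ResponsePattern.IPOS_EPOS)
            e_pos = pattern in (ResponsePattern.INEG_EPOS, ResponsePattern.IPOS_EPOS)

        # increase flags: baseline->I drawn for I-PET-positive patients,
        # EoT comparisons for EoT-positive patients
        flags: dict[tuple[str, str], bool] = {}
        for measure in ("suv", "mtv"):
            f_bi = bool(
                i_pos
                and rng.random()
                < config.lesion_increase_probs[(group, measure, "baseline_vs_ipet")]
            )
            f_ie = f_be = False
            if e_pos:
                f_ie = rng.random() < config.lesion_increase_probs[
                    (group, measure, "ipet_vs_eot")
                ]
                if f_bi and f_ie:
                    f_be = True  # entailed by the cutoff arithmetic
                else:
                    f_be = rng.random() < config.lesion_increase_probs[
                        (group, measure, "baseline_vs_eot")
                    ]
            flags[(measure, "baseline_vs_ipet")] = f_bi
            flags[(measure, "ipet_vs_eot")] = f_ie
            flags[(measure, "baseline_vs_eot")] = f_be

        proxy = {
            (False, False): ResponsePattern.INEG_ENEG,
            (False, True): ResponsePattern.INEG_EPOS,
            (True, False): ResponsePattern.IPOS_ENEG,
            (True, True): ResponsePattern.IPOS_EPOS,
        }[(bool(i_pos), bool(e_pos))]
        trajectory = trajectory_from_pattern(proxy, flags, rng)

        new_site = bool(e_pos and rng.random() < config.new_site_prob[group])

        scans: dict[str, ScanAssessment] = {
            "baseline": _make_scan(
                "baseline", None, *trajectory["baseline"], rng=rng
            )
        }
        if pattern is not ResponsePattern.MISSING_I:
            scans["I-PET"] = _make_scan(
                "I-PET", bool(i_pos), *trajectory["I-PET"], rng=rng
            )
        if pattern is not ResponsePattern.MISSING_E:
            scans["EoT-PET"] = _make_scan(
                "EoT-PET", bool(e_pos), *trajectory["EoT-PET"],
                new_site=new_site, rng=rng,
            )

        os_key = (group, "eot_positive" if e_pos else "eot_negative")
        s2 = config.os2y_by_group[os_key]
        if s2 >= 1.0:
            t_death = np.inf
        else:
            rate = -np.log(s2) / 2.0  # per year
            t_death = rng.exponential(1.0 / rate) * DAYS_PER_YEAR
        os_time = min(t_death, horizon_days)
        os_event = t_death <= horizon_days

        record = PatientRecord(
            patient_id=f"SYN{idx:05d}",
            myc_status=myc_status,
            ipi=int(rng.choice(4, p=_IPI_PROBS[group])) + 1,
            ann_arbor_stage=int(rng.choice(3, p=_STAGE_PROBS[group])) + 2,
            extranodal_count=int(rng.choice(2, p=_EXTRANODAL_PROBS[group])),
            scans=scans,
            os_time_days=float(os_time),
            os_event=bool(os_event),
        )
        patients.append(
            SyntheticPatient(
                record=record,
                pattern=pattern,
                increase_flags=flags,
                new_site=new_site,
                trajectory=trajectory,
            )
        )
    return patients


def cohort_to_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Flatten a synthetic cohort to one row per patient (the CSV layout)."""
    rows = []
    for p in patients:
        rec = p.record
        row = {
            "patient_id": rec.patient_id,
            "myc_status": rec.myc_status,
            "myc_group": "positive" if rec.myc_positive else "negative",
            "ipi": rec.ipi,
            "ann_arbor_stage": rec.ann_arbor_stage,
            "extranodal_count": rec.extranodal_count,
            "pattern": p.pattern.value,
            "ipet_ds": rec.scans["I-PET"].patient_ds if "I-PET" in rec.scans else "",
            "eot_ds": rec.scans["EoT-PET"].patient_ds if "EoT-PET" in rec.scans else "",
            "new_site": p.new_site,
            "os_time_days": round(rec.os_time_days, 3),
            "os_event": rec.os_event,
        }
        for tp, short in (("baseline", "baseline"), ("I-PET", "ipet"), ("EoT-PET", "eot")):
            suv, mtv = p.trajectory[tp]
            row[f"suv_{short}"] = round(suv, 4)
            row[f"mtv_{short}"] = round(mtv, 4)
        for (measure, comp), val in sorted(p.increase_flags.items()):
            row[f"flag_{measure}_{comp}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def verify_trajectory_flags(p: SyntheticPatient) -> dict[tuple[str, str], bool]:
    """Recompute the increase flags from a patient's emitted trajectory."""
    suv = {tp: p.trajectory[tp][0] for tp in p.trajectory}
    mtv = {tp: p.trajectory[tp][1] for tp in p.trajectory}
    pairs = {
        "baseline_vs_ipet": ("baseline", "I-PET"),
        "ipet_vs_eot": ("I-PET", "EoT-PET"),
        "baseline_vs_eot": ("baseline", "EoT-PET"),
    }
    out: dict[tuple[str, str], bool] = {}
    for comp, (a, b) in pairs.items():
        out[("suv", comp)] = flag_suv_increase(suv[a], suv[b])
        out[("mtv", comp)] = flag_mtv_increase(mtv[a], mtv[b])
    return out
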