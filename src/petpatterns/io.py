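"""Delimited-text cohort I/O.

The cohort table has one row per patient; the column dictionary is:

=====================  =====================================================
column                 meaning
=====================  =====================================================
patient_id             unique identifier
myc_status             negative | single-hit | double/triple-hit | myc+unknown
myc_group              positive | negative (derived from myc_status)
ipi                    International Prognostic Index category (1-4)
ann_arbor_stage        Ann Arbor stage (2-4)
extranodal_count       0 (at most one extranodal site) or 1 (more than one)
ipet_ds / eot_ds       patient-level Deauville score (blank = scan missing)
pattern                six-way I-PET x EoT-PET response pattern
new_site               EoT lesion at a site not involved at baseline
suv_* / mtv_*          index-lesion SUVmax / MTV (mL) per timepoint
flag_*                 smallest-detectable-change increase flags
os_time_days           follow-up time from registration, days
os_event               True when the patient died at os_time_days
=====================  =====================================================
"""

from __future__ import annotations

import math

import pandas as pd

from .scoring import PatientRecord, ScanAssessment

__all__ = ["records_from_frame", "read_cohort_csv"]


def _missing(v) -> bool:
    if v is None or v == "":
        return True
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild minimal patient records from a cohort table.

    Only the columns the statistics need are reconstructed: MYC status,
    matching covariates, the per-timepoint Deauville scores (as scans with a
    ``patient_ds``), and survival.
    """
    records = []
    for _, row in df.iterrows():
        scans: dict[str, ScanAssessment] = {}
        for col, tp in (("ipet_ds", "I-PET"), ("eot_ds", "EoT-PET")):
            if col in row and not _missing(row[col]):
                scans[tp] = ScanAssessment(timepoint=tp, patient_ds=int(float(row[col])))
        if "myc_status" in row and not _missing(row["myc_status"]):
            myc = str(row["myc_status"])
        elif str(row.get("myc_group", "")) == "positive":
            myc = "myc+unknown"
        else:
            myc = "negative"

        def opt(col, cast):
            return cast(row[col]) if col in row and not _missing(row[col]) else None

        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                myc_status=myc,
                ipi=opt("ipi", int),
                ann_arbor_stage=opt("ann_arbor_stage", int),
                extranodal_count=opt("extranodal_count", int),
                scans=scans,
                os_time_days=opt("os_time_days", float),
                os_event=opt("os_event", lambda v: str(v).lower() in ("true", "1", "1.0")),
            )
        )
    return records


def read_cohort_csv(path: str) -> list[PatientRecord]:
    return records_from_frame(pd.read_csv(path))
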