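"""Packaged reference tallies from a multicenter DLBCL PET response study.

Three small tables ship with the package so the cohort statistics can be
exercised (and the published rates reproduced) without any imaging data:

* ``response_patterns.csv`` — patient counts cross-classified by MYC group
  and interim x end-of-treatment PET status (including a risk-matched
  MYC-negative subset);
* ``new_sites.csv`` — the patients whose end-of-treatment scan showed
  PET-positive localizations not involved at baseline, with the free-text
  localizations;
* ``lesion_changes.csv`` — counts of PET-positive patients with / without a
  lesional SUVmax or MTV increase for each timepoint comparison.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .scoring import PatientRecord, ScanAssessment, site_from_text

__all__ = [
    "load_response_patterns",
    "load_new_sites",
    "load_lesion_changes",
    "expand_response_patterns",
]

_NEGATIVE_DS, _POSITIVE_DS = 2, 4  # representative DS on either side of the cut-off


def _read(name: str) -> pd.DataFrame:
    with resources.files("petpatterns.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_response_patterns() -> pd.DataFrame:
    """Patient counts by (myc_group, ipet_status, eot_status)."""
    return _read("response_patterns.csv")


def load_new_sites() -> pd.DataFrame:
    """New-localization patients; ``localizations`` is semicolon-separated."""
    df = _read("new_sites.csv")
    df["sites"] = df["localizations"].map(
        lambda s: [site_from_text(t) for t in s.split(";")]
    )
    return df


def load_lesion_changes() -> pd.DataFrame:
    """Increase / no-increase counts per (myc_group, measure, comparison)."""
    return _read("lesion_changes.csv")


def expand_response_patterns(
    groups: tuple[str, ...] = ("positive", "negative"),
) -> list[PatientRecord]:
    """Expand the response-pattern tallies into individual patient records.

    Each counted patient becomes a :class:`PatientRecord` whose scans carry a
    representative Deauville score on the right side of the main cut-off
    (DS2 for negative, DS4 for positive); missing scans are absent. This
    lets the scoring and statistics operators run on the fixture exactly as
    they would on a real cohort table.
    """
    table = load_response_patterns()
    patients: list[PatientRecord] = []
    serial = 0
    for _, row in table.iterrows():
        if row["myc_group"] not in groups:
            continue
        for _ in range(int(row["count"])):
            scans: dict[str, ScanAssessment] = {}
            for timepoint, status in (
                ("I-PET", row["ipet_status"]),
                ("EoT-PET", row["eot_status"]),
            ):
                if status == "missing":
                    continue
                scans[timepoint] = ScanAssessment(
                    timepoint=timepoint,
                    patient_ds=_POSITIVE_DS if status == "positive" else _NEGATIVE_DS,
                )
            myc = "negative" if "negative" in row["myc_group"] else "double/triple-hit"
            patients.append(
                PatientRecord(patient_id=f"FIX{serial:04d}", myc_status=myc, scans=scans)
            )
            serial += 1
    return patients
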