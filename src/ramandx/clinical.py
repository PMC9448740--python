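"""Clinical covariates and the derived risk groupings.

Three target groupings drive the classification tasks:

* **Gleason group** — histological grade, the sum of primary and secondary
  growth patterns (3+3=6 through 4+4=8 in this cohort configuration).
* **CAPRA group** — the UCSF 0–10 point risk score built from age, PSA,
  Gleason patterns, clinical T stage and percent positive biopsy cores,
  banded low (0–2), medium (3–5), high (6–10).
* **Ki67 group** — percent Ki67-positive tumour cells in the post-treatment
  biopsy, dichotomized at 3.5 %.

A per-patient PSA median split is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

T_STAGES = ("T1", "T2", "T3a")


@dataclass
class ClinicalRecord:
    """Per-biopsy clinical covariates."""

    biopsy_id: str
    patient_id: str
    timepoint: str                 # "pre" or "post"
    age_years: int
    psa_ng_ml: float
    gleason_primary: int
    gleason_secondary: int
    t_stage: str
    pct_positive_cores: float
    pct_pattern4: float
    ki67_pct: float | None = None

    def __post_init__(self) -> None:
        if self.gleason_primary not in (3, 4, 5) or self.gleason_secondary not in (3, 4, 5):
            raise ValidationError(
                f"{self.biopsy_id}: Gleason patterns must be in {{3,4,5}}, got "
                f"{self.gleason_primary}+{self.gleason_secondary}"
            )
        if self.t_stage not in T_STAGES:
            raise ValidationError(
                f"{self.biopsy_id}: t_stage must be one of {T_STAGES}, got {self.t_stage!r}"
            )
        for name in ("pct_positive_cores", "pct_pattern4"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{self.biopsy_id}: {name}={v} outside [0, 100]")
        if self.psa_ng_ml < 0:
            raise ValidationError(f"{self.biopsy_id}: negative PSA")
        if self.ki67_pct is not None and self.ki67_pct < 0:
            raise ValidationError(f"{self.biopsy_id}: negative Ki67 percentage")

    @property
    def gleason_total(self) -> int:
        return self.gleason_primary + self.gleason_secondary


@dataclass
class ClinicalTable:
    """Collection of per-biopsy records with unique biopsy ids."""

    records: list[ClinicalRecord]

    def __post_init__(self) -> None:
        ids = [r.biopsy_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate biopsy ids: {dupes}")

    def by_biopsy(self, biopsy_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.biopsy_id == biopsy_id:
                return r
        raise ValidationError(f"no clinical record for biopsy {biopsy_id!r}")

    def check_covers(self, biopsy_ids) -> None:
        have = {r.biopsy_id for r in self.records}
        missing = sorted(set(biopsy_ids) - have)
        if missing:
            raise ValidationError(f"biopsies without clinical records: {missing}")


def gleason_label(r: ClinicalRecord, max_total: int = 8) -> str:
    """Gleason group label GS6/GS7/GS8 from the pattern sum.

    Totals above ``max_total`` are rejected by default because the cohort
    configuration spans scores 6–8; raise the cap for broader cohorts.
    """
    total = r.gleason_total
    if not 6 <= total <= max_total:
        raise ValidationError(
            f"{r.biopsy_id}: Gleason total {total} outside the configured range "
            f"[6, {max_total}]"
        )
    return f"GS{total}"


def capra_points(r: ClinicalRecord) -> int:
    """UCSF CAPRA points (0–10) from the five standard covariates.

    Point schedule: age <50 → 0, ≥50 → 1; PSA ≤6 → 0, 6.01–10 → 1,
    10.01–20 → 2, 20.01–30 → 3, >30 → 4; Gleason: no pattern 4/5 → 0,
    secondary 4/5 → 1, primary 4/5 → 3; stage T1/T2 → 0, T3a → 1;
    percent positive cores <34 → 0, ≥34 → 1.
    """
    missing = [
        name
        for name, v in (
            ("age_years", r.age_years),
            ("psa_ng_ml", r.psa_ng_ml),
            ("t_stage", r.t_stage),
            ("pct_positive_cores", r.pct_positive_cores),
        )
        if v is None
    ]
    if missing:
        raise ValidationError(f"{r.biopsy_id}: missing CAPRA covariates: {missing}")

    pts = 0 if r.age_years < 50 else 1

    psa = r.psa_ng_ml
    if psa <= 6:
        pts += 0
    elif psa <= 10:
        pts += 1
    elif psa <= 20:
        pts += 2
    elif psa <= 30:
        pts += 3
    else:
        pts += 4

    if r.gleason_primary >= 4:
        pts += 3
    elif r.gleason_secondary >= 4:
        pts += 1

    if r.t_stage == "T3a":
        pts += 1

    if r.pct_positive_cores >= 34:
        pts += 1
    return pts


def capra_group(points: int) -> str:
    """Band CAPRA points: 0–2 Low, 3–5 Medium, 6–10 High."""
    if not 0 <= points <= 10:
        raise ValidationError(f"CAPRA points {points} outside [0, 10]")
    if points <= 2:
        return "Low"
    if points <= 5:
        return "Medium"
    return "High"


def ki67_group(ki67_pct: float | None, threshold: float = 3.5) -> str:
    """Dichotomize the Ki67 proliferation index at ``threshold`` percent.

    The defining intervals are open at the threshold (<3.5 % low, >3.5 %
    high); a value exactly at the threshold is assigned Low with a warning so
    the convention is visible.
    """
    if ki67_pct is None:
        raise ValidationError("ki67_pct is missing")
    if ki67_pct == threshold:
        logger.warning(
            "Ki67 value exactly at the %.2f%% threshold assigned to the Low group",
            threshold,
        )
        return "Low"
    return "High" if ki67_pct > threshold else "Low"


def psa_median_split(
    records: list[ClinicalRecord], one_per_patient: bool = True
) -> tuple[float, dict[str, str]]:
    """Median split of baseline PSA; returns (median, per-patient labels).

    With ``one_per_patient`` the earliest-listed biopsy of each patient
    supplies that patient's baseline PSA.  Labels are ``belowMedian`` /
    ``aboveMedian`` (values exactly at the median count as below).
    """
    if not records:
        raise ValidationError("no clinical records")
    values: dict[str, float] = {}
    for r in records:
        if one_per_patient and r.patient_id in values:
            continue
        values[r.patient_id] = r.psa_ng_ml
    if not values:
        raise ValidationError("no PSA values")
    median = float(np.median(list(values.values())))
    labels = {
        pid: ("aboveMedian" if v > median else "belowMedian")
        for pid, v in values.items()
    }
    return median, labels


def derive_labels(table: ClinicalTable) -> dict[str, dict[str, str]]:
    """All per-biopsy task labels: gleason, capra, ki67, psa_median."""
    median, psa_labels = psa_median_split(table.records)
    out: dict[str, dict[str, str]] = {}
    for r in table.records:
        out[r.biopsy_id] = {
            "gleason": gleason_label(r),
            "capra": capra_group(capra_points(r)),
            "ki67": ki67_group(r.ki67_pct) if r.ki67_pct is not None else "NA",
            "psa_median": psa_labels[r.patient_id],
        }
    return out
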