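"""EHR-derived phenotype features: lab-median flags, CK+statin events,
medication exclusions.

EHR inputs arrive as four delimited tables (demographics, diagnoses, labs,
meds); diagnosis flags are consumed as precomputed booleans — no ICD/CPT
parsing or note NLP here.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .config import CohortConfig, DEFAULT_LAB_THRESHOLDS, LAB_ASSAYS

SEXES = ("female", "male")
RACES = (
    "american_indian_alaska_native",
    "asian",
    "black_african_american",
    "native_hawaiian_pacific_islander",
    "unknown",
    "white",
)
HISPANIC = ("yes", "no", "unknown")
DX_FLAGS = (
    "malignant_hyperthermia",
    "lqts",
    "atrial_fibrillation",
    "arrhythmia",
    "chf",
    "hypertension",
)
MED_KINDS = ("dispensing", "current_regimen")


@dataclass(frozen=True)
class LabMeasurement:
    assay: str  # LDL | TG | CK | TSH | INR
    value: float  # LDL/TG mg/dL, CK IU/L, TSH ug/dL, INR ratio
    date: dt.date


@dataclass(frozen=True)
class MedicationRecord:
    drug: str
    date: dt.date
    kind: str = "dispensing"  # dispensing | current_regimen


@dataclass
class ParticipantEHR:
    participant_id: str
    sex: str
    race: str
    hispanic: str = "no"
    dx: frozenset[str] = frozenset()
    labs: list[LabMeasurement] = field(default_factory=list)
    meds: list[MedicationRecord] = field(default_factory=list)
    age: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.race not in RACES:
            raise ValueError(f"race must be one of {RACES}, got {self.race!r}")
        if self.hispanic not in HISPANIC:
            raise ValueError(f"hispanic must be one of {HISPANIC}, got {self.hispanic!r}")
        bad_dx = set(self.dx) - set(DX_FLAGS)
        if bad_dx:
            raise ValueError(f"unknown diagnosis flags: {sorted(bad_dx)}")
        self.dx = frozenset(self.dx)
        for lab in self.labs:
            if lab.value <= 0:
                raise ValueError(
                    f"lab value must be > 0: {lab.assay}={lab.value} "
                    f"for {self.participant_id}"
                )
        for med in self.meds:
            if med.kind not in MED_KINDS:
                raise ValueError(f"medication kind must be one of {MED_KINDS}")


@dataclass(frozen=True)
class LabFlags:
    """The five per-assay flags (median strictly above threshold) and sum."""

    ldl_flag: int = 0
    tg_flag: int = 0
    ck_flag: int = 0
    tsh_flag: int = 0
    inr_flag: int = 0

    @property
    def flag_sum(self) -> int:
        return self.ldl_flag + self.tg_flag + self.ck_flag + self.tsh_flag + self.inr_flag

    def as_dict(self) -> dict[str, int]:
        return {
            "LDL": self.ldl_flag,
            "TG": self.tg_flag,
            "CK": self.ck_flag,
            "TSH": self.tsh_flag,
            "INR": self.inr_flag,
        }


def median_lab(values: Sequence[float]) -> float | None:
    """Median of repeated measures; even counts take the midpoint of the
    two central order statistics. Empty input is a distinguished "no data"
    result (None), which downstream leaves the flag at 0."""
    if not values:
        return None
    return float(median(values))


def compute_lab_flags(
    p: ParticipantEHR, thresholds: dict[str, float] | None = None
) -> LabFlags:
    """Flag each assay whose median of repeated measures strictly exceeds
    its threshold; a median exactly at the threshold does not flag, and an
    assay with no measurements contributes 0."""
    thresholds = thresholds if thresholds is not None else DEFAULT_LAB_THRESHOLDS
    by_assay: dict[str, list[float]] = {a: [] for a in LAB_ASSAYS}
    for lab in p.labs:
        if lab.assay not in by_assay:
            raise ValueError(
                f"unknown lab assay {lab.assay!r} for {p.participant_id}; "
                f"known assays: {LAB_ASSAYS}"
            )
        by_assay[lab.assay].append(lab.value)

    flags = {}
    for assay in LAB_ASSAYS:
        med = median_lab(by_assay[assay])
        flags[assay] = int(med is not None and med > thresholds[assay])
    return LabFlags(
        ldl_flag=flags["LDL"],
        tg_flag=flags["TG"],
        ck_flag=flags["CK"],
        tsh_flag=flags["TSH"],
        inr_flag=flags["INR"],
    )


def _is_statin(drug: str, statin_drugs: Iterable[str]) -> bool:
    return drug.lower() in set(statin_drugs)


def ck_statin_rule(
    p: ParticipantEHR,
    ck_threshold: float = 1000.0,
    window_days: int = 183,
    statin_drugs: Iterable[str] | None = None,
) -> bool:
    """Possible statin myopathy: any single CK event above ``ck_threshold``
    (IU/L) with a statin dispensing within ``window_days`` of it.

    The window is symmetric around the CK event (6 months ~ 183 days by
    default); directionality is not assumed.
    """
    if statin_drugs is None:
        statin_drugs = CohortConfig().statin_drugs
    ck_dates = [lab.date for lab in p.labs if lab.assay == "CK" and lab.value > ck_threshold]
    if not ck_dates:
        return False
    statin_dates = [m.date for m in p.meds if _is_statin(m.drug, statin_drugs)]
    return any(
        abs((s - c).days) <= window_days for c in ck_dates for s in statin_dates
    )


def medication_exclusion(
    p: ParticipantEHR,
    recency_days: int | None = None,
    index_date: dt.date | None = None,
) -> set[str]:
    """Exclusion reasons from medication history.

    ``carbamazepine_ever``: any carbamazepine record of any kind (such
    participants were likely already HLA-B tested or tolerant).
    ``warfarin_current``: an explicit current-regimen warfarin record
    (dosing variants only affect starting dose). An optional recency
    heuristic additionally treats a warfarin dispensing within
    ``recency_days`` of ``index_date`` as current; off by default.
    """
    reasons: set[str] = set()
    for med in p.meds:
        drug = med.drug.lower()
        if drug == "carbamazepine":
            reasons.add("carbamazepine_ever")
        elif drug == "warfarin":
            if med.kind == "current_regimen":
                reasons.add("warfarin_current")
            elif (
                recency_days is not None
                and index_date is not None
                and abs((index_date - med.date).days) <= recency_days
            ):
                reasons.add("warfarin_current")
    return reasons


def is_excluded(p: ParticipantEHR, config: CohortConfig | None = None) -> bool:
    config = config or CohortConfig()
    return bool(medication_exclusion(p, recency_days=config.warfarin_recency_days))


def load_ehr_tables(directory: str | Path) -> list[ParticipantEHR]:
    """Load the four EHR tables from a directory.

    Expected files (tab-delimited, ISO-8601 dates):
      demographics.tsv: participant_id, sex, race, hispanic[, age]
      diagnoses.tsv:    participant_id, dx          (one flag per row)
      labs.tsv:         participant_id, assay, value, date
      meds.tsv:         participant_id, drug, date, kind
    """
    directory = Path(directory)
    demo = pd.read_csv(directory / "demographics.tsv", sep="\t", dtype={"participant_id": str})
    dx = pd.read_csv(directory / "diagnoses.tsv", sep="\t", dtype={"participant_id": str})
    labs = pd.read_csv(directory / "labs.tsv", sep="\t", dtype={"participant_id": str})
    meds = pd.read_csv(directory / "meds.tsv", sep="\t", dtype={"participant_id": str})

    if demo["participant_id"].duplicated().any():
        dup = demo.loc[demo["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant_id in demographics: {dup}")

    dx_by_id: dict[str, set[str]] = {}
    for pid, flag in zip(dx["participant_id"], dx["dx"]):
        dx_by_id.setdefault(pid, set()).add(flag)

    labs_by_id: dict[str, list[LabMeasurement]] = {}
    for row in labs.itertuples(index=False):
        labs_by_id.setdefault(row.participant_id, []).append(
            LabMeasurement(
                assay=row.assay,
                value=float(row.value),
                date=dt.date.fromisoformat(str(row.date)),
            )
        )

    meds_by_id: dict[str, list[MedicationRecord]] = {}
    for row in meds.itertuples(index=False):
        meds_by_id.setdefault(row.participant_id, []).append(
            MedicationRecord(
                drug=str(row.drug),
                date=dt.date.fromisoformat(str(row.date)),
                kind=str(row.kind),
            )
        )

    cohort = []
    has_age = "age" in demo.columns
    for row in demo.itertuples(index=False):
        pid = row.participant_id
        cohort.append(
            ParticipantEHR(
                participant_id=pid,
                sex=row.sex,
                race=row.race,
                hispanic=row.hispanic,
                dx=frozenset(dx_by_id.get(pid, set())),
                labs=labs_by_id.get(pid, []),
                meds=meds_by_id.get(pid, []),
                age=int(row.age) if has_age and pd.notna(row.age) else None,
            )
        )
    return cohort
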