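"""The participant selection algorithm: who enters the prioritized pool.

Four EHR data sources drive inclusion — self-reported race (Asian or
African ancestry, to enrich for non-European genetic variation),
diagnosis history (malignant hyperthermia, long QT syndrome, atrial
fibrillation, arrhythmia, CHF, hypertension), a CK > 1000 IU/L event with
a statin dispensed within six months, and medication history, which only
excludes: carbamazepine ever, or a current warfarin regimen. Exclusion is
evaluated first and overrides any inclusion reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import CohortConfig
from .ehr_features import ParticipantEHR, ck_statin_rule, medication_exclusion

INCLUSION_REASONS = (
    "race_priority",
    "malignant_hyperthermia",
    "lqts",
    "af",
    "arrhythmia",
    "chf",
    "hypertension",
    "ck_statin",
)
EXCLUSION_REASONS = ("carbamazepine_ever", "warfarin_current")

_DX_TO_REASON = {
    "malignant_hyperthermia": "malignant_hyperthermia",
    "lqts": "lqts",
    "atrial_fibrillation": "af",
    "arrhythmia": "arrhythmia",
    "chf": "chf",
    "hypertension": "hypertension",
}

_PRIORITY_RACES = frozenset({"asian", "black_african_american"})


@dataclass(frozen=True)
class SelectionDecision:
    participant_id: str
    eligible: bool
    excluded: bool
    inclusion_reasons: frozenset[str] = frozenset()
    exclusion_reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.excluded and self.eligible:
            raise ValueError("excluded participants cannot be eligible")


def select_participants(
    cohort: Sequence[ParticipantEHR], config: CohortConfig | None = None
) -> list[SelectionDecision]:
    """Evaluate every rule for every participant.

    Exclusion first: an excluded participant is ineligible no matter which
    inclusion rules fire. Otherwise, eligibility requires at least one
    inclusion reason (or none, under
    ``config.selection_requires_reason=False``, where reasons become pure
    priorities). Output order follows input order; decisions themselves
    depend only on each participant's own record.
    """
    config = config or CohortConfig()
    seen: set[str] = set()
    decisions: list[SelectionDecision] = []
    for p in cohort:
        if p.participant_id in seen:
            raise ValueError(f"duplicate participant_id: {p.participant_id}")
        seen.add(p.participant_id)

        if config.age_range is not None and p.age is not None:
            lo, hi = config.age_range
            if not (lo <= p.age <= hi):
                decisions.append(
                    SelectionDecision(p.participant_id, eligible=False, excluded=False)
                )
                continue

        excl = medication_exclusion(p, recency_days=config.warfarin_recency_days)
        if excl:
            decisions.append(
                SelectionDecision(
                    p.participant_id,
                    eligible=False,
                    excluded=True,
                    exclusion_reasons=frozenset(excl),
                )
            )
            continue

        reasons: set[str] = set()
        if config.race_priority_in_selection and p.race in _PRIORITY_RACES:
            reasons.add("race_priority")
        for dx_flag, reason in _DX_TO_REASON.items():
            if dx_flag in p.dx:
                reasons.add(reason)
        if ck_statin_rule(
            p,
            ck_threshold=config.ck_event_threshold,
            window_days=config.ck_statin_window_days,
            statin_drugs=config.statin_drugs,
        ):
            reasons.add("ck_statin")

        eligible = bool(reasons) or not config.selection_requires_reason
        decisions.append(
            SelectionDecision(
                p.participant_id,
                eligible=eligible,
                excluded=False,
                inclusion_reasons=frozenset(reasons),
            )
        )
    return decisions


def decisions_frame(decisions: Sequence[SelectionDecision]) -> pd.DataFrame:
    """One row per participant with one boolean column per reason."""
    rows = []
    for d in decisions:
        row: dict[str, object] = {
            "participant_id": d.participant_id,
            "eligible": d.eligible,
            "excluded": d.excluded,
        }
        for r in INCLUSION_REASONS:
            row[r] = r in d.inclusion_reasons
        for r in EXCLUSION_REASONS:
            row[r] = r in d.exclusion_reasons
        rows.append(row)
    return pd.DataFrame(rows)


def write_decisions(decisions: Sequence[SelectionDecision], path: str | Path) -> None:
    decisions_frame(decisions).to_csv(path, sep="\t", index=False)
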