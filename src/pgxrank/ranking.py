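"""Per-participant variant-count statistics and the tiered ranking.

Three count statistics summarize each participant over the 27-gene panel:
``total_variants`` (sites carrying a minor allele), ``coding_variants``
(the subset with high/moderate impact) and ``gh_variants`` (the subset in
the six GH genes); ``gh_priority_variants`` further restricts to
prior-evidence / stop-gain sites. Tier 1 — self-identified non-European
ancestry or an LQTS diagnosis — ranks ahead of everyone else; within
tiers the sort is descending (gh, coding, total, lab-flag sum) with
ascending participant_id as the deterministic final tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import is_gh_priority
from .config import CohortConfig, IMPACT_HIGH_MODERATE
from .ehr_features import ParticipantEHR, compute_lab_flags
from .variant_store import GenotypeMatrix, VariantRecord, carrier_matrix, dosage_matrix


@dataclass(frozen=True)
class ParticipantScore:
    participant_id: str
    total_variants: int
    coding_variants: int
    gh_variants: int
    gh_priority_variants: int
    lab_flag_sum: int = 0
    tier: int | None = None  # 1 = non-European or LQTS, 2 = ranked remainder
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.coding_variants > self.total_variants:
            raise ValueError("coding_variants cannot exceed total_variants")
        if self.gh_variants > self.total_variants:
            raise ValueError("gh_variants cannot exceed total_variants")
        if self.gh_priority_variants > self.gh_variants:
            raise ValueError("gh_priority_variants cannot exceed gh_variants")
        if not (0 <= self.lab_flag_sum <= 5):
            raise ValueError("lab_flag_sum must be in 0..5")


def _variant_masks(
    variants: Sequence[VariantRecord], config: CohortConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    panel = set(config.actionable_genes)
    for v in variants:
        if v.gene not in panel:
            raise ValueError(
                f"gene {v.gene!r} (variant {v.key}) absent from the "
                f"configured {len(panel)}-gene panel"
            )
    coding = np.array([v.impact == IMPACT_HIGH_MODERATE for v in variants])
    gh = np.array([v.gene in config.gh_genes for v in variants])
    gh_priority = np.array([is_gh_priority(v, config.gh_genes) for v in variants])
    return coding, gh, gh_priority


def _weights(
    codes: np.ndarray, variants: Sequence[VariantRecord], config: CohortConfig
) -> np.ndarray:
    """Per-site counting weight: carrier indicator or allele dose."""
    matrix = GenotypeMatrix(
        participant_ids=[str(i) for i in range(codes.shape[0])],
        variant_keys=[v.key for v in variants],
        codes=codes,
    )
    if config.counting_mode == "dose":
        return dosage_matrix(matrix, variants)
    return carrier_matrix(matrix, variants).astype(np.int64)


def count_variants(
    codes: np.ndarray,
    variants: Sequence[VariantRecord],
    config: CohortConfig | None = None,
    participant_id: str = "",
) -> ParticipantScore:
    """Count one participant's minor-allele sites over the gene panel.

    ``codes`` is that participant's row of the genotype matrix. The
    default counting unit is carrier sites (>= 1 minor allele); under
    ``config.counting_mode="dose"`` heterozygotes count 1 and homozygous
    alternates 2.
    """
    config = config or CohortConfig()
    codes = np.asarray(codes, dtype="<U1").reshape(1, -1)
    if codes.shape[1] != len(variants):
        raise ValueError(
            f"{codes.shape[1]} genotype codes for {len(variants)} variants"
        )
    coding, gh, gh_priority = _variant_masks(variants, config)
    w = _weights(codes, variants, config)[0]
    return ParticipantScore(
        participant_id=participant_id,
        total_variants=int(w.sum()),
        coding_variants=int(w[coding].sum()),
        gh_variants=int(w[gh].sum()),
        gh_priority_variants=int(w[gh_priority].sum()),
    )


def score_cohort(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    ehr: Sequence[ParticipantEHR] | None = None,
    config: CohortConfig | None = None,
) -> list[ParticipantScore]:
    """Vectorized counts for every participant, plus lab-flag sums when EHR
    records are supplied."""
    config = config or CohortConfig()
    if list(matrix.variant_keys) != [v.key for v in variants]:
        raise ValueError("genotype matrix columns do not match the variant table")
    coding, gh, gh_priority = _variant_masks(variants, config)
    w = _weights(matrix.codes, variants, config)

    flag_sums: dict[str, int] = {}
    if ehr is not None:
        for p in ehr:
            flag_sums[p.participant_id] = compute_lab_flags(
                p, config.lab_thresholds
            ).flag_sum

    scores = []
    for i, pid in enumerate(matrix.participant_ids):
        scores.append(
            ParticipantScore(
                participant_id=pid,
                total_variants=int(w[i].sum()),
                coding_variants=int(w[i][coding].sum()),
                gh_variants=int(w[i][gh].sum()),
                gh_priority_variants=int(w[i][gh_priority].sum()),
                lab_flag_sum=flag_sums.get(pid, 0),
            )
        )
    return scores


def _tier(p: ParticipantEHR, config: CohortConfig) -> int:
    # unknown race is not evidence of non-European ancestry
    non_european = config.race_priority_in_tier and p.race not in ("white", "unknown")
    return 1 if (non_european or "lqts" in p.dx) else 2


def rank_participants(
    scores: Sequence[ParticipantScore],
    ehr: Sequence[ParticipantEHR],
    config: CohortConfig | None = None,
) -> list[ParticipantScore]:
    """Deterministic tiered ranking; ranks are a permutation of 1..N.

    The sort is a total order — shuffling the input never changes the
    output — because the final tie-break is the participant identifier.
    """
    config = config or CohortConfig()
    ehr_by_id = {p.participant_id: p for p in ehr}

    def sort_key(s: ParticipantScore):
        p = ehr_by_id[s.participant_id]
        gh_stat = (
            s.gh_variants
            if config.gh_sort_statistic == "gh_variants"
            else s.gh_priority_variants
        )
        keys = [gh_stat, s.coding_variants, s.total_variants]
        keys.insert(config.lab_flag_sort_index, s.lab_flag_sum)
        return (_tier(p, config), *(-k for k in keys), s.participant_id)

    for s in scores:
        if s.participant_id not in ehr_by_id:
            raise ValueError(f"score without EHR match: {s.participant_id}")

    ranked = sorted(scores, key=sort_key)
    return [
        replace(s, tier=_tier(ehr_by_id[s.participant_id], config), rank=i + 1)
        for i, s in enumerate(ranked)
    ]


def take_top(ranking: Sequence[ParticipantScore], n: int) -> list[ParticipantScore]:
    """First ``n`` rows of a ranking — the recontact list."""
    if not (1 <= n <= len(ranking)):
        raise ValueError(f"n must be in 1..{len(ranking)}, got {n}")
    return list(ranking[:n])


def ranking_frame(ranking: Sequence[ParticipantScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [s.rank for s in ranking],
            "tier": [s.tier for s in ranking],
            "participant_id": [s.participant_id for s in ranking],
            "gh_variants": [s.gh_variants for s in ranking],
            "gh_priority_variants": [s.gh_priority_variants for s in ranking],
            "coding_variants": [s.coding_variants for s in ranking],
            "total_variants": [s.total_variants for s in ranking],
            "lab_flag_sum": [s.lab_flag_sum for s in ranking],
        }
    )


def write_ranking(ranking: Sequence[ParticipantScore], path: str | Path) -> None:
    ranking_frame(ranking).to_csv(path, sep="\t", index=False)
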