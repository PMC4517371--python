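"""Cohort-level configuration: gene panels, lab thresholds, rule knobs.

The defaults encode the study conditions of the Group Health pilot this
package models: a 27-gene actionable panel (CPIC-actionable pharmacogenes
plus disease genes of local interest), a six-gene subset prioritized for
return to the EHR, and the five laboratory flag thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The 12 variant effect-prediction classes used throughout.
EFFECT_CLASSES: tuple[str, ...] = (
    "3-prime-UTR",
    "5-prime-UTR",
    "intron",
    "intron-near-splice",
    "missense",
    "missense-near-splice",
    "non-coding-exon",
    "splice-acceptor",
    "splice-donor",
    "stop-gained",
    "synonymous",
    "synonymous-near-splice",
)

#: Effect classes mapped to high/moderate impact by default (coding and/or
#: splice modifying); everything else is "other".
HIGH_MODERATE_EFFECTS: frozenset[str] = frozenset(
    {
        "missense",
        "missense-near-splice",
        "splice-acceptor",
        "splice-donor",
        "stop-gained",
    }
)

IMPACT_HIGH_MODERATE = "high_moderate"
IMPACT_OTHER = "other"

#: Default 27-gene actionable panel: 20 genes observed with variants in the
#: pilot cohort plus 7 CPIC-actionable genes without called variants there.
ACTIONABLE_GENES: tuple[str, ...] = (
    "ABCA1",
    "ABCB1",
    "APOA1",
    "CACNA1S",
    "CFTR",
    "CYP2C19",
    "CYP2C9",
    "CYP2D6",
    "CYP3A4",
    "CYP3A5",
    "CYP4F2",
    "DPYD",
    "G6PD",
    "HLA-A",
    "HLA-B",
    "HMGCR",
    "IFNL3",
    "KCNH2",
    "LDLR",
    "NAT2",
    "RYR1",
    "RYR2",
    "SCN5A",
    "SLCO1B1",
    "TPMT",
    "UGT1A1",
    "VKORC1",
)

#: Genes whose variants are prioritized for return to the EHR at the site:
#: CACNA1S/RYR1 (malignant hyperthermia), SCN5A/KCNH2/RYR2 (arrhythmia),
#: LDLR (familial hypercholesterolemia).
GH_GENES: frozenset[str] = frozenset(
    {"CACNA1S", "RYR1", "SCN5A", "KCNH2", "RYR2", "LDLR"}
)

#: Lab flag thresholds (median of repeated measures must strictly exceed).
#: Units: LDL and TG mg/dL, CK IU/L, TSH ug/dL, INR dimensionless ratio.
DEFAULT_LAB_THRESHOLDS: dict[str, float] = {
    "LDL": 155.0,
    "TG": 288.0,
    "CK": 174.0,
    "TSH": 4.0,
    "INR": 1.5,
}

LAB_ASSAYS: tuple[str, ...] = ("LDL", "TG", "CK", "TSH", "INR")

DEFAULT_STATIN_DRUGS: tuple[str, ...] = (
    "atorvastatin",
    "fluvastatin",
    "lovastatin",
    "pitavastatin",
    "pravastatin",
    "rosuvastatin",
    "simvastatin",
)


@dataclass
class CohortConfig:
    """All tunable policy for selection, counting and ranking.

    Attributes
    ----------
    actionable_genes:
        Gene panel over which per-participant variant counts are computed.
    gh_genes:
        Subset of the panel prioritized for EHR return; drives the
        ``gh_variants`` count and the priority-variant designation.
    lab_thresholds:
        Per-assay strict thresholds applied to each participant's median.
    ck_event_threshold:
        CK lab value (IU/L) above which a single event, combined with a
        statin dispensing within ``ck_statin_window_days``, selects the
        participant (possible statin myopathy).
    counting_mode:
        "carrier" counts variant sites with >= 1 minor allele; "dose"
        counts alleles (het = 1, hom-alt = 2).
    gh_sort_statistic:
        Which GH statistic leads the ranking sort: "gh_variants" (all
        minor-allele sites in the six GH genes) or "gh_priority_variants"
        (prior-evidence / stop-gain sites only).
    lab_flag_sort_index:
        0-based position at which the lab-flag sum is inserted among the
        descending sort keys [gh, coding, total]; default appends it last.
    selection_requires_reason:
        If True, a participant is eligible only when at least one inclusion
        rule fires; if False all non-excluded participants are eligible and
        the fired rules are treated as priorities.
    race_priority_in_selection / race_priority_in_tier:
        Whether self-reported Asian / Black-or-African-American ancestry
        acts as an inclusion rule, and whether non-European ancestry puts a
        participant into tier 1 of the ranking.
    warfarin_recency_days:
        Optional heuristic: treat a warfarin dispensing within this many
        days of ``index_date`` as a current regimen. Off (None) by default;
        current regimens are otherwise explicit record kinds.
    age_range:
        Optional (lo, hi) inclusive enrollment-age pre-filter; off by
        default because the age screen happens upstream at enrollment.
    freq_denominator:
        "called" divides alternate-allele counts by called alleles;
        "all" divides by 2 x n_participants.
    """

    actionable_genes: tuple[str, ...] = ACTIONABLE_GENES
    gh_genes: frozenset[str] = GH_GENES
    lab_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAB_THRESHOLDS)
    )
    ck_event_threshold: float = 1000.0
    ck_statin_window_days: int = 183
    statin_drugs: tuple[str, ...] = DEFAULT_STATIN_DRUGS
    counting_mode: str = "carrier"
    gh_sort_statistic: str = "gh_variants"
    lab_flag_sort_index: int = 3
    selection_requires_reason: bool = True
    race_priority_in_selection: bool = True
    race_priority_in_tier: bool = True
    warfarin_recency_days: int | None = None
    age_range: tuple[int, int] | None = None
    freq_denominator: str = "called"

    def __post_init__(self) -> None:
        if self.counting_mode not in ("carrier", "dose"):
            raise ValueError(f"counting_mode must be carrier|dose, got {self.counting_mode!r}")
        if self.gh_sort_statistic not in ("gh_variants", "gh_priority_variants"):
            raise ValueError(f"unknown gh_sort_statistic {self.gh_sort_statistic!r}")
        if self.freq_denominator not in ("called", "all"):
            raise ValueError(f"freq_denominator must be called|all, got {self.freq_denominator!r}")
        for assay, thr in self.lab_thresholds.items():
            if thr <= 0:
                raise ValueError(f"lab threshold for {assay} must be > 0, got {thr}")
        self.gh_genes = frozenset(self.gh_genes)
        self.actionable_genes = tuple(self.actionable_genes)
        missing = self.gh_genes - set(self.actionable_genes)
        if missing:
            raise ValueError(f"gh_genes not in actionable panel: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_range" in raw and raw["age_range"] is not None:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["actionable_genes"] = list(self.actionable_genes)
        data["gh_genes"] = sorted(self.gh_genes)
        data["statin_drugs"] = list(self.statin_drugs)
        if self.age_range is not None:
            data["age_range"] = list(self.age_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
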