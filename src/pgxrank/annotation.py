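"""Variant impact classification, clinical-evidence flags, GH prioritization.

Evidence is consumed as precomputed annotation (ClinVar assertion class,
OMIM presence, HGMD class, prior-clinical-association and expert-review
flags); this module never queries live services or predicts pathogenicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    EFFECT_CLASSES,
    GH_GENES,
    HIGH_MODERATE_EFFECTS,
    IMPACT_HIGH_MODERATE,
    IMPACT_OTHER,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .variant_store import GenotypeMatrix, VariantRecord

log = logging.getLogger(__name__)

CLINVAR_STATES = ("pathogenic", "likely_pathogenic", "other", "absent")
HGMD_STATES = ("disease_causing", "frameshift_truncating", "other", "absent")

#: ClinVar assertion classes counted as prior pathogenic evidence.
CLINVAR_PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})
#: HGMD classes counted as prior pathogenic evidence.
HGMD_PATHOGENIC = frozenset({"disease_causing", "frameshift_truncating"})


@dataclass(frozen=True)
class EvidenceFlags:
    """Clinical-evidence annotation attached to one variant.

    The five sources are independent: none implies another, and an absent
    source simply contributes nothing to evidence-based counts.
    """

    clinvar_status: str = "absent"
    omim_present: bool = False
    hgmd_status: str = "absent"
    prior_clinical_association: bool = False
    expert_reviewed_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.clinvar_status not in CLINVAR_STATES:
            raise ValueError(
                f"clinvar_status {self.clinvar_status!r} not in {CLINVAR_STATES}"
            )
        if self.hgmd_status not in HGMD_STATES:
            raise ValueError(f"hgmd_status {self.hgmd_status!r} not in {HGMD_STATES}")


#: Default effect -> impact map (total over the 12 effect classes).
DEFAULT_IMPACT_MAP: dict[str, str] = {
    effect: (IMPACT_HIGH_MODERATE if effect in HIGH_MODERATE_EFFECTS else IMPACT_OTHER)
    for effect in EFFECT_CLASSES
}


def classify_impact(effect: str, impact_map: dict[str, str] | None = None) -> str:
    """Map an effect-prediction class to ``high_moderate`` or ``other``.

    A pure lookup; unknown effect labels are a hard error listing the known
    ones, so typos in annotation fields surface immediately.
    """
    mapping = DEFAULT_IMPACT_MAP if impact_map is None else impact_map
    try:
        return mapping[effect]
    except KeyError:
        raise ValueError(
            f"unknown effect class {effect!r}; known classes: {sorted(mapping)}"
        ) from None


def has_prior_clinical_pathogenicity(evidence: EvidenceFlags) -> bool:
    """Prior clinical evidence of pathogenicity, per the default policy.

    True if ClinVar asserts pathogenic/likely-pathogenic, HGMD classes the
    variant as disease-causing or frameshift/truncating, or an expert
    review called it pathogenic. These are the evidence sources used to
    flag participants for re-consent.
    """
    return (
        evidence.clinvar_status in CLINVAR_PATHOGENIC
        or evidence.hgmd_status in HGMD_PATHOGENIC
        or evidence.expert_reviewed_pathogenic
    )


def is_gh_priority(
    variant: "VariantRecord", gh_genes: frozenset[str] | Iterable[str] = GH_GENES
) -> bool:
    """Is this variant prioritized for return to the EHR?

    True iff the gene is in the six-gene GH set AND the variant either has
    prior clinical evidence of pathogenicity or is annotated stop-gained.
    """
    if variant.gene not in set(gh_genes):
        return False
    return variant.effect == "stop-gained" or has_prior_clinical_pathogenicity(
        variant.evidence
    )


@dataclass
class ReconsentReport:
    """Per-participant evidence flags used to drive re-consent decisions."""

    table: pd.DataFrame  # index participant_id; bool columns per source + union
    per_source_counts: dict[str, int]
    union_count: int


def reconsent_evidence_flags(
    cohort: "GenotypeMatrix", variants: Sequence["VariantRecord"]
) -> ReconsentReport:
    """Flag participants carrying variants with actionable prior evidence.

    Four sources are evaluated per participant: carriage of a ClinVar
    pathogenic/likely-pathogenic variant, of a stop-gained variant, of an
    HGMD disease-causing or frameshift/truncating variant, and of an
    expert-reviewed pathogenic variant. The union flag marks participants
    identified by any source; a participant carrying one variant flagged by
    several sources counts once in the union.
    """
    from .variant_store import carrier_matrix

    keys = [v.key for v in variants]
    if list(cohort.variant_keys) != keys:
        raise ValueError(
            "genotype matrix columns do not match the variant table "
            f"({len(cohort.variant_keys)} matrix keys vs {len(keys)} variants)"
        )
    carrier = carrier_matrix(cohort, variants)  # participants x variants, bool

    clinvar = np.array(
        [v.evidence.clinvar_status in CLINVAR_PATHOGENIC for v in variants]
    )
    stopgain = np.array([v.effect == "stop-gained" for v in variants])
    hgmd = np.array([v.evidence.hgmd_status in HGMD_PATHOGENIC for v in variants])
    expert = np.array([v.evidence.expert_reviewed_pathogenic for v in variants])

    table = pd.DataFrame(
        {
            "clinvar_path": (carrier & clinvar).any(axis=1),
            "stop_gained": (carrier & stopgain).any(axis=1),
            "hgmd_disease": (carrier & hgmd).any(axis=1),
            "expert_path": (carrier & expert).any(axis=1),
        },
        index=pd.Index(cohort.participant_ids, name="participant_id"),
    )
    table["any_evidence"] = table.any(axis=1)
    counts = {
        col: int(table[col].sum())
        for col in ("clinvar_path", "stop_gained", "hgmd_disease", "expert_path")
    }
    return ReconsentReport(
        table=table,
        per_source_counts=counts,
        union_count=int(table["any_evidence"].sum()),
    )
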