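"""Linked synthetic cohorts: annotated multi-sample VCF + EHR tables.

The generator emulates the statistical structure of the pilot cohort this
package models — its race and ethnicity distribution, diagnosis
prevalences, effect-class mix, per-gene variant loads, and repeated lab
measures whose 90th-percentile tails sit at the flag thresholds — so that
every pipeline stage is testable without any controlled-access download.
Genotypes are drawn per site under Hardy-Weinberg equilibrium from the
site's allele frequency; sites are independent (no linkage
disequilibrium), which suffices because the pipeline never uses LD.

Every latent quantity (true per-participant counts, true lab flags) is
recorded in truth tables for oracle testing.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import DEFAULT_IMPACT_MAP
from .config import (
    EFFECT_CLASSES,
    GH_GENES,
    HIGH_MODERATE_EFFECTS,
    IMPACT_HIGH_MODERATE,
    LAB_ASSAYS,
)
from .ehr_features import (
    DX_FLAGS,
    HISPANIC,
    LabMeasurement,
    MedicationRecord,
    ParticipantEHR,
    RACES,
)
from .variant_store import (
    EvidenceFlags,
    GenotypeMatrix,
    MISSING_CODE,
    VariantRecord,
    het_code,
    hom_alt_code,
    hom_ref_code,
)


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    chrom: str
    start: int
    end: int
    n_variants: int


#: Approximate GRCh37 loci for the 27-gene panel (positions only anchor
#: the synthetic VCF; nothing downstream depends on their accuracy).
GENE_COORDS: dict[str, tuple[str, int, int]] = {
    "ABCA1": ("9", 107543283, 107690527),
    "ABCB1": ("7", 87132948, 87342564),
    "APOA1": ("11", 116706467, 116708338),
    "CACNA1S": ("1", 201008640, 201081694),
    "CFTR": ("7", 117120017, 117308719),
    "CYP2C19": ("10", 96522463, 96612671),
    "CYP2C9": ("10", 96698415, 96749148),
    "CYP2D6": ("22", 42522501, 42526883),
    "CYP3A4": ("7", 99354604, 99381888),
    "CYP3A5": ("7", 99245813, 99277621),
    "CYP4F2": ("19", 15988833, 16008884),
    "DPYD": ("1", 97543300, 98386615),
    "G6PD": ("X", 153759606, 153775787),
    "HLA-A": ("6", 29910247, 29913661),
    "HLA-B": ("6", 31321649, 31324989),
    "HMGCR": ("5", 74632154, 74657929),
    "IFNL3": ("19", 39734976, 39737742),
    "KCNH2": ("7", 150642044, 150675403),
    "LDLR": ("19", 11200038, 11244506),
    "NAT2": ("8", 18248755, 18258728),
    "RYR1": ("19", 38924340, 39078204),
    "RYR2": ("1", 237205702, 237997288),
    "SCN5A": ("3", 38589553, 38691164),
    "SLCO1B1": ("12", 21284127, 21392730),
    "TPMT": ("6", 18128311, 18155374),
    "UGT1A1": ("2", 234668916, 234681945),
    "VKORC1": ("16", 31102175, 31106118),
}

#: Observed per-gene variant loads in the pilot cohort (1785 total over 20
#: genes; the remaining 7 panel genes had no called variants there).
GENE_VARIANT_WEIGHTS: dict[str, int] = {
    "ABCA1": 158,
    "ABCB1": 95,
    "APOA1": 10,
    "CACNA1S": 101,
    "CYP2C19": 47,
    "CYP2C9": 64,
    "CYP2D6": 193,
    "CYP3A4": 53,
    "CYP3A5": 3,
    "DPYD": 74,
    "HMGCR": 65,
    "KCNH2": 101,
    "LDLR": 100,
    "NAT2": 21,
    "RYR1": 241,
    "RYR2": 190,
    "SCN5A": 143,
    "SLCO1B1": 45,
    "TPMT": 48,
    "VKORC1": 33,
}

#: Effect-class mix over the 1785 observed variants.
EFFECT_COUNTS: dict[str, int] = {
    "3-prime-UTR": 328,
    "5-prime-UTR": 71,
    "intron": 377,
    "intron-near-splice": 19,
    "missense": 509,
    "missense-near-splice": 10,
    "non-coding-exon": 3,
    "splice-acceptor": 3,
    "splice-donor": 2,
    "stop-gained": 11,
    "synonymous": 451,
    "synonymous-near-splice": 1,
}

#: Cohort composition over N = 894 participants.
RACE_COUNTS: dict[str, int] = {
    "american_indian_alaska_native": 11,
    "asian": 69,
    "black_african_american": 41,
    "native_hawaiian_pacific_islander": 2,
    "unknown": 20,
    "white": 751,
}
HISPANIC_COUNTS: dict[str, int] = {"yes": 30, "no": 846, "unknown": 18}
DX_PREVALENCE: dict[str, float] = {
    "malignant_hyperthermia": 0.002,  # rare; not tabulated in the cohort
    "lqts": 2 / 894,
    "atrial_fibrillation": 85 / 894,
    "arrhythmia": 450 / 894,
    "chf": 18 / 894,
    "hypertension": 708 / 894,
}
FEMALE_RATE = 546 / 894


def default_gene_panel(total_variants: int = 1785) -> tuple[GeneSpec, ...]:
    """The 27-gene panel with per-gene loads scaled from the observed ones.

    Genes without observed variants keep zero; the 20 weighted genes share
    ``total_variants`` proportionally (largest-remainder allocation).
    """
    genes = sorted(GENE_COORDS)
    weights = np.array([GENE_VARIANT_WEIGHTS.get(g, 0) for g in genes], dtype=float)
    wsum = weights.sum()
    raw = weights * total_variants / wsum
    alloc = np.floor(raw).astype(int)
    remainder = total_variants - alloc.sum()
    order = np.argsort(-(raw - alloc))
    for i in range(remainder):
        alloc[order[i]] += 1
    return tuple(
        GeneSpec(g, *GENE_COORDS[g], n_variants=int(a)) for g, a in zip(genes, alloc)
    )


@dataclass(frozen=True)
class AlleleFrequencyModel:
    """Per-site alternate-allele frequency: mixture of a rare Beta
    component and a common Uniform component, globally rescaled by
    ``scale`` (the calibration knob)."""

    w_common: float = 0.1
    beta_a: float = 0.3
    beta_b: float = 30.0
    uniform_low: float = 0.01
    uniform_high: float = 0.5
    scale: float = 1.0

    def moments(self) -> tuple[float, float]:
        """(E[p], E[p^2]) of the unscaled mixture, in closed form."""
        a, b = self.beta_a, self.beta_b
        beta_m1 = a / (a + b)
        beta_m2 = a * (a + 1) / ((a + b) * (a + b + 1))
        lo, hi = self.uniform_low, self.uniform_high
        uni_m1 = (lo + hi) / 2
        uni_m2 = (hi * hi + hi * lo + lo * lo) / 3
        w = self.w_common
        return (
            w * uni_m1 + (1 - w) * beta_m1,
            w * uni_m2 + (1 - w) * beta_m2,
        )

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        common = rng.random(n) < self.w_common
        uni = rng.uniform(self.uniform_low, self.uniform_high, n)
        beta = rng.beta(self.beta_a, self.beta_b, n)
        return np.clip(np.where(common, uni, beta) * self.scale, 0.0, 0.999)


_Z90 = 1.2815515655446004  # standard normal 90th percentile


@dataclass(frozen=True)
class LabModel:
    """Lognormal participant-level assay model pinned by (median, p90).

    Repeated measures scatter around the participant's latent level with
    multiplicative noise of ``noise_frac`` x the between-participant log
    spread, so the participant's median keeps its 90th percentile at
    ``p90`` to good approximation.
    """

    median: float
    p90: float
    noise_frac: float = 0.05
    mean_extra_repeats: float = 2.0

    @property
    def sigma(self) -> float:
        return math.log(self.p90 / self.median) / _Z90


#: Assay units: LDL/TG mg/dL, CK IU/L, TSH ug/dL, INR ratio. The p90
#: defaults sit exactly at the flag thresholds, which were themselves
#: chosen as observed 90th percentiles.
DEFAULT_LAB_MODELS: dict[str, LabModel] = {
    "LDL": LabModel(median=115.0, p90=155.0),
    "TG": LabModel(median=130.0, p90=288.0),
    "CK": LabModel(median=90.0, p90=174.0),
    "TSH": LabModel(median=1.8, p90=4.0),
    "INR": LabModel(median=1.0, p90=1.5),
}


@dataclass(frozen=True)
class MedicationModel:
    statin_rate: float = 0.30
    carbamazepine_rate: float = 0.01
    warfarin_current_rate: float = 0.02
    warfarin_past_rate: float = 0.02
    #: fraction of participants given an injected CK > 1000 event with a
    #: statin dispensing inside the selection window
    ck_statin_rate: float = 0.005


@dataclass(frozen=True)
class EvidenceRates:
    """Per-impact-class annotation probabilities."""

    prior_clin: float
    clinvar_present: float
    clinvar_split: tuple[float, float, float]  # pathogenic / likely / other
    omim: float
    hgmd_present: float
    hgmd_split: tuple[float, float, float]  # disease_causing / frameshift / other
    expert: float


#: Rates follow the observed variant-level table: ~18 % of high/moderate
#: variants carry a prior clinical association, ~30 % an HGMD entry,
#: ~3 % a ClinVar assertion; lower-impact variants carry far less.
DEFAULT_EVIDENCE_MODEL: dict[str, EvidenceRates] = {
    IMPACT_HIGH_MODERATE: EvidenceRates(
        prior_clin=96 / 532,
        clinvar_present=17 / 532,
        clinvar_split=(0.5, 0.3, 0.2),
        omim=3 / 532,
        hgmd_present=157 / 532,
        hgmd_split=(0.45, 0.10, 0.45),
        expert=0.02,
    ),
    "other": EvidenceRates(
        prior_clin=72 / 1253,
        clinvar_present=12 / 1253,
        clinvar_split=(0.1, 0.1, 0.8),
        omim=6 / 1253,
        hgmd_present=23 / 1253,
        hgmd_split=(0.2, 0.05, 0.75),
        expert=0.002,
    ),
}


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort; the seed determines
    every byte of output."""

    n_participants: int = 894
    seed: int = 0
    gene_panel: tuple[GeneSpec, ...] = field(default_factory=default_gene_panel)
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            e: c / sum(EFFECT_COUNTS.values()) for e, c in EFFECT_COUNTS.items()
        }
    )
    allele_freq_model: AlleleFrequencyModel = field(default_factory=AlleleFrequencyModel)
    race_mix: dict[str, float] = field(
        default_factory=lambda: {r: c / 894 for r, c in RACE_COUNTS.items()}
    )
    hispanic_mix: dict[str, float] = field(
        default_factory=lambda: {h: c / 894 for h, c in HISPANIC_COUNTS.items()}
    )
    sex_female_rate: float = FEMALE_RATE
    dx_prevalence: dict[str, float] = field(default_factory=lambda: dict(DX_PREVALENCE))
    lab_models: dict[str, LabModel] = field(
        default_factory=lambda: dict(DEFAULT_LAB_MODELS)
    )
    med_model: MedicationModel = field(default_factory=MedicationModel)
    evidence_model: dict[str, EvidenceRates] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_MODEL)
    )
    rsid_rate: float = 0.70
    missing_rate: float = 0.002
    calendar_start: dt.date = dt.date(2005, 1, 1)
    calendar_days: int = 3652  # ten-year synthetic calendar

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, vec, labels in (
            ("effect_mix", self.effect_mix, EFFECT_CLASSES),
            ("race_mix", self.race_mix, RACES),
            ("hispanic_mix", self.hispanic_mix, HISPANIC),
        ):
            if set(vec) != set(labels):
                raise ValueError(f"{name} must cover exactly {sorted(labels)}")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(vec.values())})")
        if set(self.dx_prevalence) != set(DX_FLAGS):
            raise ValueError(f"dx_prevalence must cover exactly {sorted(DX_FLAGS)}")
        if set(self.lab_models) != set(LAB_ASSAYS):
            raise ValueError(f"lab_models must cover exactly {sorted(LAB_ASSAYS)}")
        total = sum(g.n_variants for g in self.gene_panel)
        effect_mass = sum(self.effect_mix.values())
        if total == 0 and effect_mass > 0:
            raise ValueError(
                "infeasible config: zero variants in the panel with "
                "nonzero effect-class mass"
            )

    @property
    def n_variants(self) -> int:
        return sum(g.n_variants for g in self.gene_panel)


def expected_total_variants(cfg: SimConfig) -> float:
    """Closed-form expected per-participant carrier count.

    Under Hardy-Weinberg a participant carries a site of frequency p with
    probability 1 - (1 - p)^2 = 2p - p^2; summing over independent sites
    and accounting for genotype missingness gives
    n_sites * (1 - miss) * (2 s m1 - s^2 m2) with (m1, m2) the frequency
    moments and s the model scale.
    """
    m1, m2 = cfg.allele_freq_model.moments()
    s = cfg.allele_freq_model.scale
    return cfg.n_variants * (1.0 - cfg.missing_rate) * (2 * s * m1 - s * s * m2)


def calibrate_total_variants(cfg: SimConfig, target_mean: float) -> SimConfig:
    """Rescale the allele-frequency model so the expected carrier count
    equals ``target_mean`` (exactly, in closed form; empirical means then
    land within sampling error).

    Raises ``ValueError`` when the target is unattainable for the panel
    (the expectation is maximized at s = m1/m2) or would push frequencies
    above 1.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    m1, m2 = cfg.allele_freq_model.moments()
    denom = cfg.n_variants * (1.0 - cfg.missing_rate)
    if denom == 0:
        raise ValueError("cannot calibrate a panel with zero variants")
    t = target_mean / denom
    disc = m1 * m1 - m2 * t
    if disc < 0:
        max_mean = denom * m1 * m1 / m2
        raise ValueError(
            f"target {target_mean} unattainable: panel of {cfg.n_variants} "
            f"sites supports at most a mean of {max_mean:.2f}"
        )
    s = (m1 - math.sqrt(disc)) / m2
    if s * cfg.allele_freq_model.uniform_high > 1.0:
        raise ValueError(
            f"target {target_mean} needs scale {s:.3f}, which pushes common "
            "allele frequencies above 1"
        )
    model = dataclasses.replace(cfg.allele_freq_model, scale=s)
    return dataclasses.replace(cfg, allele_freq_model=model)


# ---------------------------------------------------------------------------
# simulation internals

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulatedCohort:
    """In-memory result: inputs for the pipeline plus latent truth."""

    cfg: SimConfig
    participant_ids: list[str]
    variants: list[VariantRecord]
    matrix: GenotypeMatrix
    freqs: np.ndarray  # latent per-site allele frequencies (proportions)
    dosage: np.ndarray  # participants x variants, 0/1/2
    missing: np.ndarray  # participants x variants, bool
    depth: np.ndarray  # per-sample read depth, participants x variants
    rsids: list[str]
    ehr: list[ParticipantEHR]
    truth_scores: pd.DataFrame
    truth_lab_flags: pd.DataFrame


def _draw_variants(cfg: SimConfig, rng: np.random.Generator):
    genes, chroms, positions = [], [], []
    for spec in cfg.gene_panel:
        if spec.n_variants == 0:
            continue
        span = spec.end - spec.start + 1
        if spec.n_variants > span:
            raise ValueError(f"gene {spec.gene}: more variants than positions")
        pos = np.sort(rng.choice(span, size=spec.n_variants, replace=False)) + spec.start
        genes.extend([spec.gene] * spec.n_variants)
        chroms.extend([spec.chrom] * spec.n_variants)
        positions.extend(int(p) for p in pos)

    order = sorted(
        range(len(genes)),
        key=lambda i: (_CHROM_ORDER.get(chroms[i], 99), positions[i]),
    )
    genes = [genes[i] for i in order]
    chroms = [chroms[i] for i in order]
    positions = [positions[i] for i in order]
    n = len(genes)

    ref_idx = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    labels = list(EFFECT_CLASSES)
    probs = np.array([cfg.effect_mix[e] for e in labels])
    effects = rng.choice(labels, size=n, p=probs)
    impacts = np.array([DEFAULT_IMPACT_MAP[e] for e in effects])
    high = impacts == IMPACT_HIGH_MODERATE

    # annotation scores conditional on impact class (quartile-matched)
    gerp = np.where(high, rng.normal(3.9, 2.08, n), rng.normal(-0.47, 3.74, n))
    cadd = np.clip(
        np.where(high, rng.normal(14.36, 6.12, n), rng.normal(5.37, 4.85, n)), 0.1, None
    )
    site_depth = np.clip(rng.normal(413.0, 127.0, n), 30.0, None)

    freqs = cfg.allele_freq_model.draw(rng, n)
    has_rsid = rng.random(n) < cfg.rsid_rate

    evidence = []
    for i in range(n):
        rates = cfg.evidence_model[IMPACT_HIGH_MODERATE if high[i] else "other"]
        clinvar = "absent"
        if rng.random() < rates.clinvar_present:
            clinvar = rng.choice(
                ["pathogenic", "likely_pathogenic", "other"], p=rates.clinvar_split
            )
        hgmd = "absent"
        if rng.random() < rates.hgmd_present:
            hgmd = rng.choice(
                ["disease_causing", "frameshift_truncating", "other"],
                p=rates.hgmd_split,
            )
        evidence.append(
            EvidenceFlags(
                clinvar_status=str(clinvar),
                omim_present=bool(rng.random() < rates.omim),
                hgmd_status=str(hgmd),
                prior_clinical_association=bool(rng.random() < rates.prior_clin),
                expert_reviewed_pathogenic=bool(rng.random() < rates.expert),
            )
        )
    return genes, chroms, positions, refs, alts, effects, impacts, gerp, cadd, site_depth, freqs, has_rsid, evidence


def _random_dates(rng: np.random.Generator, cfg: SimConfig, n: int) -> list[dt.date]:
    offs = rng.integers(0, cfg.calendar_days, n)
    return [cfg.calendar_start + dt.timedelta(days=int(o)) for o in offs]


def _simulate_ehr(cfg: SimConfig, rng: np.random.Generator, pids: list[str]):
    n = len(pids)
    sexes = np.where(rng.random(n) < cfg.sex_female_rate, "female", "male")
    races = rng.choice(
        list(RACES), size=n, p=[cfg.race_mix[r] for r in RACES]
    )
    hispanics = rng.choice(
        list(HISPANIC), size=n, p=[cfg.hispanic_mix[h] for h in HISPANIC]
    )
    dx_draws = {
        flag: rng.random(n) < prev for flag, prev in cfg.dx_prevalence.items()
    }

    participants: list[ParticipantEHR] = []
    mm = cfg.med_model
    for i, pid in enumerate(pids):
        labs: list[LabMeasurement] = []
        for assay in LAB_ASSAYS:
            model = cfg.lab_models[assay]
            latent = math.log(model.median) + model.sigma * rng.standard_normal()
            k = 1 + int(rng.poisson(model.mean_extra_repeats))
            noise = model.noise_frac * model.sigma * rng.standard_normal(k)
            values = np.exp(latent + noise)
            for value, date in zip(values, _random_dates(rng, cfg, k)):
                labs.append(LabMeasurement(assay=assay, value=float(value), date=date))

        meds: list[MedicationRecord] = []
        if rng.random() < mm.statin_rate:
            drug = ["simvastatin", "atorvastatin"][int(rng.integers(0, 2))]
            n_disp = 1 + int(rng.poisson(2))
            for date in _random_dates(rng, cfg, n_disp):
                meds.append(MedicationRecord(drug=drug, date=date, kind="dispensing"))
        if rng.random() < mm.carbamazepine_rate:
            meds.append(
                MedicationRecord(
                    drug="carbamazepine",
                    date=_random_dates(rng, cfg, 1)[0],
                    kind="dispensing",
                )
            )
        if rng.random() < mm.warfarin_current_rate:
            meds.append(
                MedicationRecord(
                    drug="warfarin",
                    date=_random_dates(rng, cfg, 1)[0],
                    kind="current_regimen",
                )
            )
        elif rng.random() < mm.warfarin_past_rate:
            meds.append(
                MedicationRecord(
                    drug="warfarin",
                    date=_random_dates(rng, cfg, 1)[0],
                    kind="dispensing",
                )
            )
        if rng.random() < mm.ck_statin_rate:
            # inject a CK spike with a statin dispensing inside the window
            margin = 200
            off = int(rng.integers(margin, cfg.calendar_days - margin))
            ck_date = cfg.calendar_start + dt.timedelta(days=off)
            labs.append(
                LabMeasurement(
                    assay="CK",
                    value=float(rng.uniform(1100.0, 3000.0)),
                    date=ck_date,
                )
            )
            statin_date = ck_date + dt.timedelta(days=int(rng.integers(-150, 151)))
            meds.append(
                MedicationRecord(
                    drug="simvastatin", date=statin_date, kind="dispensing"
                )
            )

        participants.append(
            ParticipantEHR(
                participant_id=pid,
                sex=str(sexes[i]),
                race=str(races[i]),
                hispanic=str(hispanics[i]),
                dx=frozenset(f for f in DX_FLAGS if dx_draws[f][i]),
                labs=labs,
                meds=meds,
            )
        )
    return participants


def simulate_arrays(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full linked cohort in memory."""
    rng = np.random.default_rng(cfg.seed)
    pids = [f"P{i + 1:05d}" for i in range(cfg.n_participants)]

    (
        genes,
        chroms,
        positions,
        refs,
        alts,
        effects,
        impacts,
        gerp,
        cadd,
        site_depth,
        freqs,
        has_rsid,
        evidence,
    ) = _draw_variants(cfg, rng)
    n_var = len(genes)
    n_part = cfg.n_participants

    dosage = rng.binomial(2, freqs[None, :], size=(n_part, n_var))
    missing = rng.random((n_part, n_var)) < cfg.missing_rate
    depth = rng.poisson(site_depth[None, :], size=(n_part, n_var))

    called = 2 * (n_part - missing.sum(axis=0))
    ac = np.where(missing, 0, dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_pct = np.where(called > 0, 100.0 * ac / np.maximum(called, 1), 0.0)

    variants: list[VariantRecord] = []
    for j in range(n_var):
        variants.append(
            VariantRecord(
                chrom=chroms[j],
                pos=positions[j],
                ref=str(refs[j]),
                alt=str(alts[j]),
                alt_freq_pct=float(freq_pct[j]),
                gene=genes[j],
                effect=str(effects[j]),
                impact=str(impacts[j]),
                has_rsid=bool(has_rsid[j]),
                evidence=evidence[j],
                gerp=float(gerp[j]),
                cadd=float(cadd[j]),
                mean_depth=float(depth[:, j].mean()),
            )
        )

    pervar_codes = np.stack(
        [
            np.array([hom_ref_code(v) for v in variants], dtype="<U1"),
            np.array([het_code(v) for v in variants], dtype="<U1"),
            np.array([hom_alt_code(v) for v in variants], dtype="<U1"),
        ]
    )
    codes = pervar_codes[dosage, np.arange(n_var)[None, :]]
    codes[missing] = MISSING_CODE
    matrix = GenotypeMatrix(
        participant_ids=pids,
        variant_keys=[v.key for v in variants],
        codes=codes,
    )

    rsid_counter = 0
    rsids = []
    for j in range(n_var):
        if has_rsid[j]:
            rsid_counter += 1
            rsids.append(f"rs{1000000 + rsid_counter}")
        else:
            rsids.append(".")

    ehr = _simulate_ehr(cfg, rng, pids)

    # --- latent truth, tallied directly from the generated arrays -------
    carrier = (dosage > 0) & ~missing
    coding_mask = np.array([e in HIGH_MODERATE_EFFECTS for e in effects])
    gh_mask = np.array([g in GH_GENES for g in genes])
    prior_path = np.array(
        [
            ev.clinvar_status in ("pathogenic", "likely_pathogenic")
            or ev.hgmd_status in ("disease_causing", "frameshift_truncating")
            or ev.expert_reviewed_pathogenic
            for ev in evidence
        ]
    )
    priority_mask = gh_mask & (prior_path | (np.array(effects) == "stop-gained"))
    truth_scores = pd.DataFrame(
        {
            "participant_id": pids,
            "total_variants": carrier.sum(axis=1),
            "coding_variants": carrier[:, coding_mask].sum(axis=1),
            "gh_variants": carrier[:, gh_mask].sum(axis=1),
            "gh_priority_variants": carrier[:, priority_mask].sum(axis=1),
        }
    )

    flag_rows = []
    thresholds = {a: cfg.lab_models[a].p90 for a in LAB_ASSAYS}
    for p in ehr:
        by_assay: dict[str, list[float]] = {a: [] for a in LAB_ASSAYS}
        for lab in p.labs:
            by_assay[lab.assay].append(lab.value)
        row: dict[str, object] = {"participant_id": p.participant_id}
        for a in LAB_ASSAYS:
            vals = by_assay[a]
            row[f"{a}_flag"] = int(bool(vals) and float(np.median(vals)) > thresholds[a])
        row["flag_sum"] = sum(int(row[f"{a}_flag"]) for a in LAB_ASSAYS)
        flag_rows.append(row)
    truth_lab_flags = pd.DataFrame(flag_rows)

    return SimulatedCohort(
        cfg=cfg,
        participant_ids=pids,
        variants=variants,
        matrix=matrix,
        freqs=freqs,
        dosage=dosage,
        missing=missing,
        depth=depth,
        rsids=rsids,
        ehr=ehr,
        truth_scores=truth_scores,
        truth_lab_flags=truth_lab_flags,
    )


# ---------------------------------------------------------------------------
# file output

_VCF_INFO_HEADER = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect prediction class">',
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="high_moderate or other">',
    '##INFO=<ID=RSID_PRESENT,Number=1,Type=Integer,Description="1 if a prior rsID exists">',
    '##INFO=<ID=GERP,Number=1,Type=Float,Description="GERP conservation score">',
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled CADD score">',
    '##INFO=<ID=MEAN_DP,Number=1,Type=Float,Description="Mean read depth across participants">',
    '##INFO=<ID=CLINVAR,Number=1,Type=String,Description="ClinVar assertion class">',
    '##INFO=<ID=OMIM,Number=0,Type=Flag,Description="Present in OMIM">',
    '##INFO=<ID=HGMD,Number=1,Type=String,Description="HGMD class">',
    '##INFO=<ID=PRIOR_CLIN,Number=0,Type=Flag,Description="Prior clinical association">',
    '##INFO=<ID=EXPERT_PATH,Number=0,Type=Flag,Description="Expert-reviewed pathogenic">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

_GT_STRINGS = ("0/0", "0/1", "1/1")


def write_vcf(cohort: SimulatedCohort, path: str | Path) -> None:
    """Write the cohort as an uncompressed annotated multi-sample VCF.

    Plain text output with fixed float formatting so identical seeds give
    byte-identical files; the file is read back through standard VCF
    tooling downstream.
    """
    lines = ["##fileformat=VCFv4.2", "##source=pgxrank-synthetic"]
    contigs: dict[str, int] = {}
    for v in cohort.variants:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + 10000)
    for chrom in sorted(contigs, key=lambda c: _CHROM_ORDER.get(c, 99)):
        lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    lines.extend(_VCF_INFO_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.participant_ids)
    )

    for j, v in enumerate(cohort.variants):
        info = [
            f"GENE={v.gene}",
            f"EFFECT={v.effect}",
            f"IMPACT={v.impact}",
            f"RSID_PRESENT={int(v.has_rsid)}",
            f"GERP={v.gerp:.4f}",
            f"CADD={v.cadd:.4f}",
        ]
        ev = v.evidence
        if ev.clinvar_status != "absent":
            info.append(f"CLINVAR={ev.clinvar_status}")
        if ev.omim_present:
            info.append("OMIM")
        if ev.hgmd_status != "absent":
            info.append(f"HGMD={ev.hgmd_status}")
        if ev.prior_clinical_association:
            info.append("PRIOR_CLIN")
        if ev.expert_reviewed_pathogenic:
            info.append("EXPERT_PATH")

        dose = cohort.dosage[:, j]
        miss = cohort.missing[:, j]
        dp = cohort.depth[:, j]
        samples = "\t".join(
            f"./.:{dp[i]}" if miss[i] else f"{_GT_STRINGS[dose[i]]}:{dp[i]}"
            for i in range(len(dose))
        )
        lines.append(
            f"{v.chrom}\t{v.pos}\t{cohort.rsids[j]}\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info)
            + f"\tGT:DP\t{samples}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ehr_tables(ehr: Sequence[ParticipantEHR], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in ehr],
            "sex": [p.sex for p in ehr],
            "race": [p.race for p in ehr],
            "hispanic": [p.hispanic for p in ehr],
        }
    ).to_csv(directory / "demographics.tsv", sep="\t", index=False)

    dx_rows = [
        {"participant_id": p.participant_id, "dx": flag}
        for p in ehr
        for flag in sorted(p.dx)
    ]
    pd.DataFrame(dx_rows, columns=["participant_id", "dx"]).to_csv(
        directory / "diagnoses.tsv", sep="\t", index=False
    )

    lab_rows = [
        {
            "participant_id": p.participant_id,
            "assay": lab.assay,
            "value": f"{lab.value:.6f}",
            "date": lab.date.isoformat(),
        }
        for p in ehr
        for lab in p.labs
    ]
    pd.DataFrame(lab_rows, columns=["participant_id", "assay", "value", "date"]).to_csv(
        directory / "labs.tsv", sep="\t", index=False
    )

    med_rows = [
        {
            "participant_id": p.participant_id,
            "drug": med.drug,
            "date": med.date.isoformat(),
            "kind": med.kind,
        }
        for p in ehr
        for med in p.meds
    ]
    pd.DataFrame(med_rows, columns=["participant_id", "drug", "date", "kind"]).to_csv(
        directory / "meds.tsv", sep="\t", index=False
    )


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write every pipeline input plus truth tables.

    Layout under ``outdir``: ``cohort.vcf``, ``ehr/*.tsv`` and
    ``truth/*.tsv``. Returns the paths. Identical configs (including the
    seed) produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_arrays(cfg)

    vcf_path = outdir / "cohort.vcf"
    write_vcf(cohort, vcf_path)
    ehr_dir = outdir / "ehr"
    write_ehr_tables(cohort.ehr, ehr_dir)

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.truth_scores.to_csv(truth_dir / "participant_scores.tsv", sep="\t", index=False)
    cohort.truth_lab_flags.to_csv(truth_dir / "lab_flags.tsv", sep="\t", index=False)
    from .variant_store import variant_table

    variant_table(cohort.variants).to_csv(truth_dir / "variants.tsv", sep="\t", index=False)

    return {"vcf": vcf_path, "ehr": ehr_dir, "truth": truth_dir}
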