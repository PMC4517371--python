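"""Annotated multi-sample VCF -> the two-table relational model.

One table holds variant-level metadata (one row per site x alternate
allele), the other holds participant-level genotypes as single-character
IUPAC codes; the two are joined by a human-readable index key of the form

    chr{chrom}.pos{pos}.ref{ref}.altper{freq}.gene{gene}

e.g. ``chr1.pos237754201.refG.altper0.11.geneRYR2``: chromosome 1,
position 237754201, reference guanine, cohort alternate-allele frequency
0.11 %, gene RYR2. The key round-trips losslessly through
:func:`parse_index_key`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import (
    CLINVAR_STATES,
    DEFAULT_IMPACT_MAP,
    EvidenceFlags,
    HGMD_STATES,
    classify_impact,
)
from .config import (
    CohortConfig,
    EFFECT_CLASSES,
    IMPACT_HIGH_MODERATE,
    IMPACT_OTHER,
)

log = logging.getLogger(__name__)

MISSING_CODE = "."

#: Standard IUPAC two-base ambiguity codes for heterozygous genotypes.
IUPAC_HET: dict[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: INFO fields that must be present on every record.
REQUIRED_INFO = ("GENE", "EFFECT", "IMPACT", "RSID_PRESENT", "GERP", "CADD")


class VcfContractError(ValueError):
    """The input VCF violates the documented annotation contract."""


class KeyFormatError(ValueError):
    """An index key does not conform to the documented dialect."""


@dataclass(frozen=True)
class VariantRecord:
    """One normalized alternate allele with its annotation.

    ``alt_freq_pct`` is the cohort alternate-allele frequency in percent
    (0-100), by default over called alleles at the site. ``impact`` is
    ``high_moderate`` or ``other``; ``impact_overridden`` marks records
    where the annotation source's impact disagreed with the default
    effect -> impact map (the source is authoritative).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_freq_pct: float
    gene: str
    effect: str
    impact: str
    has_rsid: bool
    evidence: EvidenceFlags = field(default_factory=EvidenceFlags)
    gerp: float = 0.0
    cadd: float = 0.0
    mean_depth: float = 0.0
    impact_overridden: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.alt_freq_pct <= 100.0):
            raise ValueError(f"alt_freq_pct out of [0, 100]: {self.alt_freq_pct}")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(
                f"effect {self.effect!r} not one of {sorted(EFFECT_CLASSES)}"
            )
        if self.impact not in (IMPACT_HIGH_MODERATE, IMPACT_OTHER):
            raise ValueError(f"impact must be high_moderate|other, got {self.impact!r}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) > 1 or len(self.alt) > 1

    @property
    def key(self) -> str:
        return make_index_key(self)


def format_altper(freq_pct: float) -> str:
    """Render a percent frequency for the index key.

    Minimal decimal form with two significant digits, no trailing zeros,
    no exponent, no percent sign: 0.11 -> "0.11", 50.0 -> "50", 0 -> "0".
    """
    if freq_pct < 0 or freq_pct > 100:
        raise ValueError(f"frequency percent out of range: {freq_pct}")
    return np.format_float_positional(
        float(freq_pct), precision=2, unique=False, fractional=False, trim="-"
    )


def _key_chrom_label(chrom: str) -> str:
    # keys always carry a single "chr" prefix regardless of input style
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def make_index_key(v: VariantRecord) -> str:
    """Build the index key joining the variant and genotype tables."""
    if "." in v.gene:
        raise KeyFormatError(
            f"gene symbol {v.gene!r} contains '.', which would break key parsing"
        )
    label = _key_chrom_label(v.chrom)
    if "." in label:
        raise KeyFormatError(f"chromosome label {v.chrom!r} contains '.'")
    return (
        f"chr{label}.pos{v.pos}.ref{v.ref}"
        f".altper{format_altper(v.alt_freq_pct)}.gene{v.gene}"
    )


_KEY_RE = re.compile(
    r"^chr(?P<chrom>[^.]+)"
    r"\.pos(?P<pos>\d+)"
    r"\.ref(?P<ref>[ACGTacgt]+)"
    r"\.altper(?P<freq>\d+(?:\.\d+)?)"
    r"\.gene(?P<gene>[^.]+)$"
)


def parse_index_key(key: str) -> tuple[str, int, str, float, str]:
    """Recover (chrom, pos, ref, alt_freq_pct, gene) from an index key."""
    m = _KEY_RE.match(key)
    if m is None:
        # pinpoint the first token that does not follow the dialect
        for prefix, pat in (
            ("chr", r"^chr[^.]+"),
            ("pos", r"\.pos\d+"),
            ("ref", r"\.ref[ACGTacgt]+"),
            ("altper", r"\.altper\d+(?:\.\d+)?"),
            ("gene", r"\.gene[^.]+$"),
        ):
            if not re.search(pat, key):
                raise KeyFormatError(f"malformed index key {key!r}: bad {prefix} token")
        raise KeyFormatError(f"malformed index key {key!r}")
    freq = float(m.group("freq"))
    if freq > 100.0:
        raise KeyFormatError(f"malformed index key {key!r}: frequency {freq} > 100")
    return (m.group("chrom"), int(m.group("pos")), m.group("ref"), freq, m.group("gene"))


def encode_genotype_iupac(
    ref: str, alt: str, genotype: tuple[str, str] | None
) -> str:
    """Encode a diploid genotype as one character.

    Homozygous genotypes are the base itself; heterozygous SNV genotypes
    use the IUPAC two-base ambiguity code; a missing genotype is ".".
    IUPAC has no code for indels, so indel records use a sentinel that
    preserves the single-column contract: "i" for heterozygous carriers,
    "I" for homozygous alternate, and the first reference base for
    homozygous reference (the exact alleles live in the variant table).
    """
    if genotype is None or any(a is None for a in genotype):
        return MISSING_CODE
    a, b = genotype
    if len(ref) > 1 or len(alt) > 1:  # indel record
        n_alt = (a == alt) + (b == alt)
        if n_alt == 2:
            return "I"
        if n_alt == 1:
            return "i"
        return ref[0]
    for base in (a, b):
        if base not in "ACGT":
            raise ValueError(f"allele {base!r} is not one of A/C/G/T")
    if a == b:
        return a
    return IUPAC_HET[frozenset((a, b))]


def hom_ref_code(v: VariantRecord) -> str:
    return v.ref[0] if v.is_indel else v.ref


def het_code(v: VariantRecord) -> str:
    return "i" if v.is_indel else IUPAC_HET[frozenset((v.ref, v.alt))]


def hom_alt_code(v: VariantRecord) -> str:
    return "I" if v.is_indel else v.alt


@dataclass
class GenotypeMatrix:
    """Participant x variant matrix of single-character genotype codes."""

    participant_ids: list[str]
    variant_keys: list[str]
    codes: np.ndarray  # dtype <U1, shape (n_participants, n_variants)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.participant_ids), len(self.variant_keys)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.participant_ids)} participants x "
                f"{len(self.variant_keys)} variants"
            )
        valid = set("ACGTRYSWKMiI") | {MISSING_CODE}
        bad = set(np.unique(self.codes)) - valid
        if bad:
            raise ValueError(f"invalid genotype codes in matrix: {sorted(bad)}")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column(self, key: str) -> np.ndarray:
        try:
            j = self.variant_keys.index(key)
        except ValueError:
            raise KeyError(f"variant key not in matrix: {key}") from None
        return self.codes[:, j]

    def row(self, participant_id: str) -> np.ndarray:
        try:
            i = self.participant_ids.index(participant_id)
        except ValueError:
            raise KeyError(f"participant not in matrix: {participant_id}") from None
        return self.codes[i, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes,
            index=pd.Index(self.participant_ids, name="participant_id"),
            columns=self.variant_keys,
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(
            participant_ids=list(df.index),
            variant_keys=list(df.columns),
            codes=df.to_numpy(dtype="<U1"),
        )


def carrier_matrix(
    matrix: GenotypeMatrix, variants: Sequence[VariantRecord]
) -> np.ndarray:
    """Boolean participant x variant matrix of minor-allele carriage.

    A participant carries a variant iff their code differs from the
    homozygous-reference code and is not the missing sentinel.
    """
    ref_codes = np.array([hom_ref_code(v) for v in variants], dtype="<U1")
    return (matrix.codes != ref_codes[None, :]) & (matrix.codes != MISSING_CODE)


def dosage_matrix(
    matrix: GenotypeMatrix, variants: Sequence[VariantRecord]
) -> np.ndarray:
    """Integer allele-dose matrix (het = 1, hom-alt = 2, missing = 0)."""
    het = np.array([het_code(v) for v in variants], dtype="<U1")
    hom = np.array([hom_alt_code(v) for v in variants], dtype="<U1")
    return (matrix.codes == het[None, :]).astype(np.int64) + 2 * (
        matrix.codes == hom[None, :]
    ).astype(np.int64)


def _per_alt(value, alt_index: int, n_alts: int):
    """Pick the per-alt element of an INFO value when it is a tuple."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0]
    return value


def _info_flag(info, name: str) -> bool:
    # pysam raises on INFO keys absent from the header; treat as unset
    try:
        return name in info and bool(info[name])
    except ValueError:
        return False


def _parse_evidence(info, alt_index: int, n_alts: int) -> EvidenceFlags:
    def enum_field(name: str, states: tuple[str, ...]) -> str:
        try:
            present = name in info
        except ValueError:
            present = False
        if not present:
            return "absent"
        val = str(_per_alt(info[name], alt_index, n_alts)).lower()
        if val not in states:
            raise VcfContractError(
                f"INFO {name} value {val!r} not one of {states[:-1]}"
            )
        return val

    return EvidenceFlags(
        clinvar_status=enum_field("CLINVAR", CLINVAR_STATES),
        omim_present=_info_flag(info, "OMIM"),
        hgmd_status=enum_field("HGMD", HGMD_STATES),
        prior_clinical_association=_info_flag(info, "PRIOR_CLIN"),
        expert_reviewed_pathogenic=_info_flag(info, "EXPERT_PATH"),
    )


def read_annotated_vcf(
    path: str | Path, config: CohortConfig | None = None
) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read an annotated multi-sample VCF into the two-table model.

    Multi-allelic sites are split into one :class:`VariantRecord` per
    alternate allele before any counting; the frequency denominator covers
    all called alleles at the site (or ``2 x n_participants`` under the
    ``freq_denominator="all"`` policy). Mean depth per variant comes from
    FORMAT DP when present, else INFO MEAN_DP.

    Raises
    ------
    VcfContractError
        If a required annotation field is missing (named, with the record
        coordinates) or a genotype is not diploid.
    """
    config = config or CohortConfig()
    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n_samples = len(samples)
        for rec in vf:
            where = f"{rec.chrom}:{rec.pos}"
            info = rec.info
            for name in REQUIRED_INFO:
                try:
                    present = name in info
                except ValueError:
                    present = False
                if not present:
                    raise VcfContractError(
                        f"missing required annotation field {name} at {where}"
                    )
            alts = rec.alts or ()
            if not alts:
                continue
            n_alts = len(alts)

            gts = []
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    gt = (None, None)
                if len(gt) != 2:
                    raise VcfContractError(
                        f"non-diploid genotype {gt!r} for sample {sample} at {where}"
                    )
                gts.append(gt)

            alleles = [a for gt in gts for a in gt if a is not None]
            called = len(alleles)
            if config.freq_denominator == "called":
                denom = called
            else:
                denom = 2 * n_samples

            if "DP" in rec.format:
                depths = [
                    rec.samples[s].get("DP")
                    for s in samples
                    if rec.samples[s].get("DP") is not None
                ]
                mean_depth = float(np.mean(depths)) if depths else 0.0
            elif "MEAN_DP" in info:
                mean_depth = float(info["MEAN_DP"])
            else:
                raise VcfContractError(
                    f"missing required annotation field MEAN_DP "
                    f"(no FORMAT DP either) at {where}"
                )

            for i, alt in enumerate(alts):
                alt_index = i + 1
                ac = sum(1 for a in alleles if a == alt_index)
                freq_pct = 100.0 * ac / denom if denom else 0.0

                effect = str(_per_alt(info["EFFECT"], i, n_alts))
                impact = str(_per_alt(info["IMPACT"], i, n_alts)).lower()
                if impact not in (IMPACT_HIGH_MODERATE, IMPACT_OTHER):
                    raise VcfContractError(
                        f"INFO IMPACT value {impact!r} at {where} "
                        f"(expected high_moderate|other)"
                    )
                overridden = DEFAULT_IMPACT_MAP.get(effect) not in (None, impact)
                if overridden:
                    log.info(
                        "impact override at %s (%s): source says %s, "
                        "default map says %s",
                        where,
                        effect,
                        impact,
                        DEFAULT_IMPACT_MAP[effect],
                    )

                v = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_freq_pct=freq_pct,
                    gene=str(_per_alt(info["GENE"], i, n_alts)),
                    effect=effect,
                    impact=impact,
                    has_rsid=bool(int(_per_alt(info["RSID_PRESENT"], i, n_alts))),
                    evidence=_parse_evidence(info, i, n_alts),
                    gerp=float(_per_alt(info["GERP"], i, n_alts)),
                    cadd=float(_per_alt(info["CADD"], i, n_alts)),
                    mean_depth=mean_depth,
                    impact_overridden=overridden,
                )
                records.append(v)

                # genotype column relative to (ref, this alt): other alt
                # alleles do not count as carriage of this record
                code_by_dose = (hom_ref_code(v), het_code(v), hom_alt_code(v))
                col = np.empty(n_samples, dtype="<U1")
                for s_i, gt in enumerate(gts):
                    if gt[0] is None or gt[1] is None:
                        col[s_i] = MISSING_CODE
                    else:
                        dose = (gt[0] == alt_index) + (gt[1] == alt_index)
                        col[s_i] = code_by_dose[dose]
                columns.append(col)

    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype="<U1")
    )
    matrix = GenotypeMatrix(
        participant_ids=samples,
        variant_keys=[v.key for v in records],
        codes=codes,
    )
    return records, matrix


def variant_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Variant-level table, one row per record, keyed by the index key."""
    return pd.DataFrame(
        {
            "key": [v.key for v in records],
            "chrom": [v.chrom for v in records],
            "pos": [v.pos for v in records],
            "ref": [v.ref for v in records],
            "alt": [v.alt for v in records],
            "alt_freq_pct": [v.alt_freq_pct for v in records],
            "gene": [v.gene for v in records],
            "effect": [v.effect for v in records],
            "impact": [v.impact for v in records],
            "has_rsid": [v.has_rsid for v in records],
            "clinvar": [v.evidence.clinvar_status for v in records],
            "omim": [v.evidence.omim_present for v in records],
            "hgmd": [v.evidence.hgmd_status for v in records],
            "prior_clin": [v.evidence.prior_clinical_association for v in records],
            "expert_path": [v.evidence.expert_reviewed_pathogenic for v in records],
            "gerp": [v.gerp for v in records],
            "cadd": [v.cadd for v in records],
            "mean_depth": [v.mean_depth for v in records],
            "impact_overridden": [v.impact_overridden for v in records],
        }
    )


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    variant_table(records).to_csv(path, sep="\t", index=False)
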