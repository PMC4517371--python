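"""Cohort- and variant-level summary reports.

Demographic summaries are tabulated by self-reported sex with a combined
column, categorical cells rendered as "percent %(count)". Variant
summaries cross-tabulate effect class by impact, list evidence-source and
per-gene counts, and report (25th, 50th, 75th) quantiles for mean depth,
GERP and CADD. Quantiles use linear interpolation between closest order
statistics; percentages are rounded half-away-from-zero to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import EFFECT_CLASSES, IMPACT_HIGH_MODERATE, IMPACT_OTHER
from .ehr_features import DX_FLAGS, HISPANIC, LAB_ASSAYS, ParticipantEHR, RACES, compute_lab_flags
from .ranking import ParticipantScore
from .variant_store import VariantRecord

_RACE_LABELS = {
    "american_indian_alaska_native": "American Indian or Alaska Native",
    "asian": "Asian",
    "black_african_american": "Black or African American",
    "native_hawaiian_pacific_islander": "Native Hawaiian or other Pacific Islander",
    "unknown": "Unknown",
    "white": "White",
}
_DX_LABELS = {
    "malignant_hyperthermia": "Hx of Malignant Hyperthermia",
    "lqts": "Hx of LQTS",
    "hypertension": "Hx of Hypertension",
    "arrhythmia": "Hx of Arrhythmia",
    "atrial_fibrillation": "Hx of AF",
    "chf": "Hx of CHF",
}


def pct_round(count: int, total: int) -> int:
    """Integer percent, rounded half away from zero."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def _fmt_cell(count: int, total: int) -> str:
    return f"{pct_round(count, total)} %({count})"


@dataclass
class CohortSummary:
    """Demographic-side summary: formatted table plus raw counts."""

    table: pd.DataFrame  # formatted strings; columns Female/Male/Combined
    counts: pd.DataFrame  # integer counts, same shape minus mean rows
    n_by_column: dict[str, int]

    def render(self) -> str:
        head = "  ".join(
            f"{col} (N={self.n_by_column[col]})" for col in self.table.columns
        )
        return f"{head}\n{self.table.to_string()}\n"


def summarize_cohort(
    ehr: Sequence[ParticipantEHR],
    scores: Sequence[ParticipantScore] | None = None,
) -> CohortSummary:
    """Tabulate race/ethnicity/diagnosis/lab-flag composition by sex.

    When participant scores are supplied, mean +/- SD rows for the three
    count statistics are appended (one decimal, as printed in cohort
    reports).
    """
    if not ehr:
        raise ValueError("cannot summarize an empty cohort")
    groups = {
        "Female": [p for p in ehr if p.sex == "female"],
        "Male": [p for p in ehr if p.sex == "male"],
        "Combined": list(ehr),
    }
    n_by_col = {col: len(ps) for col, ps in groups.items()}

    count_rows: dict[str, dict[str, int]] = {}

    def add_row(label: str, pred) -> None:
        count_rows[label] = {
            col: sum(1 for p in ps if pred(p)) for col, ps in groups.items()
        }

    for race in RACES:
        add_row(_RACE_LABELS[race], lambda p, r=race: p.race == r)
    for hisp in ("no", "yes", "unknown"):
        add_row(f"Ethnicity: {hisp.capitalize()}", lambda p, h=hisp: p.hispanic == h)
    for dx in ("lqts", "hypertension", "arrhythmia", "atrial_fibrillation", "chf",
               "malignant_hyperthermia"):
        add_row(_DX_LABELS[dx], lambda p, d=dx: d in p.dx)

    flags_by_id = {p.participant_id: compute_lab_flags(p) for p in ehr}
    for assay in LAB_ASSAYS:
        add_row(
            f"Median {assay} flag",
            lambda p, a=assay: flags_by_id[p.participant_id].as_dict()[a] == 1,
        )

    counts = pd.DataFrame(count_rows).T[["Female", "Male", "Combined"]]
    counts.index.name = "row"
    formatted = counts.copy().astype(object)
    for col in formatted.columns:
        formatted[col] = [
            _fmt_cell(int(c), n_by_col[col]) for c in counts[col]
        ]

    if scores is not None:
        sex_by_id = {p.participant_id: p.sex for p in ehr}
        stat_names = {
            "Total PGx Variants (total variants)": "total_variants",
            "Coding PGx Variants (coding variants)": "coding_variants",
            "Group Health PGx Variants (gh variants)": "gh_variants",
        }
        for label, attr in stat_names.items():
            row = {}
            for col, _ in groups.items():
                if col == "Combined":
                    vals = [getattr(s, attr) for s in scores]
                else:
                    want = "female" if col == "Female" else "male"
                    vals = [
                        getattr(s, attr)
                        for s in scores
                        if sex_by_id.get(s.participant_id) == want
                    ]
                if vals:
                    arr = np.asarray(vals, dtype=float)
                    row[col] = f"{arr.mean():.1f}±{arr.std(ddof=1) if len(arr) > 1 else 0.0:.1f}"
                else:
                    row[col] = "-"
            formatted.loc[label] = row

    return CohortSummary(table=formatted, counts=counts, n_by_column=n_by_col)


@dataclass
class VariantSummary:
    """Variant-side summary: effect x impact cross-tab, evidence rows,
    per-gene rows, and quantile rows for depth/GERP/CADD."""

    table: pd.DataFrame  # formatted strings; columns Other/High-Moderate/Combined
    counts: pd.DataFrame
    quartiles: pd.DataFrame  # rows depth/GERP/CADD, cols q25/q50/q75 per class
    n_by_column: dict[str, int]

    def render(self) -> str:
        head = "  ".join(
            f"{col} (N={self.n_by_column[col]})" for col in self.table.columns
        )
        quart = self.quartiles.to_string(float_format=lambda x: f"{x:.2f}")
        return (
            f"{head}\n{self.table.to_string()}\n\n"
            f"Quartiles (25th/50th/75th, linear interpolation):\n{quart}\n"
        )


def summarize_variants(variants: Sequence[VariantRecord]) -> VariantSummary:
    """Cross-tabulate the variant table by effect class and impact."""
    if not variants:
        raise ValueError("cannot summarize an empty variant table")
    groups = {
        "Other": [v for v in variants if v.impact == IMPACT_OTHER],
        "High/Moderate": [v for v in variants if v.impact == IMPACT_HIGH_MODERATE],
        "Combined": list(variants),
    }
    n_by_col = {col: len(vs) for col, vs in groups.items()}

    count_rows: dict[str, dict[str, int]] = {}

    def add_row(label: str, pred) -> None:
        count_rows[label] = {
            col: sum(1 for v in vs if pred(v)) for col, vs in groups.items()
        }

    for effect in EFFECT_CLASSES:
        add_row(effect, lambda v, e=effect: v.effect == e)
    add_row("Prior rsID", lambda v: v.has_rsid)
    add_row("Prior Clinical Association", lambda v: v.evidence.prior_clinical_association)
    add_row("OMIM", lambda v: v.evidence.omim_present)
    add_row("ClinVar", lambda v: v.evidence.clinvar_status != "absent")
    add_row("HGMD", lambda v: v.evidence.hgmd_status != "absent")
    for gene in sorted({v.gene for v in variants}):
        add_row(gene, lambda v, g=gene: v.gene == g)

    counts = pd.DataFrame(count_rows).T[["Other", "High/Moderate", "Combined"]]
    counts.index.name = "row"
    formatted = counts.copy().astype(object)
    for col in formatted.columns:
        formatted[col] = [_fmt_cell(int(c), n_by_col[col]) for c in counts[col]]

    quart_rows = {}
    for label, attr in (
        ("Average Depth", "mean_depth"),
        ("GERP", "gerp"),
        ("CADD", "cadd"),
    ):
        row = {}
        for col, vs in groups.items():
            vals = np.array([getattr(v, attr) for v in vs], dtype=float)
            if len(vals):
                q = np.percentile(vals, [25, 50, 75])  # linear interpolation
            else:
                q = (float("nan"),) * 3
            row[f"{col} q25"], row[f"{col} q50"], row[f"{col} q75"] = (
                float(q[0]),
                float(q[1]),
                float(q[2]),
            )
        quart_rows[label] = row
    quartiles = pd.DataFrame(quart_rows).T

    return VariantSummary(
        table=formatted, counts=counts, quartiles=quartiles, n_by_column=n_by_col
    )
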