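# Methods

This note documents the models, conventions and design choices behind
`pgxrank`, in the order the pipeline runs.

## Data model and index keys

The pipeline keeps two tables joined by a string index key,
`chr{chrom}.pos{pos}.ref{ref}.altper{freq}.gene{gene}`. Conventions:

- Coordinates are 1-based, as in VCF; no conversion happens anywhere.
- Chromosome labels are kept verbatim from the input except inside the
  key, which always carries a single `chr` prefix (an input `chr7` is
  not doubled).
- The frequency token is the cohort alternate-allele frequency in
  percent, rendered with two significant digits, no trailing zeros and
  no exponent (`0.11`, `50`, `100`). Parsing accepts any decimal. A key
  therefore round-trips exactly when the stored frequency is already in
  this canonical form; re-keying after re-reading a cohort is stable
  because frequencies are recomputed the same way.
- Gene symbols containing `.` are rejected at key-construction time —
  they would be unparseable. Hyphens (`HLA-B`) are fine.

Multi-allelic sites are split into one record per alternate allele
*before* any counting. The frequency denominator covers all called
alleles at the site; missing genotypes are excluded from the
denominator. A config switch (`freq_denominator="all"`) uses
2 × n_participants instead, because the upstream convention behind
published percent frequencies is not always knowable.

## Genotype encoding

Diploid genotypes live in one character per participant per variant:
the base itself for homozygotes, the standard IUPAC two-base ambiguity
code for heterozygous SNVs (R/Y/S/W/K/M), `.` for missing. IUPAC has no
indel codes, so indel records use `i` (het) / `I` (hom-alt) / first
reference base (hom-ref) as sentinels; the exact alleles remain in the
variant table. For a split multi-allelic record, the column encodes the
allele count of *that* alternate only; a second alternate allele at the
site is treated as reference in that column, which keeps per-record
carrier semantics exact.

A participant *carries* a variant iff their code differs from the
homozygous-reference code and is not missing.

## Impact and evidence

The default effect → impact map sends missense, missense-near-splice,
splice-acceptor, splice-donor and stop-gained to `high_moderate` and
the remaining seven effect classes to `other`. When the input VCF's
IMPACT field disagrees with the map, the annotation source is
authoritative; the disagreement is recorded on the record
(`impact_overridden`) and logged, since upstream annotators legitimately
downgrade individual missense calls.

"Prior clinical evidence of pathogenicity" — used both for the
GH-priority designation and the re-consent report — means: ClinVar
pathogenic/likely-pathogenic, or HGMD disease-causing or
frameshift/truncating, or expert-reviewed pathogenic. OMIM presence
alone is tracked but is deliberately not pathogenicity evidence. A
variant is GH-priority iff its gene is in the six-gene set and it
either has such evidence or is annotated stop-gained.

## Lab flags and selection rules

Each assay's flag fires iff the participant's **median** over repeated
measures strictly exceeds the threshold (LDL 155 mg/dL, TG 288 mg/dL,
CK 174 IU/L, TSH 4 µg/dL, INR 1.5); boundary values do not flag, and an
assay with no data contributes 0. Even-length medians take the midpoint
of the central order statistics. The flag thresholds mirror the
observed 90th percentiles of the source cohort's distributions.

The CK + statin selection rule is distinct from the CK *flag*: it fires
on any single CK event > 1000 IU/L with a statin dispensing within 183
days in either direction. The window is symmetric because no direction
is clinically implied; both the threshold and the window are
configurable. The CK flag (174 IU/L, median-based) does not feed
selection.

Medication exclusions: any carbamazepine record ever, or an explicit
current-regimen warfarin record. "Current regimen" is modeled as a
record kind rather than inferred from dispensing recency; an optional
recency heuristic (dispensing within N days of an index date) exists
but is off by default because no recency rule is defensible a priori.
Exclusion is evaluated before inclusion and always wins — the
clinically conservative order.

Race-based prioritization (self-reported Asian or Black/African
American) appears both as a selection inclusion rule and as the tier-1
criterion of the ranking; each is independently configurable because
workflows differ in where they apply the enrichment. The age-50–65
eligibility screen happens upstream at enrollment, so it is only an
optional pre-filter here, off by default.

## Ranking

Tier 1 contains participants whose self-reported race is neither white
nor unknown, or who have an LQTS diagnosis; *unknown race is never
tier 1*, since absence of information is not evidence of ancestry.
Within both tiers the sort keys are descending gh variants, coding
variants, total variants, then the lab-flag sum, with ascending
participant id as the final tie-break; the ranking is therefore a total
order, immune to input shuffling. The position of the lab-flag sum
among the keys is configurable (its exact place in the original
workflow is not documented); so is using `gh_priority_variants` (the
prior-evidence/stop-gain subset) as the leading key instead of all
six-gene sites. The default reads "gh variants" as *all* minor-allele
sites in the six genes, which matches the magnitude of the published
per-participant mean (~39).

Counting defaults to carrier counting (sites with ≥ 1 minor allele); an
allele-dose mode (het = 1, hom-alt = 2) is selectable.

## Synthetic cohort generator

The generator emulates the source cohort's published structure:

- **Demographics / diagnoses:** categorical draws with the published
  proportions (e.g. 61 % female, 84 % white, 8 % Asian; hypertension
  79 %, arrhythmia 50 %, AF 10 %, CHF 2 %, LQTS 2/894). Malignant
  hyperthermia is not tabulated there; prevalence defaults to 0.2 %.
  Diagnoses are drawn independently of each other and of sex.
- **Variants:** the 27-gene panel allocates sites per gene
  proportionally to the published per-gene loads (seven genes,
  including *HLA-B*, carry none); effect classes follow the published
  12-class mix; GERP/CADD/depth are drawn from normals matched to the
  published quartiles by impact class.
- **Genotypes:** per-site Hardy-Weinberg draws from a mixture frequency
  model (90 % rare Beta(0.3, 30), 10 % common Uniform(0.01, 0.5)),
  independent sites, no linkage disequilibrium — the pipeline never
  exploits LD, so the simplest exchangeable model suffices.
- **Labs:** per-assay lognormal participant levels pinned by (median,
  p90) with the p90 at the flag threshold, small multiplicative
  measurement noise (5 % of the between-participant log spread), and
  1 + Poisson(2) repeats over a fixed ten-year calendar. This makes
  ~10 % of participants flag per assay by construction.
- **Evidence:** annotation probabilities conditional on impact class,
  matched to the published variant-level table (~18 % of high/moderate
  variants with a prior clinical association, ~30 % with HGMD entries,
  ~3 % ClinVar; much lower rates for other-impact variants).
- **Medications:** 30 % statin users, 1 % carbamazepine, 2 % current
  warfarin; the CK>1000 + statin co-occurrence is an explicit knob
  (default 0.5 %) that injects a qualifying event pair.

Every latent quantity is written to truth tables, so pipeline counts
can be checked exactly, end to end, through the file formats.

### Calibration

`calibrate_total_variants` solves, in closed form, for the global
frequency scale s such that
n_sites · (1 − miss) · (2 s m1 − s² m2) = target, where (m1, m2) are
the mixture's first two moments. The smaller quadratic root is taken
(the expectation is increasing there); the target is infeasible when it
exceeds n_sites · m1²/m2 or would push common frequencies above 1. The
default target, 75.2 carriers over the full 1,785-site panel, matches
the published cohort mean.

Note the calibration fixes the *expectation over frequency draws*: a
single simulated panel realizes 1,785 random frequencies, and the
cohort mean inherits that Monte Carlo spread (SD ≈ 4 at full panel
size). Tests and the acceptance script therefore judge the mean against
the site-level standard error (the spread of per-site carrier fractions
× √n_sites), or average over several independently drawn panels.

### What the generator does not emulate

No haplotype or LD structure, no population stratification (counts do
not differ by simulated ancestry, unlike real cohorts), no star-allele
diplotypes, no structural variants, and no frequency–pathogenicity
correlation: evidence flags are independent of allele frequency, so
common synthetic variants can carry pathogenic annotations and the
fraction of participants with re-consent-grade evidence is far higher
than in real panels. The per-participant count SD (~8) is also smaller
than published (~15) because real between-participant overdispersion
(ancestry, platform) is absent. Passing tests therefore demonstrate
pipeline correctness and calibration of the stated marginals — not
realism of joint structure.

## Numerical conventions

- Quantiles: linear interpolation between closest order statistics
  (NumPy default), stated in report footers.
- Percentages in reports: rounded half-away-from-zero to integers.
- Mean ± SD rows: one decimal, sample SD (ddof = 1).
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs give byte-identical
  output files (floats are written with fixed formats).

## Problem sizes used in the test suite

The suite exercises 50 seeded cohorts of 100 participants × 500
variants for the end-to-end count oracle, 10,000 participants for lab
and Hardy-Weinberg checks, a 5,000-variant panel for the effect-mix
goodness of fit, and 1,000 participants at the full 1,785-site panel
for the calibration check — sizes chosen so each statistical assertion
has the power its tolerance needs while the whole suite stays quick on
one CPU.
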