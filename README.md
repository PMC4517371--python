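# pgxrank

Prospective participant selection and ranking for pharmacogenetic (PGx)
return-of-results programs.

## The problem

A biobank has sequenced a cohort on a targeted pharmacogene panel using
non-CLIA samples, and can afford to re-consent, redraw and CLIA-validate
only a subset before returning results to the electronic health record
(EHR). Which participants should be recontacted first? `pgxrank`
implements a reproducible answer: a rule-based **selection algorithm**
over EHR phenotype data and a deterministic **tiered ranking** over
per-participant variant counts, for a 27-gene actionable panel
(CPIC-actionable pharmacogenes plus disease genes of site interest).

It is written for informatics teams running return-of-results pilots and
for methodologists who want a tested, end-to-end reference pipeline from
an annotated multi-sample VCF plus EHR tables to a recontact list.

## The model

**Relational data model.** The annotated VCF is split into a
variant-level table (one row per site × alternate allele) and a
participant-level genotype table whose columns hold single-character
IUPAC genotype codes (e.g. `R` = A/G heterozygote, `.` = missing). The
two are joined by a human-readable index key:

```
chr{chrom}.pos{pos}.ref{ref}.altper{freq}.gene{gene}
e.g. chr1.pos237754201.refG.altper0.11.geneRYR2
```

meaning chromosome 1, position 237 754 201, reference G, cohort
alternate-allele frequency 0.11 %, gene *RYR2*. The key round-trips
losslessly through the parser.

**Selection.** Four EHR data sources drive inclusion: self-reported
Asian or African ancestry (to enrich for non-European variation);
diagnosis history of malignant hyperthermia, long QT syndrome (LQTS),
atrial fibrillation, arrhythmia, CHF or hypertension; and any creatine
kinase event > 1000 IU/L with a statin dispensed within 6 months
(possible statin myopathy). Medication history only excludes:
carbamazepine ever, or a current warfarin regimen. Exclusion is
evaluated first and overrides inclusion.

**Ranking.** For each participant over the 27-gene panel:
*total variants* = sites carrying a minor allele; *coding variants* =
the high/moderate-impact subset (missense, missense-near-splice,
splice-acceptor/donor, stop-gained); *gh variants* = the subset in the
six genes prioritized for EHR return (*CACNA1S*, *RYR1* — malignant
hyperthermia; *SCN5A*, *KCNH2*, *RYR2* — arrhythmia; *LDLR* — high
cholesterol). Five lab flags (median LDL > 155 mg/dL, triglycerides
> 288 mg/dL, CK > 174 IU/L, TSH > 4 µg/dL, INR > 1.5) are summed into a
fourth key. Tier 1 (non-European self-identified race or LQTS) ranks
first; within tiers the sort is descending (gh, coding, total,
flag sum), tie-broken by participant id, so the ranking is a total
order and fully reproducible.

**Synthetic cohorts.** Because the original study data are
controlled-access, a seeded generator produces linked cohorts (annotated
VCF + EHR tables + latent truth tables) with the published cohort
structure: race mix, diagnosis prevalences, effect-class proportions,
Hardy-Weinberg genotypes, and lab distributions whose 90th percentiles
sit at the flag thresholds. `calibrate_total_variants` rescales the
allele-frequency model in closed form so the expected per-participant
carrier count hits a chosen mean (default target 75.2).

## Worked example

```bash
pgxrank simulate --seed 7 --n 100 --n-variants 300 --calibrate-mean 12 --out demo
pgxrank select   --ehr demo/ehr --out demo/decisions.tsv
pgxrank rank     --vcf demo/cohort.vcf --ehr demo/ehr --top 5 --out demo/rank
```

prints

```
wrote demo/cohort.vcf and EHR/truth tables under demo
100 participants: 90 eligible, 4 excluded -> demo/decisions.tsv
ranked 96 participants (4 excluded) -> demo/rank/ranking.tsv; top 5 -> demo/rank/recontact.tsv
```

and `demo/rank/recontact.tsv` holds the five top-ranked participants:

```
rank  tier  participant_id  gh_variants  gh_priority_variants  coding_variants  total_variants  lab_flag_sum
1     1     P00020          10           2                     4                16              1
2     1     P00071          9            1                     1                12              0
3     1     P00083          8            1                     2                14              0
4     1     P00047          7            2                     3                16              1
5     1     P00092          7            0                     2                14              0
```

All five are tier 1 — participants of self-reported non-European
ancestry or with an LQTS history come first regardless of counts — and
within the tier they are ordered by descending gh / coding / total
counts. Four participants were dropped before ranking because of the
medication exclusions. The same library calls are available in Python
(`pgxrank.simulate_cohort`, `pgxrank.select_participants`,
`pgxrank.score_cohort`, `pgxrank.rank_participants`).

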