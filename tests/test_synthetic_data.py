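"""Synthetic cohort generator: determinism, Hardy-Weinberg, calibration."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from pgxrank.synthetic_data import (
    EFFECT_COUNTS,
    GeneSpec,
    SimConfig,
    calibrate_total_variants,
    default_gene_panel,
    expected_total_variants,
    simulate_arrays,
    simulate_cohort,
)


def small_cfg(**kwargs):
    defaults = dict(n_participants=40, seed=123, gene_panel=default_gene_panel(120))
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestPanel:
    def test_default_panel_covers_27_genes(self):
        panel = default_gene_panel()
        assert len(panel) == 27
        assert sum(g.n_variants for g in panel) == 1785

    def test_scaling_preserves_total_and_zero_genes(self):
        panel = default_gene_panel(500)
        assert sum(g.n_variants for g in panel) == 500
        zero_genes = {g.gene for g in panel if g.n_variants == 0}
        assert {"HLA-B", "CFTR", "G6PD"} <= zero_genes

    def test_zero_variant_panel_is_infeasible(self):
        empty = (GeneSpec("RYR2", "1", 100, 200, 0),)
        with pytest.raises(ValueError, match="infeasible"):
            SimConfig(n_participants=5, gene_panel=empty)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_cfg()
        p1 = simulate_cohort(cfg, tmp_path / "a")
        p2 = simulate_cohort(cfg, tmp_path / "b")
        for name in ("vcf",):
            assert p1[name].read_bytes() == p2[name].read_bytes()
        for sub in ("ehr", "truth"):
            for f1 in sorted(Path(p1[sub]).iterdir()):
                f2 = Path(p2[sub]) / f1.name
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_different_seeds_differ(self, tmp_path):
        p1 = simulate_cohort(small_cfg(seed=1), tmp_path / "a")
        p2 = simulate_cohort(small_cfg(seed=2), tmp_path / "b")
        assert p1["vcf"].read_bytes() != p2["vcf"].read_bytes()


class TestDegenerateSettings:
    def test_zero_frequency_means_all_homozygous_reference(self):
        model = dataclasses.replace(SimConfig().allele_freq_model, scale=0.0)
        cohort = simulate_arrays(small_cfg(allele_freq_model=model))
        assert (cohort.dosage == 0).all()
        assert (cohort.truth_scores.total_variants == 0).all()

    def test_prevalence_one_flags_every_participant(self):
        prev = dict(SimConfig().dx_prevalence)
        prev["hypertension"] = 1.0
        cohort = simulate_arrays(small_cfg(dx_prevalence=prev))
        assert all("hypertension" in p.dx for p in cohort.ehr)


class TestHardyWeinberg:
    def test_genotype_frequencies_match_expectation(self):
        """At n = 10,000 participants, per-site genotype counts follow
        p^2 / 2pq / q^2 within binomial sampling error (chi-square)."""
        panel = (GeneSpec("RYR2", "1", 237205702, 237997288, 5),)
        model = dataclasses.replace(
            SimConfig().allele_freq_model, w_common=1.0, uniform_low=0.1, uniform_high=0.4
        )
        cfg = SimConfig(
            n_participants=10_000, seed=5, gene_panel=panel,
            allele_freq_model=model, missing_rate=0.0,
        )
        cohort = simulate_arrays(cfg)
        for j, v in enumerate(cohort.variants):
            p = v.alt_freq_pct / 100.0
            dose = cohort.dosage[:, j]
            observed = np.bincount(dose, minlength=3)
            # expected counts from the realized allele frequency
            expected = 10_000 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((observed - expected) ** 2 / expected).sum()
            assert stats.chi2.sf(chi2, df=1) > 1e-4


class TestEffectMix:
    def test_effect_class_mix_converges(self):
        """Chi-square goodness of fit not rejected at alpha = 0.01 for a
        5,000-variant panel."""
        cfg = SimConfig(n_participants=2, seed=9, gene_panel=default_gene_panel(5000))
        cohort = simulate_arrays(cfg)
        effects = [v.effect for v in cohort.variants]
        total = sum(EFFECT_COUNTS.values())
        labels = sorted(EFFECT_COUNTS)
        observed = np.array([effects.count(e) for e in labels])
        expected = np.array([5000 * EFFECT_COUNTS[e] / total for e in labels])
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.01


class TestCalibration:
    def test_conditional_expectation_matches_simulation(self):
        """Given the realized site frequencies, the mean carrier count
        matches sum_j (1 - (1 - p_j)^2) within sampling error."""
        cfg = small_cfg(n_participants=4000, seed=21)
        cohort = simulate_arrays(cfg)
        mean = cohort.truth_scores.total_variants.mean()
        se = cohort.truth_scores.total_variants.std(ddof=1) / np.sqrt(4000)
        conditional = (1 - cfg.missing_rate) * (1 - (1 - cohort.freqs) ** 2).sum()
        assert abs(mean - conditional) < 4 * se

    def test_closed_form_moments_match_monte_carlo(self):
        """The closed-form per-site carrier probability 2 s m1 - s^2 m2
        agrees with a direct draw from the frequency model."""
        model = SimConfig().allele_freq_model
        rng = np.random.default_rng(17)
        p = model.draw(rng, 400_000)
        q = 1 - (1 - p) ** 2
        m1, m2 = model.moments()
        s = model.scale
        mc_se = q.std(ddof=1) / np.sqrt(len(q))
        assert abs(q.mean() - (2 * s * m1 - s * s * m2)) < 4 * mc_se

    def test_calibration_hits_target_expectation(self):
        cfg = small_cfg()
        cal = calibrate_total_variants(cfg, 5.0)
        assert expected_total_variants(cal) == pytest.approx(5.0, rel=1e-6)

    def test_fixed_point_leaves_config_unchanged(self):
        cfg = small_cfg()
        current = expected_total_variants(cfg)
        cal = calibrate_total_variants(cfg, current)
        assert cal.allele_freq_model.scale == pytest.approx(
            cfg.allele_freq_model.scale, rel=1e-9
        )

    def test_doubling_scale_doubles_expectation_in_rare_regime(self):
        model = dataclasses.replace(
            SimConfig().allele_freq_model, w_common=0.0, scale=0.05
        )
        cfg = small_cfg(allele_freq_model=model)
        doubled = dataclasses.replace(
            cfg,
            allele_freq_model=dataclasses.replace(model, scale=0.1),
        )
        ratio = expected_total_variants(doubled) / expected_total_variants(cfg)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_unattainable_target_is_hard_error(self):
        cfg = small_cfg()  # 120 sites cannot average 500 carriers
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_total_variants(cfg, 500.0)


class TestTruthTables:
    def test_truth_counts_match_pipeline_end_to_end(self, tmp_path):
        """The generator's latent truth equals the pipeline's own counts
        after a full write/read cycle."""
        import pandas as pd

        from pgxrank.ehr_features import load_ehr_tables
        from pgxrank.ranking import score_cohort
        from pgxrank.variant_store import read_annotated_vcf

        paths = simulate_cohort(small_cfg(seed=77), tmp_path)
        variants, matrix = read_annotated_vcf(paths["vcf"])
        ehr = load_ehr_tables(paths["ehr"])
        scores = score_cohort(matrix, variants, ehr=ehr)
        truth = pd.read_csv(paths["truth"] / "participant_scores.tsv", sep="\t")
        for s, row in zip(scores, truth.itertuples(index=False)):
            assert s.participant_id == row.participant_id
            assert s.total_variants == row.total_variants
            assert s.coding_variants == row.coding_variants
            assert s.gh_variants == row.gh_variants
            assert s.gh_priority_variants == row.gh_priority_variants

    def test_truth_lab_flags_match_ehr_features(self, tmp_path):
        import pandas as pd

        from pgxrank.ehr_features import compute_lab_flags, load_ehr_tables

        paths = simulate_cohort(small_cfg(seed=78), tmp_path)
        ehr = load_ehr_tables(paths["ehr"])
        truth = pd.read_csv(paths["truth"] / "lab_flags.tsv", sep="\t")
        for p, row in zip(ehr, truth.itertuples(index=False)):
            flags = compute_lab_flags(p)
            assert p.participant_id == row.participant_id
            assert flags.flag_sum == row.flag_sum


class TestVcfOutputContract:
    def test_written_vcf_parses_with_standard_tools(self, tmp_path):
        import pysam

        paths = simulate_cohort(small_cfg(), tmp_path)
        with pysam.VariantFile(str(paths["vcf"])) as vf:
            recs = list(vf)
        assert len(recs) == 120
        assert all(len(r.alts) == 1 for r in recs)
        # sorted by contig then position
        seen = [(r.chrom, r.pos) for r in recs]
        by_contig: dict[str, list[int]] = {}
        for chrom, pos in seen:
            by_contig.setdefault(chrom, []).append(pos)
        for positions in by_contig.values():
            assert positions == sorted(positions)
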