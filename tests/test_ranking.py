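"""Variant counting and the deterministic tiered ranking."""

import random

import numpy as np
import pytest

from pgxrank.annotation import EvidenceFlags
from pgxrank.config import CohortConfig
from pgxrank.ranking import (
    ParticipantScore,
    count_variants,
    rank_participants,
    score_cohort,
    take_top,
)
from pgxrank.variant_store import GenotypeMatrix, het_code, hom_ref_code

from conftest import make_participant, make_variant


def _three_site_fixture():
    variants = [
        make_variant(pos=1, ref="A", alt="G", gene="RYR1", effect="stop-gained",
                     impact="high_moderate"),
        make_variant(pos=2, ref="C", alt="T", gene="CYP2D6", effect="missense",
                     impact="high_moderate"),
        make_variant(pos=3, ref="A", alt="C", gene="ABCA1", effect="intron",
                     impact="other"),
    ]
    return variants


class TestCountVariants:
    def test_all_homozygous_reference_counts_zero(self):
        variants = _three_site_fixture()
        codes = np.array([hom_ref_code(v) for v in variants])
        s = count_variants(codes, variants)
        assert (s.total_variants, s.coding_variants, s.gh_variants,
                s.gh_priority_variants) == (0, 0, 0, 0)

    def test_three_heterozygous_sites_hand_count(self):
        """Het at RYR1 stop-gained, CYP2D6 missense, ABCA1 intron:
        total 3, coding 2, gh 1, gh-priority 1 (the RYR1 stop-gain)."""
        variants = _three_site_fixture()
        codes = np.array([het_code(v) for v in variants])
        s = count_variants(codes, variants)
        assert (s.total_variants, s.coding_variants, s.gh_variants,
                s.gh_priority_variants) == (3, 2, 1, 1)

    def test_dose_mode_counts_hom_alt_twice(self):
        variants = [make_variant(pos=1, ref="A", alt="G", gene="ABCA1")]
        hom_alt = np.array(["G"])
        carrier = count_variants(hom_alt, variants)
        dose = count_variants(hom_alt, variants, CohortConfig(counting_mode="dose"))
        assert carrier.total_variants == 1
        assert dose.total_variants == 2

    def test_gene_outside_panel_is_hard_error(self):
        v = make_variant(gene="BRCA1")
        with pytest.raises(ValueError, match="BRCA1"):
            count_variants(np.array(["R"]), [v])

    def test_matches_brute_force_loop(self):
        """Vectorized counts equal an independent per-site loop on a small
        random cohort."""
        rng = np.random.default_rng(42)
        genes = ["RYR1", "RYR2", "CYP2D6", "ABCA1", "LDLR"]
        effects = ["missense", "intron", "stop-gained", "synonymous"]
        variants = []
        for j in range(50):
            effect = effects[rng.integers(len(effects))]
            variants.append(
                make_variant(
                    pos=j + 1, ref="A", alt="G", gene=genes[rng.integers(len(genes))],
                    effect=effect,
                    impact="high_moderate" if effect in ("missense", "stop-gained") else "other",
                    evidence=EvidenceFlags(
                        clinvar_status="pathogenic" if rng.random() < 0.2 else "absent"
                    ),
                )
            )
        pids = [f"P{i:02d}" for i in range(20)]
        pool = np.array(["A", "R", "G", "."])
        codes = pool[rng.integers(0, 4, size=(20, 50))]
        matrix = GenotypeMatrix(pids, [v.key for v in variants], codes)
        scores = score_cohort(matrix, variants)

        from pgxrank.annotation import is_gh_priority
        from pgxrank.config import GH_GENES

        for i, s in enumerate(scores):
            total = coding = gh = ghp = 0
            for j, v in enumerate(variants):
                code = codes[i, j]
                if code in (".", "A"):
                    continue
                total += 1
                coding += v.impact == "high_moderate"
                gh += v.gene in GH_GENES
                ghp += is_gh_priority(v)
            assert (s.total_variants, s.coding_variants, s.gh_variants,
                    s.gh_priority_variants) == (total, coding, gh, ghp)

    def test_count_invariants_hold(self):
        rng = np.random.default_rng(3)
        variants = _three_site_fixture()
        pool = np.array(["A", "R", "G"])
        for _ in range(20):
            codes = np.array(
                [pool[rng.integers(0, 3)] if v.ref == "A" else
                 np.random.default_rng(1).choice(["C", "Y", "T"]) for v in variants]
            )
            s = count_variants(codes, variants)
            assert s.coding_variants <= s.total_variants
            assert s.gh_variants <= s.total_variants
            assert s.gh_priority_variants <= s.gh_variants


def _score(pid, gh=0, coding=0, total=0, flags=0):
    return ParticipantScore(
        participant_id=pid, total_variants=total, coding_variants=min(coding, total),
        gh_variants=min(gh, total), gh_priority_variants=0, lab_flag_sum=flags,
    )


class TestRankParticipants:
    def test_primary_key_descending_gh(self):
        scores = [_score("A", gh=38, coding=10, total=70),
                  _score("B", gh=40, coding=10, total=70)]
        ehr = [make_participant("A"), make_participant("B")]
        ranked = rank_participants(scores, ehr)
        assert [s.participant_id for s in ranked] == ["B", "A"]

    def test_tertiary_key_total(self):
        scores = [_score("A", gh=10, coding=5, total=70),
                  _score("B", gh=10, coding=5, total=80)]
        ehr = [make_participant("A"), make_participant("B")]
        assert [s.participant_id for s in rank_participants(scores, ehr)] == ["B", "A"]

    def test_lab_flags_break_count_ties(self):
        scores = [_score("A", gh=10, coding=5, total=70, flags=0),
                  _score("B", gh=10, coding=5, total=70, flags=3)]
        ehr = [make_participant("A"), make_participant("B")]
        assert [s.participant_id for s in rank_participants(scores, ehr)] == ["B", "A"]

    def test_full_tie_breaks_by_participant_id(self):
        scores = [_score("B", gh=10, coding=5, total=70),
                  _score("A", gh=10, coding=5, total=70)]
        ehr = [make_participant("A"), make_participant("B")]
        assert [s.participant_id for s in rank_participants(scores, ehr)] == ["A", "B"]

    def test_tier1_non_european_precedes_higher_counts(self):
        scores = [_score("A", gh=100, coding=50, total=200),
                  _score("B", gh=0, coding=0, total=0)]
        ehr = [make_participant("A", race="white"),
               make_participant("B", race="asian")]
        ranked = rank_participants(scores, ehr)
        assert [s.participant_id for s in ranked] == ["B", "A"]
        assert ranked[0].tier == 1 and ranked[1].tier == 2

    def test_lqts_is_tier1(self):
        scores = [_score("A", gh=100, total=200), _score("B")]
        ehr = [make_participant("A"), make_participant("B", dx=frozenset({"lqts"}))]
        assert rank_participants(scores, ehr)[0].participant_id == "B"

    def test_unknown_race_is_never_tier1(self):
        scores = [_score("A"), _score("B")]
        ehr = [make_participant("A", race="unknown"), make_participant("B", race="asian")]
        ranked = {s.participant_id: s for s in rank_participants(scores, ehr)}
        assert ranked["A"].tier == 2
        assert ranked["B"].tier == 1

    def test_ranks_are_a_permutation(self):
        rng = random.Random(5)
        scores = [_score(f"P{i:02d}", gh=rng.randint(0, 50), coding=rng.randint(0, 20),
                         total=100) for i in range(30)]
        ehr = [make_participant(s.participant_id,
                                race=rng.choice(["white", "asian", "unknown"]))
               for s in scores]
        ranked = rank_participants(scores, ehr)
        assert sorted(s.rank for s in ranked) == list(range(1, 31))

    def test_shuffled_input_gives_identical_ranking(self):
        rng = random.Random(11)
        scores = [_score(f"P{i:02d}", gh=rng.randint(0, 5), coding=rng.randint(0, 5),
                         total=10, flags=rng.randint(0, 5)) for i in range(40)]
        ehr = [make_participant(s.participant_id) for s in scores]
        base = rank_participants(scores, ehr)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        assert rank_participants(shuffled, ehr) == base

    def test_score_without_ehr_match_is_hard_error(self):
        with pytest.raises(ValueError, match="P99"):
            rank_participants([_score("P99")], [make_participant("P01")])

    def test_gh_priority_as_alternative_sort_key(self):
        a = ParticipantScore("A", total_variants=10, coding_variants=5,
                             gh_variants=5, gh_priority_variants=0)
        b = ParticipantScore("B", total_variants=10, coding_variants=5,
                             gh_variants=3, gh_priority_variants=2)
        ehr = [make_participant("A"), make_participant("B")]
        default = rank_participants([a, b], ehr)
        alt = rank_participants(
            [a, b], ehr, CohortConfig(gh_sort_statistic="gh_priority_variants")
        )
        assert default[0].participant_id == "A"
        assert alt[0].participant_id == "B"


class TestTakeTop:
    def _ranking(self, n=10):
        scores = [_score(f"P{i:02d}", gh=n - i, total=n) for i in range(n)]
        ehr = [make_participant(s.participant_id) for s in scores]
        return rank_participants(scores, ehr)

    def test_full_list_and_single_top(self):
        ranking = self._ranking()
        assert take_top(ranking, 10) == ranking
        assert take_top(ranking, 1) == [ranking[0]]

    def test_out_of_range_is_hard_error(self):
        ranking = self._ranking()
        for bad in (0, 11, -1):
            with pytest.raises(ValueError):
                take_top(ranking, bad)

    def test_tier1_fills_small_cuts(self):
        """With more tier-1 participants than the cut, the recontact list
        is entirely tier 1."""
        scores = [_score(f"P{i}", total=5) for i in range(6)]
        ehr = [make_participant(s.participant_id,
                                race="asian" if i < 4 else "white")
               for i, s in enumerate(scores)]
        top = take_top(rank_participants(scores, ehr), 3)
        assert all(s.tier == 1 for s in top)


class TestScoreValidation:
    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="coding"):
            ParticipantScore("P", total_variants=1, coding_variants=2,
                             gh_variants=0, gh_priority_variants=0)
        with pytest.raises(ValueError, match="gh_priority"):
            ParticipantScore("P", total_variants=5, coding_variants=2,
                             gh_variants=1, gh_priority_variants=2)
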