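import numpy as np
import pytest

from conftest import enum_best_duplex_score
from mirkit import synthetic_data as sd
from mirkit import target_prediction as tp
from mirkit._util import revcomp
from mirkit.io_core import RunConfig, SequenceRecord

MIR = "UGAGCUAGCUAGCUAGGCAUC"  # 21 nt


class TestDuplexAlign:
    def test_perfect_complement(self):
        aln = tp.duplex_align(MIR, revcomp(MIR))
        assert aln.pairing == "|" * 21
        assert aln.mismatch_cost == 0.0 and aln.raw_score == 21.0

    def test_single_gu_wobble_costs_half(self):
        # mature G at position 5 opposite U instead of C
        site = list(revcomp(MIR))
        p = MIR.index("G", 2)
        site[len(MIR) - 1 - p] = "U"
        aln = tp.duplex_align(MIR, "".join(site))
        assert aln.mismatch_cost == 0.5
        assert aln.pairing.count("o") == 1

    def test_two_mismatches_and_gap_cost_three(self):
        site = list(revcomp(MIR))
        site[4] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[4]]
        site[9] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[9]]
        del site[15]  # miRNA base left unopposed -> gap
        aln = tp.duplex_align(MIR, "".join(site))
        assert aln.mismatch_cost == 3.0

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            tp.duplex_align("ACGX", "ACGU")

    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGU"))
        for _ in range(80):
            m = int(rng.integers(4, 13))
            n = m + int(rng.integers(0, 4))
            a = "".join(bases[rng.integers(0, 4, m)])
            w = "".join(bases[rng.integers(0, 4, n)])
            aln = tp.duplex_align(a, w)
            assert aln.raw_score == pytest.approx(enum_best_duplex_score(a, w)), (a, w)

    def test_cost_consistent_with_pairing_string(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGU"))
        for _ in range(40):
            a = "".join(bases[rng.integers(0, 4, 12)])
            w = "".join(bases[rng.integers(0, 4, 15)])
            aln = tp.duplex_align(a, w)
            aligned = sum(1 for c in aln.mrna_coords if c >= 0)
            window_gaps = (aln.window_span[1] - aln.window_span[0]) - aligned
            expect = (
                aln.pairing.count(" ") * 1.0
                + aln.pairing.count("o") * 0.5
                + aln.pairing.count("-") * 1.0
                + window_gaps * 1.0
            )
            assert aln.mismatch_cost == pytest.approx(expect)


class TestScoreSite:
    # the 10-nt AU context flanks the seed-pairing subinterval on the mRNA,
    # so it includes site bases opposite miRNA positions 1 and 14-18; these
    # fixtures put A/U (or G/C) there explicitly
    MIR_AU = "UGAGCUAGCUAGCUAAUUGCA"
    MIR_GC = "GGAGCUAGCUAGCGCCGGGCA"

    def test_perfect_site_with_au_context(self):
        site = revcomp(self.MIR_AU)
        mrna = "AUAUA" + site + "UUAAU"
        aln = tp.duplex_align(self.MIR_AU, site)
        seed_bonus, au_bonus, final = tp.score_site(aln, mrna, 5)
        assert seed_bonus == 2.0 and au_bonus == 1.0
        assert final == aln.raw_score + 3.0

    def test_seed_mismatch_no_bonus(self):
        site = list(revcomp(MIR))
        p = 5  # miRNA position 6 (1-based), inside the 2-13 seed block
        site[len(MIR) - 1 - p] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[len(MIR) - 1 - p]]
        site = "".join(site)
        aln = tp.duplex_align(MIR, site)
        seed_bonus, _, _ = tp.score_site(aln, "G" * 5 + site + "G" * 5, 5)
        assert seed_bonus == 0.0

    def test_gc_context_no_au_bonus(self):
        site = revcomp(self.MIR_GC)
        aln = tp.duplex_align(self.MIR_GC, site)
        _, au_bonus, _ = tp.score_site(aln, "GCGCG" + site + "CGCGC", 5)
        assert au_bonus == 0.0

    def test_added_mismatch_never_raises_score(self):
        rng = np.random.default_rng(21)
        site = revcomp(MIR)
        mrna = "AUGCA" + site + "AUGCA"
        base = tp.score_site(tp.duplex_align(MIR, site), mrna, 5)[2]
        for pos in rng.integers(0, 21, 12):
            worse = list(site)
            worse[pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[worse[pos]]
            worse = "".join(worse)
            score = tp.score_site(tp.duplex_align(MIR, worse), "AUGCA" + worse + "AUGCA", 5)[2]
            assert score <= base


@pytest.fixture(scope="module")
def planted():
    genome, truth = sd.make_genome(n_precursors=6, seed=23, buffer_len=60)
    unigenes = sd.make_unigenes(truth, n_decoys=4, seed=23)
    sites = tp.predict_targets(
        [(m.id, m.mature) for m in truth.mirnas], unigenes, RunConfig()
    )
    return truth, unigenes, sites


class TestPredictTargets:

    def test_recoverable_planted_sites_found_at_planted_cr(self, planted):
        truth, _, sites = planted
        for target in truth.targets:
            found = [
                s
                for s in sites
                if s.mirna_id == target.mirna_id and s.unigene_id == target.unigene_id
            ]
            if target.cost <= 3.0:
                assert len(found) == 1, target
                assert found[0].cr == target.cr
                assert found[0].mismatch_cost == pytest.approx(target.cost)
            else:
                assert found == [], target

    def test_decoys_have_no_sites(self, planted):
        _, _, sites = planted
        assert not any(s.unigene_id.startswith("decoy") for s in sites)

    def test_two_mirnas_on_one_unigene_give_two_sites(self):
        m1 = SequenceRecord("miR1a", MIR)
        m2 = SequenceRecord("miR2a", "GUCGAUGCAUUCAAGAUUGCG")
        uni = SequenceRecord(
            "u1", "AUGCA" + revcomp(m1.seq) + "CCGGAAUU" + revcomp(m2.seq) + "AUGCA"
        )
        sites = tp.predict_targets([m1, m2], [uni])
        assert {(s.mirna_id, s.unigene_id) for s in sites} == {
            ("miR1a", "u1"),
            ("miR2a", "u1"),
        }


class TestSummarizeFamilies:
    def site(self, fam, uni):
        return tp.TargetSite(
            mirna_id=fam + "a", family=fam, unigene_id=uni, cr=(0, 21),
            pairing="|" * 21, mismatch_cost=0.0, raw_score=21.0, final_score=24.0,
        )

    def test_distinct_targets_counted(self):
        sites = [self.site("miR1", f"u{i}") for i in range(3)]
        summaries, missing = tp.summarize_families(sites)
        assert summaries == [tp.FamilyTargetSummary("miR1", 3)] and missing == []

    def test_family_without_sites_listed_missing(self):
        summaries, missing = tp.summarize_families(
            [self.site("miR1", "u1")], all_families=["miR1", "miR9"]
        )
        assert missing == ["miR9"]

    def test_two_members_same_unigene_counted_once(self):
        sites = [self.site("miR1", "u1"), self.site("miR1", "u1")]
        (summary,), _ = tp.summarize_families(sites)
        assert summary.n_targets == 1

    def test_count_stats(self):
        summaries = [
            tp.FamilyTargetSummary("a", 1),
            tp.FamilyTargetSummary("b", 25),
            tp.FamilyTargetSummary("c", 4),
        ]
        assert tp.target_count_stats(summaries) == (1, 25, 10.0)
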