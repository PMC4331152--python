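import numpy as np
import pytest

from conftest import enum_max_pairs
from mirkit._fold import max_pairs
from mirkit._util import revcomp
from mirkit.hairpin_filter import (
    HairpinCandidate,
    StructureError,
    count_loops,
    duplex_stats,
    fold_fallback,
    mircheck_filter,
    parse_vienna,
    structure_filter,
    trim_free_tails,
)
from mirkit.io_core import RunConfig


def hairpin(arm: str, loop_len: int = 12, star: str | None = None):
    """A candidate built from an explicit arm/star with a dot loop."""
    star = star if star is not None else revcomp(arm)
    seq = arm + "A" * loop_len + star
    structure, mfe = fold_fallback(seq)
    return HairpinCandidate(
        "h", seq, structure, mfe, (0, len(arm)), provenance="fallback"
    )


class TestParseVienna:
    def test_energy_parsed(self):
        text = ">cand mature=1..4\nGCGCAAAAGCGC\n((((....)))) (-19.2)\n"
        (c,) = parse_vienna(text)
        assert c.mfe == -19.2 and c.structure == "((((....))))"
        assert c.mature_span == (0, 4)

    def test_all_dots_structure(self):
        (c,) = parse_vienna(">x\nAAAAAAAA\n........ (0.0)\n")
        assert c.structure.count("(") == 0

    def test_bracket_imbalance_rejected(self):
        with pytest.raises(StructureError):
            parse_vienna(">x\nGCGCAAAA\n(((..... (-1.0)\n")


class TestFoldFallback:
    def test_four_gc_pairs(self):
        structure, energy = fold_fallback("GGGGAAAACCCC")
        assert structure.count("(") == 4 and energy == -8

    def test_all_a_no_pairs(self):
        structure, energy = fold_fallback("AAAAAAAAAAAA")
        assert structure == "." * 12 and energy == 0

    def test_perfect_gc_stem(self):
        structure, energy = fold_fallback("G" * 10 + "AAAA" + "C" * 10)
        assert energy == -20 and count_loops(structure) == 1

    def test_matches_enumeration_on_short_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(80):
            n = int(rng.integers(5, 15))
            seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])
            assert max_pairs(seq) == enum_max_pairs(seq), seq

    def test_disallowed_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_fallback("ACGX")


class TestCountLoops:
    @pytest.mark.parametrize(
        "structure,n",
        [("((((....))))", 1), ("((..))..((..))", 2), ("............", 0)],
    )
    def test_examples(self, structure, n):
        assert count_loops(structure) == n


class TestTrimFreeTails:
    def test_tails_removed_and_span_shifted(self):
        c = HairpinCandidate(
            "t", "AAGGCCAAGG", "..((..))..", -2.0, (2, 8), provenance="external"
        )
        trimmed, reason = trim_free_tails(c)
        assert reason is None
        assert trimmed.structure == "((..))" and trimmed.mature_span == (0, 6)

    def test_idempotent_on_flush_candidate(self):
        c = HairpinCandidate("t", "GGCCAAGG", "((..))..", -2.0, (0, 4))
        once, _ = trim_free_tails(c)
        twice, _ = trim_free_tails(once)
        assert once == twice

    def test_mature_in_tail_rejected(self):
        c = HairpinCandidate("t", "AAGGCCAAGG", "..((..))..", -2.0, (0, 4))
        trimmed, reason = trim_free_tails(c)
        assert trimmed is None and reason == "mature_in_tail"

    def test_no_pairs_gives_empty_stem(self):
        c = HairpinCandidate("t", "AAAA", "....", 0.0, (0, 2))
        trimmed, reason = trim_free_tails(c)
        assert trimmed is None and reason == "empty_stem"


class TestStructureFilter:
    def test_good_hairpin_passes(self):
        arm = "GCGCGCGCGCAUAUAUAUGCGC"  # 22 nt, GC-rich
        ok, reasons = structure_filter(hairpin(arm))
        assert ok and reasons == []

    def test_too_few_pairs_fails(self):
        # 17-bp stem: below the 18-bp floor even with fine energy
        arm = "GCGCGCGCGCGCGCGCG"
        ok, reasons = structure_filter(hairpin(arm))
        assert not ok and reasons == ["min_paired_bp"]

    def test_two_loops_fail(self):
        # two explicit 10-bp stems: 20 paired bp and fine energy, 2 loops
        unit_seq = "G" * 10 + "AAAA" + "C" * 10
        unit_st = "(" * 10 + "...." + ")" * 10
        c = HairpinCandidate(
            "t", unit_seq + "AAA" + unit_seq, unit_st + "..." + unit_st, -30.0, (0, 10)
        )
        ok, reasons = structure_filter(c)
        assert not ok and reasons == ["one_central_loop"]

    def test_weak_energy_fails(self):
        arm = "GCGCGCGCGCAUAUAUAUGCGC"
        c = hairpin(arm)
        c = HairpinCandidate(c.id, c.seq, c.structure, -17.9, c.mature_span)
        ok, reasons = structure_filter(c)
        assert not ok and reasons == ["energy"]

    def test_thresholds_monotone(self):
        arm = "GCGCGCGCGCAUAUAUAUGCGC"
        c = hairpin(arm)
        ok, _ = structure_filter(c, RunConfig())
        stricter = RunConfig(min_paired_bp=30, energy_max_kcal=-60.0)
        ok2, _ = structure_filter(c, stricter)
        assert ok and not ok2  # strengthening never converts fail to pass


def explicit_duplex(mismatch_positions=(), seed_positions=()):
    """Hand-built 21-bp duplex with opposed unpaired positions injected."""
    arm = "UGAGCUAGCUAGCUAGGCAUC"
    star = list(revcomp(arm))
    st_arm = list("(" * 21)
    st_star = list(")" * 21)
    for p in list(mismatch_positions) + list(seed_positions):
        st_arm[p] = "."
        st_star[20 - p] = "."
    seq = arm + "AAAA" + "".join(star)
    structure = "".join(st_arm) + "...." + "".join(st_star)
    return HairpinCandidate("d", seq, structure, -30.0, (0, 21))


class TestMircheckFilter:
    def test_perfect_duplex(self):
        ok, stats, reasons = mircheck_filter(explicit_duplex())
        assert ok and stats.mismatches == 0 and stats.bulged == 0

    def test_five_mismatches_fail(self):
        ok, stats, reasons = mircheck_filter(
            explicit_duplex(mismatch_positions=(9, 11, 13, 15, 17))
        )
        assert not ok and reasons == ["max_mismatches"] and stats.mismatches == 5

    def test_three_consecutive_seed_mismatches_fail(self):
        # positions 3-5 (1-based) sit inside the 2-8 seed span
        ok, stats, reasons = mircheck_filter(explicit_duplex(seed_positions=(2, 3, 4)))
        assert not ok and reasons == ["seed_run"] and stats.max_run_seed_mm == 3

    def test_asymmetric_bulges_counted(self):
        # 2-nt bulge on the mature side only: 11-nt arm with 2 internal
        # dots opposed by a fully paired 9-nt star
        seq = "GGGGGAAGGGG" + "AAAA" + "CCCCCCCCC"
        structure = "(((((..((((" + "...." + ")))))))))"
        c = HairpinCandidate("b", seq, structure, -20.0, (0, 11))
        stats = duplex_stats(c)
        assert stats.bulged == 2 and stats.mismatches == 0

    def test_mature_spanning_loop_rejected(self):
        seq = "GGGGAAAACCCC"
        c = HairpinCandidate("x", seq, "((((....))))", -8.0, (2, 10))
        with pytest.raises(StructureError, match="mature_spans_loop"):
            mircheck_filter(c)


class TestPlantedPrecursors:
    def test_generator_hairpins_pass_both_filters(self, small_genome):
        from mirkit.hairpin_filter import fold_fallback

        _, truth = small_genome
        for planted in truth.mirnas:
            structure, mfe = fold_fallback(planted.precursor)
            cand = HairpinCandidate(
                planted.id,
                planted.precursor,
                structure,
                mfe,
                (0, len(planted.mature)),
                provenance="fallback",
            )
            trimmed, reason = trim_free_tails(cand)
            assert reason is None
            ok_s, rs = structure_filter(trimmed)
            ok_m, _, rm = mircheck_filter(trimmed)
            assert ok_s and ok_m, (planted.id, rs, rm)
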