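import numpy as np
import pytest

from mirkit import discovery as dc
from mirkit import synthetic_data as sd
from mirkit.io_core import RunConfig, SequenceRecord


class TestMatchKnownMatures:
    def test_planted_loci_found_at_planted_coordinates(self, small_genome):
        genome, truth = small_genome
        loci = dc.match_known_matures(truth.mature_records(), genome)
        for planted in truth.mirnas:
            mine = [
                l
                for l in loci
                if l.query_id == planted.id and l.strand == planted.locus.strand
            ]
            assert len(mine) == 1
            (locus,) = mine
            # the mature arm sits at one end of the planted precursor
            assert planted.locus.start <= locus.start < locus.end <= planted.locus.end

    def test_absent_mature_zero_loci(self, small_genome):
        genome, _ = small_genome
        # a sequence engineered to not occur: 21 alternating CG on a genome
        probe = SequenceRecord("probe", "CG" * 10 + "C")
        assert dc.match_known_matures([probe], genome) == []

    def test_minus_strand_reported(self):
        mature = "UGAGCUAGCUAGCUAGGCAUC"
        from mirkit._util import revcomp, to_dna

        genome = [SequenceRecord("c", "A" * 30 + to_dna(revcomp(mature)) + "A" * 30)]
        loci = dc.match_known_matures([SequenceRecord("m", mature)], genome)
        assert [(l.start, l.strand) for l in loci] == [(30, "-")]


class TestExtractFlankWindows:
    def test_window_lengths_for_two_flanks(self, small_genome):
        genome, truth = small_genome
        locus = dc.match_known_matures(truth.mature_records(), genome)[0]
        windows = dc.extract_flank_windows(locus, genome, [20, 100])
        # locus length 21: (20,20)=61, (20,100)=141, (100,20)=141, (100,100)=221
        assert sorted(len(w.seq) for w in windows) == [61, 141, 141, 221]

    def test_default_flank_set_yields_36_windows(self, small_genome):
        genome, truth = small_genome
        locus = dc.match_known_matures(truth.mature_records(), genome)[0]
        assert len(dc.extract_flank_windows(locus, genome, RunConfig().flank_lengths)) == 36

    def test_contig_start_clipping_flagged(self):
        genome = [SequenceRecord("c", "ACGTACGTACGTACGTACGTACGT" * 3)]
        locus = dc.MatureLocus("m", "c", 5, 26, "+")
        (w,) = dc.extract_flank_windows(locus, genome, [20])
        assert w.clipped and w.genomic_start == 0 and w.mature_span == (5, 26)


class TestCallConserved:
    def test_planted_set_recovered(self, small_genome, small_config):
        genome, truth = small_genome
        loci = dc.match_known_matures(truth.mature_records(), genome)
        records = dc.call_conserved(loci, genome, small_config)
        assert {r.mature for r in records} == {m.mature for m in truth.mirnas}
        assert {r.family for r in records} == {m.id for m in truth.mirnas}

    def test_exact_match_in_non_hairpin_background_rejected(self, small_config):
        rng = np.random.default_rng(3)
        mature = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 21)])
        bg = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 400)])
        genome = [SequenceRecord("c", bg[:200] + mature + bg[200:])]
        loci = dc.match_known_matures([SequenceRecord("m", mature)], genome)
        assert len(loci) >= 1
        assert dc.call_conserved(loci, genome, small_config) == []


class TestMapReads:
    def test_counts_and_mismatch_cap(self):
        ref = SequenceRecord("miR1", "UGAGCUAGCUAGCUAGGCAUC")
        exact = SequenceRecord("r1", ref.seq, 12)
        two_mm = SequenceRecord("r2", "GGAGCUAGCUAGCUAGGCAUG", 5)
        three_mm = SequenceRecord("r3", "GGAGCUAGCUAGCUAGGCCGG", 7)
        counts = dc.map_reads([exact, two_mm, three_mm], [ref], max_mm=2)
        assert counts == {"miR1": 17}

    def test_multi_reference_reads_counted_on_every_reference(self):
        r1 = SequenceRecord("a", "UGAGCUAGCUAGCUAGGCAUC")
        r2 = SequenceRecord("b", "AAAA" + "UGAGCUAGCUAGCUAGGCAUC")
        read = SequenceRecord("r", "UGAGCUAGCUAGCUAGGCAUC", 4)
        assert dc.map_reads([read], [r1, r2], max_mm=0) == {"a": 4, "b": 4}

    def test_matches_brute_force_hamming_scan(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        refs = [
            SequenceRecord(f"ref{i}", "".join(bases[rng.integers(0, 4, 25)]))
            for i in range(4)
        ]
        reads = []
        for i in range(30):
            src = refs[rng.integers(0, 4)].seq
            start = rng.integers(0, 5)
            read = list(src[start : start + 20])
            for _ in range(rng.integers(0, 4)):
                read[rng.integers(0, 20)] = bases[rng.integers(0, 4)]
            reads.append(SequenceRecord(f"r{i}", "".join(read), int(rng.integers(1, 9))))

        def brute(read, ref, mm):
            return any(
                sum(a != b for a, b in zip(read, ref[o : o + len(read)])) <= mm
                for o in range(len(ref) - len(read) + 1)
            )

        got = dc.map_reads(reads, refs, max_mm=2)
        want = {
            ref.id: sum(r.count for r in reads if brute(r.seq, ref.seq, 2))
            for ref in refs
        }
        assert got == want


class TestConservationRule:
    @pytest.mark.parametrize(
        "has_hits,reads,expected",
        [
            (False, 3.0, "not_conserved"),
            (False, 15.0, "conserved_in_assembly"),
            (True, 0.0, "conserved_in_assembly"),
            (True, 100.0, "conserved_in_assembly"),
        ],
    )
    def test_two_by_two_table(self, has_hits, reads, expected):
        assert dc.call_conservation(has_hits, reads) == expected


class TestCallNovelty:
    KNOWN = "UGACAGAAGAGAGUGAGCACA"
    # 7 / 6 scattered substitutions of KNOWN: 14 and 15 identities out of 21,
    # verified against an exhaustive offset-scan alignment oracle
    CAND_14 = "AGAGAGCAGCGAUUGCGCCCA"
    CAND_15 = "AGAGAGCAGCGAUUGCGCACA"

    def test_identical_is_known(self):
        assert dc.call_novelty(self.KNOWN, [SequenceRecord("k", self.KNOWN)]) == "known"

    def test_two_thirds_identity_is_new(self):
        assert dc.call_novelty(self.CAND_14, [SequenceRecord("k", self.KNOWN)]) == "new"

    def test_fifteen_of_twentyone_is_known(self):
        assert dc.call_novelty(self.CAND_15, [SequenceRecord("k", self.KNOWN)]) == "known"

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError):
            dc.call_novelty(self.KNOWN, [])


class TestHomologySearch:
    def test_genome_substring_found_with_full_identity(self, small_genome):
        genome, truth = small_genome
        query = truth.mirnas[0].precursor[:54]
        hits = dc.homology_search(query, genome)
        assert hits and any(h.identity == 1.0 for h in hits)

    def test_shuffled_query_vs_random_genome_no_hits(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        genome = [SequenceRecord("c", "".join(bases[rng.integers(0, 4, 3000)]))]
        for _ in range(10):
            q = "".join(bases[rng.integers(0, 4, 70)])
            assert dc.homology_search(q, genome) == []

    def test_two_copy_precursor_two_plus_strand_hits(self):
        genome, truth = sd.make_genome(
            n_precursors=2, seed=5, n_multicopy=1, buffer_len=60
        )
        multi = next(m for m in truth.mirnas if m.n_copies == 2)
        hits = dc.homology_search(multi.precursor, genome)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) >= 2


class TestDiscoverNew:
    def test_unknown_planted_mature_called_new(self, small_genome, small_config):
        genome, truth = small_genome
        known = [SequenceRecord(m.id, m.mature) for m in truth.mirnas[1:]]
        reads = [SequenceRecord("r1", truth.mirnas[0].mature, 50)]
        records = dc.discover_new(reads, genome, known, small_config)
        assert len(records) == 1
        assert records[0].status == "new" and records[0].family == "new-1"
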