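from types import SimpleNamespace

import numpy as np
import pytest

from oracles import full_dp_local_score

from conftest import random_seq
from gallsift.assemble import Contig
from gallsift.hybridscan import (BOTH, FIVE_PRIME, FULL_MATCH, NONE,
                                 THREE_PRIME, CigarAlignment,
                                 align_contig_to_reference,
                                 assess_endophyte_synteny, classify_hybrid,
                                 count_support, estimate_insertion_site,
                                 filter_by_support, mapping_confidence)
from gallsift.kmers import revcomp
from gallsift.seqio import ReadRecord, SequenceRecord


@pytest.fixture(scope="module")
def foreign():
    g = np.random.default_rng(4242)
    return random_seq(g, 500)


def _mm(seq, positions):
    chars = list(seq)
    for p in positions:
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + 2) % 4]
    return "".join(chars)


class TestAlignContig:
    def test_exact_substring_single_alignment(self, small_genome):
        g = small_genome[0].seq
        alns = align_contig_to_reference(g[5000:5400], small_genome)
        assert len(alns) == 1
        a = alns[0]
        assert (a.chrom, a.ref_start, a.strand, a.cigar) == ("chrA", 5000, "+", "400M")
        assert a.n_mismatch == 0 and a.score == 400

    def test_hybrid_contig_clipped_representations(self, small_genome, foreign):
        g = small_genome[0].seq
        contig = g[1000:1100] + foreign[:200] + g[1100:1200]
        alns = align_contig_to_reference(contig, small_genome)
        cigars = sorted(a.cigar for a in alns)
        assert cigars == ["100M300S", "300S100M"]
        assert {a.ref_start for a in alns} == {1000, 1100}

    def test_fully_foreign_contig_unalignable(self, small_genome, foreign):
        assert align_contig_to_reference(foreign, small_genome) == []

    def test_contig_shorter_than_seed_returns_nothing(self, small_genome):
        assert align_contig_to_reference("ACGTACGTACGTAC", small_genome) == []

    def test_cigar_length_bookkeeping(self, small_genome):
        """M+I+S lengths sum to contig length on randomly mutated substrings."""
        g = small_genome[0].seq
        rng = np.random.default_rng(17)
        for _ in range(20):
            s = int(rng.integers(0, len(g) - 400))
            contig = _mm(g[s:s + 400], rng.choice(400, size=6, replace=False))
            if rng.integers(0, 2):
                contig = revcomp(contig)
            for a in align_contig_to_reference(contig, small_genome):
                assert sum(n for n, op in a.ops() if op in "MIS") == len(contig)

    def test_score_matches_full_dp_oracle_with_indels(self, small_genome):
        g = small_genome[0].seq
        rng = np.random.default_rng(23)
        for _ in range(5):
            s = int(rng.integers(0, len(g) - 450))
            contig = _mm(g[s:s + 450], rng.choice(450, size=4, replace=False))
            cut = int(rng.integers(100, 300))
            contig = contig[:cut] + contig[cut + 2:]  # 2-bp deletion
            alns = align_contig_to_reference(contig, small_genome)
            assert alns
            assert alns[0].score == full_dp_local_score(g, contig)


class TestMappingConfidence:
    def _aln(self, cigar, score, ref_start, chrom="chrA"):
        return CigarAlignment("c", chrom, ref_start, "+", cigar, 100, 0, score)

    def test_single_alignment_gets_60(self):
        out = mapping_confidence([self._aln("100M", 100, 1000)])
        assert out[0].confidence == 60

    def test_equal_score_loci_get_zero(self):
        out = mapping_confidence([self._aln("100M", 100, 1000),
                                  self._aln("100M", 100, 5000)])
        assert [a.confidence for a in out] == [0, 0]

    def test_formula_100_vs_80(self):
        out = mapping_confidence([self._aln("100M", 100, 1000),
                                  self._aln("100M", 80, 5000)])
        by_start = {a.ref_start: a.confidence for a in out}
        assert by_start == {1000: 12, 5000: 0}  # round(60*(100-80)/100) = 12

    def test_disjoint_contig_intervals_do_not_compete(self):
        # the two host anchors of one hybrid contig must both stay confident
        out = mapping_confidence([self._aln("100M300S", 100, 1000),
                                  self._aln("300S100M", 100, 1100)])
        assert [a.confidence for a in out] == [60, 60]

    def test_empty_input(self):
        assert mapping_confidence([]) == []


class TestClassifyHybrid:
    def _scan(self, contig_seq, genome, **kw):
        alns = mapping_confidence(align_contig_to_reference(contig_seq, genome))
        return classify_hybrid(contig_seq, alns, **kw)

    def test_host_substring_is_full_match(self, small_genome):
        call = self._scan(small_genome[0].seq[3000:3300], small_genome)
        assert call.anchor_class == FULL_MATCH

    def test_both_anchored_insertion(self, small_genome, foreign):
        g = small_genome[0].seq
        call = self._scan(g[1000:1100] + foreign[:200] + g[1100:1200], small_genome)
        assert call.anchor_class == BOTH
        assert call.foreign_core == (100, 300)
        assert call.insertion_site == ("chrA", 1100)
        assert call.insertion_points == ("chrA", 1100, 1100)

    def test_classification_invariant_under_reverse_complement(self, small_genome, foreign):
        g = small_genome[0].seq
        contig = g[1000:1100] + foreign[:200] + g[1100:1200]
        fwd = self._scan(contig, small_genome)
        rev = self._scan(revcomp(contig), small_genome)
        assert rev.anchor_class == fwd.anchor_class == BOTH
        assert rev.insertion_site == fwd.insertion_site
        assert rev.foreign_core == (100, 300)  # symmetric contig

    def test_representation_invariance_internal_insertion_op(self, small_genome, foreign):
        """A '100M200I100M' encoding classifies exactly like the dual-clip one."""
        g = small_genome[0].seq
        contig = g[1000:1100] + foreign[:200] + g[1100:1200]
        via_aligner = self._scan(contig, small_genome)
        internal = CigarAlignment("c", "chrA", 1000, "+", "100M200I100M",
                                  n_match=200, n_mismatch=0, score=200,
                                  confidence=60)
        via_internal = classify_hybrid(contig, [internal])
        assert via_internal.anchor_class == via_aligner.anchor_class == BOTH
        assert via_internal.foreign_core == via_aligner.foreign_core
        assert via_internal.insertion_site == via_aligner.insertion_site
        assert via_internal.insertion_points == via_aligner.insertion_points

    def test_three_prime_anchor_only(self, small_genome, foreign):
        g = small_genome[0].seq
        call = self._scan(foreign[:150] + g[2000:2120], small_genome)
        assert call.anchor_class == THREE_PRIME
        assert call.foreign_core == (0, 150)
        assert call.insertion_site == ("chrA", 2000)

    def test_five_prime_anchor_only(self, small_genome, foreign):
        g = small_genome[0].seq
        call = self._scan(g[2000:2120] + foreign[:150], small_genome)
        assert call.anchor_class == FIVE_PRIME
        assert call.insertion_site == ("chrA", 2120)

    def test_fully_foreign_is_none(self, small_genome, foreign):
        assert self._scan(foreign, small_genome).anchor_class == NONE

    def test_low_identity_anchor_ignored(self, small_genome, foreign):
        g = small_genome[0].seq
        noisy_prefix = _mm(g[1000:1100], range(5, 85, 10))  # 8 mm -> 92% identity
        contig = noisy_prefix + foreign[:200] + g[1100:1200]
        call = self._scan(contig, small_genome)
        assert call.anchor_class == THREE_PRIME

    def test_microhomology_reported_as_negative_gap(self, small_genome, foreign):
        g = small_genome[0].seq
        p = 4000
        # clamp the foreign ends so chance matches cannot extend the anchors
        core = list(foreign[:200])
        core[0] = "ACGT"[("ACGT".index(g[p]) + 1) % 4]
        core[-1] = "ACGT"[("ACGT".index(g[p - 7]) + 1) % 4]
        contig = g[p - 80:p] + "".join(core) + g[p - 6:p + 74]
        call = self._scan(contig, small_genome)
        assert call.anchor_class == BOTH
        assert call.insertion_points == ("chrA", p, p - 6)
        assert call.insertion_site == ("chrA", p)
        assert estimate_insertion_site(call) == ("chrA", p, p - 6)

    def test_estimate_requires_hybrid(self, small_genome):
        call = self._scan(small_genome[0].seq[3000:3300], small_genome)
        with pytest.raises(ValueError, match="not a hybrid"):
            estimate_insertion_site(call)

    def test_contradictory_anchors_flagged(self):
        a = CigarAlignment("c", "chrA", 1000, "+", "100M200S", 100, 0, 100, 60)
        b = CigarAlignment("c", "chrB", 8000, "+", "100M200S", 100, 0, 100, 60)
        call = classify_hybrid("A" * 300, [a, b])
        assert call.anchor_class == NONE
        assert call.warning == "contradictory_anchors"


class TestSupport:
    def _contig(self, small_genome, foreign):
        g = small_genome[0].seq
        return g[1000:1200] + foreign[:200] + g[1200:1400], 200  # junction at 200

    def test_tiling_junction_reads_counted(self, small_genome, foreign):
        contig, j = self._contig(small_genome, foreign)
        reads = [ReadRecord(f"r{i}", contig[s:s + 150])
                 for i, s in enumerate([120, 140, 160, 170, 185])]
        rep = count_support(contig, reads, junctions=[j])
        assert (rep.support, rep.junction_support) == (5, 5)

    def test_reads_elsewhere_support_but_not_junction(self, small_genome, foreign):
        contig, j = self._contig(small_genome, foreign)
        reads = [ReadRecord("far", contig[380:530]),
                 ReadRecord("span", contig[130:280])]
        rep = count_support(contig, reads, junctions=[j])
        assert (rep.support, rep.junction_support) == (2, 1)

    def test_mismatch_budget(self, small_genome, foreign):
        contig, j = self._contig(small_genome, foreign)
        two = ReadRecord("two", _mm(contig[100:250], [10, 60]))
        three = ReadRecord("three", _mm(contig[100:250], [10, 60, 110]))
        rep = count_support(contig, [two, three], junctions=[j])
        assert rep.support == 1

    def test_unplaceable_reads_give_zero(self, small_genome, foreign, rng):
        contig, j = self._contig(small_genome, foreign)
        reads = [ReadRecord(f"x{i}", random_seq(rng, 150)) for i in range(5)]
        rep = count_support(contig, reads, junctions=[j])
        assert (rep.support, rep.junction_support) == (0, 0)

    def test_junction_support_bounded_by_support(self, small_genome, foreign, rng):
        contig, j = self._contig(small_genome, foreign)
        reads = [ReadRecord(f"r{i}", contig[s:s + 150])
                 for i, s in enumerate(rng.integers(0, len(contig) - 150, 30))]
        rep = count_support(contig, reads, junctions=[j])
        assert rep.junction_support <= rep.support


class TestFilterBySupport:
    def _setup(self):
        from gallsift.hybridscan import HybridCall, SupportReport
        calls = [HybridCall(f"c{i}", BOTH) for i in range(3)]
        reports = {"c0": SupportReport("c0", 2, 1),
                   "c1": SupportReport("c1", 3, 2),
                   "c2": SupportReport("c2", 2, 0)}
        return calls, reports

    def test_threshold_semantics(self):
        calls, reports = self._setup()
        kept = filter_by_support(calls, reports)
        assert [(c.contig_id, c.allowlisted) for c in kept] == [("c1", False)]

    def test_allowlist_exempts_with_flag(self):
        calls, reports = self._setup()
        kept = filter_by_support(calls, reports, allowlist=["c2"])
        assert [(c.contig_id, c.allowlisted) for c in kept] == \
               [("c1", False), ("c2", True)]

    def test_unknown_allowlist_id_warns(self):
        calls, reports = self._setup()
        with pytest.warns(UserWarning, match="nope"):
            filter_by_support(calls, reports, allowlist=["nope"])


class TestEndophyteSynteny:
    def test_contained_contigs_support_endophyte(self, rng):
        isolate = SequenceRecord("iso", random_seq(rng, 5000))
        contigs = [Contig("a", isolate.seq[500:900], 5.0),
                   Contig("b", revcomp(isolate.seq[2000:2300]), 5.0),
                   Contig("short", isolate.seq[100:250], 5.0)]
        out = assess_endophyte_synteny(contigs, isolate)
        assert out["endophyte_supported"] is True
        assert out["qualifying_ids"] == ["a", "b"]
        assert out["total_bases"] == 700

    def test_unrelated_contigs_negative(self, rng):
        isolate = SequenceRecord("iso", random_seq(rng, 5000))
        contigs = [Contig("a", random_seq(rng, 400), 5.0)]
        out = assess_endophyte_synteny(contigs, isolate)
        assert out["endophyte_supported"] is False
        assert out["n_qualifying_contigs"] == 0

    def test_empty_contig_list_negative(self, rng):
        isolate = SequenceRecord("iso", random_seq(rng, 2000))
        out = assess_endophyte_synteny([], isolate)
        assert out["endophyte_supported"] is False

    def test_empty_isolate_errors(self):
        fake = SimpleNamespace(id="iso", seq="")
        with pytest.raises(ValueError, match="empty"):
            assess_endophyte_synteny([], fake)
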