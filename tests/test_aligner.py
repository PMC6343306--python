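import numpy as np
import pytest

from oracles import affine_dp_score
from pybsmeth.aligner import (
    AlignParams,
    OrientedQuery,
    Read,
    align,
    align_paired,
    compute_mapq,
    convert_read,
    deep_scan_pair,
    extend_hit,
    extend_ungapped,
    find_candidates,
    gate_indel,
    multi_seed,
    seed_align,
    soft_clip_realign,
    Alignment,
)
from pybsmeth.genome_index import (
    ReferenceGenome,
    build_index,
    convert_genome,
    revcomp,
)
from pybsmeth import samio


def make_genome(seq, name="chr1"):
    return ReferenceGenome([name], {name: seq})


def oq_for(seq, view="c2t", q=30):
    from pybsmeth.genome_index import c2t, g2a

    key = c2t(seq) if view == "c2t" else g2a(seq)
    conv = "C2T" if view == "c2t" else "G2A"
    return OrientedQuery(seq, key, [q] * len(seq), "+", view, conv)


class TestConvertRead:
    def test_c2t_example(self, read_factory):
        orients = convert_read(read_factory("ACGT"))
        assert orients[0].key == "ATGT"
        assert orients[0].view == "c2t"

    def test_fixed_point(self, read_factory):
        orients = convert_read(read_factory("AAAA"))
        assert orients[0].key == "AAAA"
        assert orients[1].key == "TTTT"  # revcomp of AAAA

    def test_revcomp_then_convert(self, read_factory):
        # revcomp("ACGT") == "ACGT"; its G->A conversion is "ACAT"
        orients = convert_read(read_factory("ACGT"))
        rev = orients[1]
        assert rev.seq == "ACGT"
        assert rev.strand == "-"
        assert rev.view == "g2a"
        assert rev.key == "ACAT"

    def test_directional_has_two_orientations(self, read_factory):
        assert len(convert_read(read_factory("ACGT"), "directional")) == 2

    def test_non_directional_has_four(self, read_factory):
        assert len(convert_read(read_factory("ACGT"), "non_directional")) == 4

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            convert_read(Read("x", "", []))

    def test_quals_reversed_with_sequence(self):
        read = Read("x", "ACGT", [10, 20, 30, 40])
        rev = convert_read(read)[1]
        assert rev.quals == [40, 30, 20, 10]


class TestSeedAlign:
    def test_exact_seed_single_hit(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        seq = ref[1000:1075]
        hits = seed_align(oq_for(seq), idx, params)
        assert hits[0].pos == 1000
        assert hits[0].cost == 0

    def test_distant_seed_empty(self, indexed_genome, params, rng):
        pair, idx = indexed_genome
        # a random 75-mer shares no 12-mer chunk with the genome w.h.p.
        local = np.random.default_rng(99)
        for _ in range(5):
            seq = "".join(local.choice(list("ACGT"), size=75))
            hits = seed_align(oq_for(seq), idx, params)
            for h in hits:  # any hit must satisfy the budget
                assert h.cost <= params.max_mm + 1.5 * params.max_gap

    def test_mismatches_plus_deletion_cost(self, indexed_genome, params):
        """3 substitutions plus one 2-base deletion costs 3 + 1.5 = 4.5."""
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        start = 2000
        window = ref[start : start + 77]  # 2 extra ref bases are deleted
        seq = list(window[:30] + window[32:77])
        for off in (5, 15, 25):  # plant substitutions in the prefix
            seq[off] = {"A": "G", "C": "G", "G": "T", "T": "G"}[seq[off]]
        seq = "".join(seq)
        assert len(seq) == 75
        hits = seed_align(oq_for(seq), idx, params)
        assert hits
        best = hits[0]
        assert best.pos == start
        assert best.cost == pytest.approx(4.5)
        assert best.gap is not None and best.gap[0] == "D" and best.gap[1] == 2

    def test_hits_sorted_by_cost(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        hits = seed_align(oq_for(ref[500:575]), idx, params)
        costs = [h.cost for h in hits]
        assert costs == sorted(costs)


class TestMultiSeed:
    def test_consistent_seeds_merge(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        seq = ref[3000:3160]
        hits = multi_seed(oq_for(seq), idx, params)
        assert sum(1 for h in hits if h.pos == 3000) == 1

    def test_second_seed_rescues(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        seq = list(ref[4000:4160])
        for off in range(0, 72, 12):  # destroy every chunk of seed 1
            seq[off] = {"A": "C", "C": "A", "G": "C", "T": "C"}[seq[off]]
        hits = multi_seed(oq_for("".join(seq)), idx, params)
        assert any(h.pos == 4000 for h in hits)

    def test_150bp_read_uses_single_seed(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        seq = ref[5000:5150]
        # dispatch: ≤150 bp goes through the single leading seed
        hits = find_candidates(oq_for(seq), idx, params)
        assert any(h.pos == 5000 for h in hits)


class TestExtendHit:
    def test_perfect_match_score(self, params):
        ref = "A" * 10 + "ACGTT" * 15 + "A" * 10
        seq = ref[10:85]
        aln = extend_hit(oq_for(seq), ref, 10, params)
        assert aln.cigar == [("M", 75)]
        assert aln.score == 75 * 30
        assert aln.n_mismatch == 0
        assert aln.pos == 10

    def test_single_deletion_score(self, params, rng):
        local = np.random.default_rng(3)
        ref = "".join(local.choice(list("ACGT"), size=120))
        window = ref[20:95]  # 75 ref bases
        seq = window[:40] + window[41:]  # delete one base -> 74 bp read
        aln = extend_hit(oq_for(seq), ref, 20, params)
        assert ("D", 1) in aln.cigar
        assert aln.score == 74 * 30 - 46

    def test_bisulfite_asymmetry(self, params):
        # read T over ref C is a match in C2T space
        ref = "AAAACAAAAAAAGAAAAAAAAAA"
        seq = "AAAATAAAAAAAGAAAAAAA"
        aln = extend_hit(oq_for(seq), ref, 0, params)
        assert aln.n_mismatch == 0
        assert aln.score == len(seq) * 30
        # read C over ref T is a mismatch
        ref2 = "AAAATAAAAAAAGAAAAAAAAAA"
        seq2 = "AAAACAAAAAAAGAAAAAAA"
        aln2 = extend_hit(oq_for(seq2), ref2, 0, params)
        assert aln2.n_mismatch == 1

    def test_matches_exhaustive_oracle(self, params):
        """Random small instances against the full-matrix DP oracle."""
        local = np.random.default_rng(17)
        for _ in range(60):
            n = int(local.integers(5, 31))
            m = int(local.integers(n, 61))
            read = "".join(local.choice(list("ACGT"), size=n))
            window = "".join(local.choice(list("ACGT"), size=m))
            quals = [int(q) for q in local.integers(10, 41, size=n)]
            oq = OrientedQuery(read, read, quals, "+", "c2t", "C2T")
            aln = extend_hit(oq, window, 0, params, band=m + n)
            expected = affine_dp_score(read, quals, window, "c2t")
            assert aln is not None and aln.score == expected


class TestGateIndel:
    def _setup(self, rng_seed=5):
        local = np.random.default_rng(rng_seed)
        ref = "".join(local.choice(list("ACGT"), size=300))
        return ref

    def test_clean_read_skips_gapped(self, params):
        ref = self._setup()
        seq = list(ref[50:125])
        seq[10] = {"A": "G", "C": "G", "G": "T", "T": "G"}[seq[10]]
        seq = "".join(seq)
        oq = oq_for(seq)
        ungapped = extend_ungapped(oq, ref, 50, params)
        assert ungapped.n_mismatch == 1
        ungapped._ref_seq = ref
        aln = gate_indel(ungapped, oq, ref, 50, params)
        assert all(op == "M" for op, _ in aln.cigar)

    def test_indel_read_triggers_gapped(self, params):
        ref = self._setup()
        window = ref[50:127]
        seq = window[:30] + window[32:77]  # 2-base deletion
        oq = oq_for(seq)
        ungapped = extend_ungapped(oq, ref, 50, params)
        assert ungapped.n_mismatch >= params.mismatch_threshold
        aln = gate_indel(ungapped, oq, ref, 50, params)
        assert ("D", 2) in aln.cigar

    def test_threshold_boundary_runs_gapped(self, params):
        """n_mismatch == threshold opens the gate; best score wins."""
        ref = self._setup(11)
        seq = list(ref[40:115])
        for off in (10, 20):
            seq[off] = {"A": "G", "C": "G", "G": "T", "T": "G"}[seq[off]]
        seq = "".join(seq)
        oq = oq_for(seq)
        ungapped = extend_ungapped(oq, ref, 40, params)
        assert ungapped.n_mismatch == params.mismatch_threshold
        aln = gate_indel(ungapped, oq, ref, 40, params)
        # the gapped DP ran but cannot beat the 2-mismatch diagonal
        assert aln.score >= ungapped.score

    def test_no_indel_mode_never_gaps(self):
        params = AlignParams(indels=False)
        ref = self._setup()
        window = ref[50:127]
        seq = window[:30] + window[32:77]
        oq = oq_for(seq)
        ungapped = extend_ungapped(oq, ref, 50, params)
        aln = gate_indel(ungapped, oq, ref, 50, params)
        assert aln is None or all(op in "MS" for op, _ in aln.cigar)


class TestSoftClipRealign:
    def test_chimeric_read_gets_aux(self, params):
        local = np.random.default_rng(23)
        seq = "".join(local.choice(list("ACGT"), size=2000))
        genome = make_genome(seq)
        pair = convert_genome(genome)
        idx = build_index(pair, seed_len=12)
        chimera = seq[100:160] + seq[1000:1030]  # 60 bp at A + 30 bp at B
        read = Read("chi", chimera, [30] * 90)
        records = list(align([read], idx, params))
        primary = records[0]
        assert primary.pos == 100
        ops = samio.cigar_ops(primary.cigar)
        # junction may shift by a chance-matching base either side
        assert ops[0][0] == "M" and ops[0][1] >= 59
        assert ops[-1][0] == "S" and ops[-1][1] >= 28
        clip_len = ops[-1][1]
        assert len(records) == 2  # supplementary emitted
        supp = records[1]
        assert supp.flag & samio.FLAG_SUPPLEMENTARY
        assert supp.pos == 1030 - clip_len  # clip anchors at the chimera's end
        assert supp.cigar == f"{clip_len}M"

    def test_short_clip_not_realigned(self, params):
        local = np.random.default_rng(29)
        seq = "".join(local.choice(list("ACGT"), size=2000))
        genome = make_genome(seq)
        idx = build_index(convert_genome(genome), seed_len=12)
        chimera = seq[100:175] + seq[1000:1015]  # clip of 15 <= 20
        read = Read("chi", chimera, [30] * 90)
        records = list(align([read], idx, params))
        assert len(records) == 1

    def test_full_match_no_aux(self, indexed_genome, params):
        pair, idx = indexed_genome
        seq = pair.ref_seq("chr1")[500:600]
        read = Read("ok", seq, [30] * 100)
        records = list(align([read], idx, params))
        assert len(records) == 1
        assert records[0].cigar == "100M"


class TestComputeMapq:
    def _aln(self, score, quals=None):
        oq = OrientedQuery("A" * 10, "A" * 10, quals or [30] * 10, "+", "c2t", "C2T")
        return Alignment("r", "chr1", 0, "+", "C2T", [("M", 10)], 0, score, query=oq)

    def test_unique_hit_is_60(self):
        assert compute_mapq(self._aln(300), None) == 60

    def test_co_optimal_is_0(self):
        assert compute_mapq(self._aln(300), 300) == 0

    def test_monotone_in_gap(self, rng):
        local = np.random.default_rng(31)
        for _ in range(200):
            s2 = int(local.integers(0, 2000))
            g1 = int(local.integers(0, 3000))
            g2 = g1 + int(local.integers(0, 3000))
            m_small = compute_mapq(self._aln(s2 + g1), s2)
            m_big = compute_mapq(self._aln(s2 + g2), s2)
            assert m_big >= m_small

    def test_capped_at_60(self):
        assert compute_mapq(self._aln(10**6), 0) == 60


class TestDeepScanPair:
    def _aln(self, chrom, pos, strand, score):
        oq = OrientedQuery("A" * 50, "A" * 50, [30] * 50, strand, "c2t", "C2T")
        return Alignment("r", chrom, pos, strand, "C2T", [("M", 50)], 0, score, query=oq)

    def test_unique_proper_pair(self):
        p = deep_scan_pair(
            [self._aln("chr1", 100, "+", 900)], [self._aln("chr1", 400, "-", 900)]
        )
        assert p.proper and p.insert == 350

    def test_second_best_makes_proper_pair(self):
        """A nearby weaker hit beats the distant individual best."""
        h1 = [self._aln("chr1", 3_000_000, "+", 900), self._aln("chr1", 100, "+", 840)]
        h2 = [self._aln("chr1", 400, "-", 900)]
        p = deep_scan_pair(h1, h2)
        assert p.proper
        assert p.a1.pos == 100

    def test_no_proper_returns_improper_bests(self):
        h1 = [self._aln("chr1", 100, "+", 900)]
        h2 = [self._aln("chr2", 400, "-", 900)]
        p = deep_scan_pair(h1, h2)
        assert not p.proper
        assert p.a1.pos == 100 and p.a2.pos == 400

    def test_single_mapped_mate(self):
        p = deep_scan_pair([self._aln("chr1", 100, "+", 900)], [])
        assert p.a1 is not None and p.a2 is None and not p.proper

    def test_same_strand_never_proper(self):
        p = deep_scan_pair(
            [self._aln("chr1", 100, "+", 900)], [self._aln("chr1", 400, "+", 900)]
        )
        assert not p.proper


class TestAlignEndToEnd:
    def test_zero_error_read_maps_exactly(self, indexed_genome, params):
        pair, idx = indexed_genome
        seq = pair.ref_seq("chr1")[7000:7100]
        records = list(align([Read("a", seq, [30] * 100)], idx, params))
        assert records[0].pos == 7000
        assert records[0].cigar == "100M"
        assert records[0].mapq == 60

    def test_reverse_strand_read(self, indexed_genome, params):
        pair, idx = indexed_genome
        seq = revcomp(pair.ref_seq("chr1")[7000:7100])
        records = list(align([Read("a", seq, [30] * 100)], idx, params))
        assert records[0].pos == 7000
        assert records[0].flag & samio.FLAG_REVERSE

    def test_bisulfite_converted_read_maps(self, indexed_genome, params):
        pair, idx = indexed_genome
        seq = pair.ref_seq("chr1")[7000:7100].replace("C", "T")
        rec = list(align([Read("a", seq, [30] * 100)], idx, params))[0]
        assert rec.pos == 7000
        tags = dict((t[0], t[2]) for t in [tuple(x.split(":")) for x in []])
        assert "NM:i:0" in rec.to_line()
        assert "XB:Z:C2T" in rec.to_line()

    def test_planted_deletion_in_cigar(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        window = ref[8000:8104]
        seq = window[:50] + window[54:104]  # 4-base deletion at offset 50
        rec = list(align([Read("a", seq, [30] * 100)], idx, params))[0]
        assert "4D" in rec.cigar
        assert rec.pos == 8000

    def test_pure_n_read_unmapped(self, indexed_genome, params):
        rec = list(align([Read("n", "N" * 80, [2] * 80)], indexed_genome[1], params))[0]
        assert rec.flag & samio.FLAG_UNMAPPED

    def test_cigar_conservation(self, indexed_genome, params, rng):
        """M+I+S lengths sum to read length for every emitted record."""
        pair, idx = indexed_genome
        local = np.random.default_rng(41)
        reads = []
        ref = pair.ref_seq("chr1")
        for i in range(30):
            start = int(local.integers(0, len(ref) - 110))
            seq = list(ref[start : start + 100])
            for _ in range(int(local.integers(0, 4))):
                off = int(local.integers(0, 100))
                seq[off] = "ACGT"[int(local.integers(0, 4))]
            reads.append(Read(f"r{i}", "".join(seq), [30] * 100))
        for rec in align(reads, idx, params):
            if rec.flag & samio.FLAG_UNMAPPED:
                continue
            assert samio.cigar_read_length(rec.cigar) == len(rec.seq)

    def test_determinism(self, indexed_genome, params):
        pair, idx = indexed_genome
        local = np.random.default_rng(43)
        ref = pair.ref_seq("chr1")
        reads = [
            Read(f"r{i}", ref[int(local.integers(0, 10_000)) :][:100], [30] * 100)
            for i in range(20)
        ]
        out1 = [r.to_line() for r in align(reads, idx, params)]
        out2 = [r.to_line() for r in align(reads, idx, params)]
        assert out1 == out2

    def test_gate_never_lowers_score(self, indexed_genome):
        """Enabling indel detection never lowers any read's score."""
        pair, idx = indexed_genome
        local = np.random.default_rng(47)
        ref = pair.ref_seq("chr1")
        reads = []
        for i in range(25):
            start = int(local.integers(0, len(ref) - 120))
            window = ref[start : start + 104]
            if i % 2:
                seq = window[:50] + window[52:102]  # deletion
            else:
                seq = list(window[:100])
                for off in (10, 40, 70):
                    seq[off] = "ACGT"[int(local.integers(0, 4))]
                seq = "".join(seq)
            reads.append(Read(f"r{i}", seq, [30] * 100))

        def scores(indels):
            out = {}
            for rec in align(reads, idx, AlignParams(indels=indels)):
                if rec.flag & (samio.FLAG_UNMAPPED | samio.FLAG_SUPPLEMENTARY):
                    continue
                score = int(rec.to_line().split("AS:i:")[1].split("\t")[0])
                out[rec.qname] = score
            return out

        s_off, s_on = scores(False), scores(True)
        for name, sc in s_off.items():
            assert s_on.get(name, sc) >= sc


class TestAlignPaired:
    def test_proper_pair_flags(self, indexed_genome, params):
        pair, idx = indexed_genome
        ref = pair.ref_seq("chr1")
        r1 = Read("p", ref[2000:2100], [30] * 100, mate=1)
        r2 = Read("p", revcomp(ref[2300:2400]), [30] * 100, mate=2)
        recs = list(align_paired([(r1, r2)], idx, params))
        assert len(recs) == 2
        assert all(r.flag & samio.FLAG_PAIRED for r in recs)
        assert all(r.flag & samio.FLAG_PROPER for r in recs)
        assert recs[0].pos == 2000 and recs[1].pos == 2300
        assert recs[0].tlen == 400 and recs[1].tlen == -400
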