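"""Contig re-alignment, CIGAR walking, size filter, dedup and VCF I/O."""

import numpy as np
import pytest

from blackbird.assembler import Contig
from blackbird.segmentation import ReferenceGenome
from blackbird.sv_call import (ContigAlignment, SVCall, align_contigs,
                               calls_from_alignment, deduplicate, filter_calls,
                               left_normalize, read_vcf, write_vcf)

from conftest import random_dna


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(42)
    return ReferenceGenome({"chrT": random_dna(rng, 30_000)})


def contig_of(seq, name="c1", seg=None):
    return Contig(name, seq, (0,), seg)


class TestAlign:
    def test_exact_copy_full_match(self, reference):
        seg = reference["chrT"][5_000:9_000]
        (aln,) = align_contigs([contig_of(seg)], reference)
        assert aln.target_start == 5_000
        assert aln.strand == "+"
        assert [op for op, _ in aln.cigar] == ["="]

    def test_excision_yields_single_d_op(self, reference):
        R = reference["chrT"]
        contig = R[5_000:7_000] + R[7_100:9_000]
        (aln,) = align_contigs([contig_of(contig)], reference)
        d_ops = [(op, n) for op, n in aln.cigar if op == "D"]
        assert d_ops == [("D", 100)]

    def test_insertion_yields_single_i_op(self, reference):
        rng = np.random.default_rng(1)
        R = reference["chrT"]
        contig = R[5_000:7_000] + random_dna(rng, 300) + R[7_000:9_000]
        (aln,) = align_contigs([contig_of(contig)], reference)
        i_ops = [(op, n) for op, n in aln.cigar if op == "I"]
        assert i_ops == [("I", 300)]

    def test_reverse_strand_contig_normalized(self, reference):
        from blackbird.dna import revcomp
        contig = revcomp(reference["chrT"][5_000:9_000])
        (aln,) = align_contigs([contig_of(contig)], reference)
        assert aln.strand == "-"
        assert aln.target_start == 5_000
        assert aln.query_seq == reference["chrT"][5_000:9_000]

    def test_unplaceable_contig_dropped(self, reference):
        rng = np.random.default_rng(2)
        junk = random_dna(rng, 1_000)
        assert align_contigs([contig_of(junk)], reference) == []

    def test_minimap2_backend_agrees_on_indels(self, reference):
        import shutil
        if shutil.which("minimap2") is None:
            pytest.skip("minimap2 binary not on PATH")
        rng = np.random.default_rng(3)
        R = reference["chrT"]
        contig = (R[2_000:6_000] + random_dna(rng, 250)
                  + R[6_000:10_000][: -1] + R[10_000 - 1:14_000])
        contig2 = R[14_000:18_000] + R[18_400:22_000]
        calls = {}
        for backend in ("builtin", "minimap2"):
            alns = align_contigs([contig_of(contig, "a"), contig_of(contig2, "b")],
                                 reference, backend=backend)
            got = []
            for aln in alns:
                got += [c.key() for c in calls_from_alignment(aln, reference)
                        if c.length >= 50]
            calls[backend] = sorted(got)
        assert calls["builtin"] == calls["minimap2"]


class TestCigarWalk:
    def test_deletion_coordinates(self, reference):
        aln = ContigAlignment("c", "A" * 200, "chrT", 1_000, "+",
                              (("=", 100), ("D", 50), ("=", 100)))
        (call,) = calls_from_alignment(aln, reference, normalize=False)
        assert (call.svtype, call.pos, call.length) == ("DEL", 1_100, 50)
        assert call.seq == reference["chrT"][1_100:1_150]

    def test_insertion_coordinates(self, reference):
        query = "A" * 100 + "G" * 300 + "T" * 100
        aln = ContigAlignment("c", query, "chrT", 1_000, "+",
                              (("=", 100), ("I", 300), ("=", 100)))
        (call,) = calls_from_alignment(aln, reference, normalize=False)
        assert (call.svtype, call.pos, call.length) == ("INS", 1_100, 300)
        assert call.seq == "G" * 300

    def test_sub_threshold_event_still_emitted_here(self, reference):
        aln = ContigAlignment("c", "A" * 200, "chrT", 1_000, "+",
                              (("=", 100), ("D", 49), ("=", 100)))
        (call,) = calls_from_alignment(aln, reference)
        assert call.length == 49          # dropped later by the size filter

    def test_soft_clips_consume_query_only(self, reference):
        aln = ContigAlignment("c", "A" * 250, "chrT", 2_000, "+",
                              (("S", 30), ("=", 200), ("S", 20)))
        assert calls_from_alignment(aln, reference) == []

    def test_inconsistent_cigar_skipped(self, reference):
        aln = ContigAlignment("c", "A" * 100, "chrT", 2_000, "+",
                              (("=", 90),))
        assert calls_from_alignment(aln, reference) == []

    def test_left_normalization_shifts_through_repeat(self):
        ref = ReferenceGenome({"c": "GGGG" + "AT" * 10 + "CCGG"})
        # deleting the last AT is equivalent to deleting the first
        call = SVCall("DEL", "c", 4 + 18, 2, "AT")
        norm = left_normalize(call, ref["c"])
        assert norm.pos == 4 and norm.seq == "AT"


def _dp_align(query, target):
    """Unit-cost global alignment (quadratic DP) with leftmost traceback."""
    n, m = len(query), len(target)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[0, :] = np.arange(m + 1)
    D[:, 0] = np.arange(n + 1)
    q = np.frombuffer(query.encode(), dtype="S1")
    t = np.frombuffer(target.encode(), dtype="S1")
    idx = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = D[i - 1, :-1] + (q[i - 1] != t)
        up = D[i - 1, 1:] + 1
        row = np.minimum(sub, up)
        # horizontal moves folded in via a prefix-min over (value - column)
        cand = np.concatenate(([D[i, 0]], row))
        best = np.minimum.accumulate(cand - idx) + idx
        D[i, 1:] = best[1:]
    # state-aware traceback: unit-cost optima are not unique (a gap run can
    # tie with a fragmented run threading accidental matches), so keep the
    # current gap open while it stays optimal and prefer exact matches
    # otherwise — this picks the contiguous-indel representative
    ops = []
    i, j = n, m
    state = None
    while i > 0 or j > 0:
        match = i > 0 and j > 0 and query[i - 1] == target[j - 1]
        can_diag = (i > 0 and j > 0
                    and D[i, j] == D[i - 1, j - 1] + (0 if match else 1))
        can_i = i > 0 and D[i, j] == D[i - 1, j] + 1
        can_d = j > 0 and D[i, j] == D[i, j - 1] + 1
        if state == "I" and can_i:
            op = "I"
        elif state == "D" and can_d:
            op = "D"
        elif can_diag and match:
            op = "="
        elif can_d:
            op = "D"
        elif can_i:
            op = "I"
        else:
            op = "X"
        if op == "I":
            i -= 1
        elif op == "D":
            j -= 1
        else:
            i -= 1
            j -= 1
        ops.append(op)
        state = op if op in "ID" else None
    ops.reverse()
    merged = []
    for op in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += 1
        else:
            merged.append([op, 1])
    return [(op, n_) for op, n_ in merged]


class TestCoordinateOracle:
    def test_against_quadratic_dp(self):
        """Indel positions/lengths from the anchor-chain aligner match a
        brute-force DP alignment on small instances."""
        rng = np.random.default_rng(11)
        for trial in range(25):
            target = random_dna(rng, 900)
            # keep >= 100 bp of flank on both sides of the event
            L = int(rng.integers(50, 301))
            p = int(rng.integers(150, 800 - L))
            if trial % 2 == 0:
                query = target[:p] + random_dna(rng, L) + target[p:]
            else:
                query = target[:p] + target[p + L:]
            ref = ReferenceGenome({"c": target})
            (aln,) = align_contigs([contig_of(query)], ref)
            got = [left_normalize(c, target)
                   for c in calls_from_alignment(aln, ref)
                   if c.length >= 50]
            dp_aln = ContigAlignment("c", query, "c", 0, "+",
                                     tuple(_dp_align(query, target)))
            expected = [left_normalize(c, target)
                        for c in calls_from_alignment(dp_aln, ref)
                        if c.length >= 50]
            assert [(c.svtype, c.pos, c.length) for c in got] == \
                [(c.svtype, c.pos, c.length) for c in expected]


class TestFilterDedup:
    def test_size_window_is_inclusive(self):
        calls = [SVCall("DEL", "c", 10, n, "A" * n)
                 for n in (49, 50, 10_000, 10_001)]
        kept = filter_calls(calls)
        assert [c.length for c in kept] == [50, 10_000]

    def test_empty(self):
        assert filter_calls([]) == []

    def test_exact_duplicates_collapse(self):
        a = SVCall("DEL", "c", 100, 60, "A" * 60, contig_id="x")
        b = SVCall("DEL", "c", 100, 60, "A" * 60, contig_id="y")
        assert len(deduplicate([a, b])) == 1

    def test_different_length_kept(self):
        a = SVCall("DEL", "c", 100, 60, "A" * 60)
        b = SVCall("DEL", "c", 100, 61, "A" * 61)
        assert len(deduplicate([a, b])) == 2

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        calls = [SVCall(("DEL", "INS")[int(rng.integers(2))], "c",
                        int(rng.integers(5)) * 100 + 100,
                        int(rng.integers(3)) + 60, "")
                 for _ in range(50)]
        once = deduplicate(calls)
        assert deduplicate(once) == once
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert deduplicate(shuffled) == once

    def test_slack_collapses_nearby_same_length(self):
        a = SVCall("DEL", "c", 100, 60, "")
        b = SVCall("DEL", "c", 104, 60, "")
        assert len(deduplicate([a, b], slack=0)) == 2
        assert len(deduplicate([a, b], slack=5)) == 1


class TestVcf:
    def _roundtrip(self, tmp_path, calls, reference):
        path = str(tmp_path / "out.vcf")
        write_vcf(calls, reference, path, params_line="test=1")
        return path, read_vcf(path)

    def test_del_ins_spelling(self, tmp_path, reference):
        R = reference["chrT"]
        calls = [
            SVCall("DEL", "chrT", 1_000, 50, R[1_000:1_050]),
            SVCall("INS", "chrT", 2_000, 300, "G" * 300),
        ]
        path, back = self._roundtrip(tmp_path, calls, reference)
        text = open(path).read()
        assert "##blackbird_params=test=1" in text
        assert "##contig=<ID=chrT,length=30000>" in text
        dele, ins = back
        assert (dele.svtype, dele.pos, dele.length) == ("DEL", 1_000, 50)
        assert dele.seq == R[1_000:1_050]
        assert (ins.svtype, ins.pos, ins.length) == ("INS", 2_000, 300)
        assert ins.seq == "G" * 300
        # spot-check the raw records: anchor-base spelling and SVLEN signs
        lines = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
        assert len(lines[0][3]) == 51 and len(lines[0][4]) == 1
        assert "SVLEN=-50" in lines[0][7]
        assert len(lines[1][3]) == 1 and len(lines[1][4]) == 301
        assert "SVLEN=300" in lines[1][7]

    def test_event_at_position_zero_uses_following_base(self, tmp_path, reference):
        R = reference["chrT"]
        calls = [SVCall("DEL", "chrT", 0, 60, R[0:60])]
        path, back = self._roundtrip(tmp_path, calls, reference)
        line = [l for l in open(path) if not l.startswith("#")][0].split("\t")
        assert line[1] == "1"
        assert line[3] == R[0:60] + R[60]
        assert line[4] == R[60]

    def test_empty_callset_header_only(self, tmp_path, reference):
        path, back = self._roundtrip(tmp_path, [], reference)
        assert back == []
        assert all(l.startswith("#") for l in open(path))

    def test_genotypes_roundtrip(self, tmp_path, reference):
        R = reference["chrT"]
        calls = [SVCall("DEL", "chrT", 500, 55, R[500:555],
                        genotype=(1, 0), phased=True),
                 SVCall("DEL", "chrT", 900, 55, R[900:955])]
        _, back = self._roundtrip(tmp_path, calls, reference)
        assert back[0].genotype == (1, 0) and back[0].phased
        assert back[1].genotype in (None, (None,))

    def test_sorted_output(self, tmp_path, reference):
        R = reference["chrT"]
        calls = [SVCall("DEL", "chrT", p, 55, R[p:p + 55])
                 for p in (5_000, 1_000, 3_000)]
        _, back = self._roundtrip(tmp_path, calls, reference)
        assert [c.pos for c in back] == [1_000, 3_000, 5_000]
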