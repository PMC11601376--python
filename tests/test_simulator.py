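"""Synthetic data generator: determinism, truth bookkeeping, read models."""

import dataclasses
import hashlib

import edlib
import numpy as np
import pysam
import pytest
from scipy import stats

from blackbird.simulator import (SimConfig, SVSpec, _apply_long_errors,
                                 implant_svs, make_reference,
                                 reconstruct_haplotypes, sample_svs, simulate,
                                 simulate_linked_reads, simulate_long_reads)
from blackbird.sv_call import read_vcf

SMALL = SimConfig(genome_length=60_000, n_del=2, n_ins_random=2,
                  n_ins_mobile=1, n_ins_tandem=1, sv_len_max=1_000,
                  placement_margin=4_000, seed=9)


def md5(path):
    return hashlib.md5(open(path, "rb").read()).hexdigest()


class TestReference:
    def test_deterministic_per_seed(self):
        a = make_reference(SMALL)
        b = make_reference(SMALL)
        assert a.sequences == b.sequences
        c = make_reference(dataclasses.replace(SMALL, seed=10))
        assert c.sequences != a.sequences

    def test_gc_content_near_target(self):
        cfg = dataclasses.replace(SMALL, genome_length=200_000, gc=0.5)
        ref = make_reference(cfg)
        seq = ref["ctg1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_repeat_copies_implanted(self):
        cfg = dataclasses.replace(SMALL, repeat_copies=2, repeat_unit_len=1_000,
                                  repeat_positions=[10_000, 20_000])
        ref = make_reference(cfg)
        donor = ref["ctg1"][10_000:11_000]
        assert ref["ctg1"][20_000:21_000] == donor


class TestImplant:
    def test_hom_del_shrinks_both_haplotypes(self):
        ref = make_reference(SMALL)
        spec = SVSpec("DEL", "ctg1", 20_000, 500, zygosity="hom")
        haps, _, _ = implant_svs(ref, [spec])
        assert all(len(h) == 60_000 - 500 for h in haps["ctg1"])

    def test_het_ins_lengthens_one_haplotype(self):
        ref = make_reference(SMALL)
        spec = SVSpec("INS", "ctg1", 20_000, 300, zygosity="het", hap=1,
                      seq="A" * 300)
        haps, _, _ = implant_svs(ref, [spec])
        assert len(haps["ctg1"][0]) == 60_000
        assert len(haps["ctg1"][1]) == 60_300

    def test_length_bookkeeping_oracle(self):
        """Haplotype length deltas equal the signed sums of event lengths."""
        cfg = dataclasses.replace(SimConfig(), seed=21)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference(cfg, rng)
        specs = sample_svs(cfg, ref, rng)
        assert len(specs) == 30
        haps, _, _ = implant_svs(ref, specs)
        for hap in (0, 1):
            expected = sum(
                (s.length if s.svtype == "INS" else -s.length)
                for s in specs if s.genotype()[hap] == 1)
            assert len(haps["ctg1"][hap]) - len(ref["ctg1"]) == expected

    def test_overlapping_specs_rejected(self):
        ref = make_reference(SMALL)
        specs = [SVSpec("DEL", "ctg1", 20_000, 500),
                 SVSpec("INS", "ctg1", 20_100, 100, seq="A" * 100)]
        with pytest.raises(ValueError):
            implant_svs(ref, specs)

    def test_truth_roundtrip_exact(self, tmp_path):
        sim = simulate(SMALL, str(tmp_path / "s"))
        truth = read_vcf(sim.truth_vcf)
        rebuilt = reconstruct_haplotypes(sim.reference, truth)
        assert rebuilt == sim.haplotypes


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    return simulate(SMALL, str(tmp_path_factory.mktemp("lr") / "s"))


class TestLinkedReads:
    def test_coverage_accounting(self):
        # at >= a few fragment lengths of genome, read bases track coverage
        cfg = dataclasses.replace(SMALL, genome_length=200_000, seed=29)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference(cfg, rng)
        haps, maps, _ = implant_svs(ref, [])
        _, frags = simulate_linked_reads(haps, maps, cfg, rng)
        total = sum(f.n_pairs for f in frags) * 2 * cfg.read_len
        expected = cfg.slr_coverage * cfg.genome_length
        assert abs(total - expected) / expected < 0.10

    def test_fragment_length_bounds(self, sim):
        lengths = [f.length for f in sim.fragments]
        assert min(lengths) >= SMALL.fragment_len_min
        assert max(lengths) <= SMALL.fragment_len_max

    def test_fragment_drawn_lengths_uniform(self):
        cfg = dataclasses.replace(SMALL, genome_length=150_000, seed=30)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference(cfg, rng)
        haps, maps, _ = implant_svs(ref, [])
        _, frags = simulate_linked_reads(haps, maps, cfg, rng)
        draws = np.array([f.drawn_length for f in frags])
        span = cfg.fragment_len_max + 1 - cfg.fragment_len_min
        pvalue = stats.kstest(
            (draws - cfg.fragment_len_min) / span, "uniform").pvalue
        assert pvalue > 0.01

    def test_reads_per_fragment_rate(self, sim):
        lam = np.array([f.length * SMALL.fragment_read_coverage
                        / (2 * SMALL.read_len) for f in sim.fragments])
        counts = np.array([f.n_pairs for f in sim.fragments])
        total, expect = counts.sum(), lam.sum()
        # Poisson totals concentrate: 5 sigma band
        assert abs(total - expect) <= 5 * np.sqrt(expect)

    def test_barcodes_unique_per_fragment(self, sim):
        barcodes = [f.barcode for f in sim.fragments]
        assert len(set(barcodes)) == len(barcodes)

    def test_reads_share_fragment_barcode_and_span(self, sim):
        by_bx = {}
        with pysam.AlignmentFile(sim.bam) as bam:
            for rec in bam.fetch(until_eof=True):
                if not rec.is_unmapped:
                    by_bx.setdefault(rec.get_tag("BX"), []).append(
                        rec.reference_start)
        frag = {f.barcode: f for f in sim.fragments}
        for bx, positions in by_bx.items():
            f = frag[bx]
            # positions are reference-projected; net SV shifts stay < 3 kbp
            assert max(positions) - min(positions) <= f.length + 3_000

    def test_breakpoint_reads_are_clipped_or_unmapped(self, sim):
        ins = [c for c in sim.truth if c.svtype == "INS"][0]
        window = (ins.pos - 100, ins.pos + 100)
        flagged = 0
        with pysam.AlignmentFile(sim.bam) as bam:
            for rec in bam.fetch("ctg1", *window):
                if rec.is_unmapped:
                    flagged += 1
                    continue
                clip = sum(n for op, n in rec.cigartuples or () if op == 4)
                if clip / rec.query_length > 0.2:
                    flagged += 1
        assert flagged >= 3

    def test_dropout_interval_has_zero_reads(self, tmp_path):
        cfg = dataclasses.replace(SMALL, dropouts=[("ctg1", 30_000, 30_500)])
        sim = simulate(cfg, str(tmp_path / "d"))
        with pysam.AlignmentFile(sim.bam) as bam:
            n = sum(1 for rec in bam.fetch("ctg1", 30_000, 30_500)
                    if not rec.is_unmapped
                    and rec.reference_start < 30_500
                    and rec.reference_end > 30_000)
        assert n == 0

    def test_fastq_export(self, tmp_path):
        sim = simulate(SMALL, str(tmp_path / "f"), fastq=True)
        r1 = (tmp_path / "f" / "reads_R1.fastq").read_text().splitlines()
        assert r1[0].startswith("@") and " BX:Z:" in r1[0]
        assert len(r1) % 4 == 0


class TestLongReads:
    def test_lengths_within_bounds_and_count(self):
        cfg = dataclasses.replace(SMALL, genome_length=200_000,
                                  long_coverage=5.0, seed=31)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference(cfg, rng)
        haps, maps, _ = implant_svs(ref, [])
        reads = simulate_long_reads(haps, maps, cfg, rng)
        assert all(9_000 <= len(r.seq) <= 12_600 for r in reads)  # +1% ins errors
        expected = 5.0 * 200_000 / 10_500
        assert abs(len(reads) - expected) / expected < 0.20

    def test_error_rate_matches_edit_distance(self):
        rng = np.random.default_rng(32)
        from conftest import random_dna
        source = random_dna(rng, 10_000)
        mutated, _ = _apply_long_errors(source, [("M", 10_000)], 0.01, rng)
        dist = edlib.align(mutated, source, mode="NW")["editDistance"]
        assert abs(dist - 100) <= 30

    def test_error_cigar_consistent_with_sequence(self):
        rng = np.random.default_rng(33)
        from conftest import random_dna
        source = random_dna(rng, 5_000)
        mutated, ops = _apply_long_errors(source, [("M", 5_000)], 0.01, rng)
        q_len = sum(n for op, n in ops if op in "MIS")
        assert q_len == len(mutated)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, tmp_path):
        a = simulate(SMALL, str(tmp_path / "a"))
        b = simulate(SMALL, str(tmp_path / "b"))
        for attr in ("ref_fasta", "truth_vcf"):
            assert md5(getattr(a, attr)) == md5(getattr(b, attr))
        assert md5(a.bam) == md5(b.bam)

    def test_different_seed_differs(self, tmp_path):
        a = simulate(SMALL, str(tmp_path / "a"))
        c = simulate(dataclasses.replace(SMALL, seed=10), str(tmp_path / "c"))
        assert md5(a.truth_vcf) != md5(c.truth_vcf)
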