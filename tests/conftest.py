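"""Shared fixtures: synthetic BAM construction and session-scoped datasets.

The expensive end-to-end datasets (full benchmark genome, hybrid dropout
scenario) are built once per session and shared by the pipeline and
acceptance tests.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pysam
import pytest

from blackbird.config import RunConfig
from blackbird.pipeline import run_call
from blackbird.simulator import SimConfig, make_reference, sample_svs, simulate
from blackbird.sv_call import read_vcf


@dataclass
class BamRead:
    """Declarative spec for one record in a synthetic test BAM."""

    name: str
    seq: str
    contig: Optional[str] = "chr1"
    pos: int = 0
    cigar: Optional[str] = None      # default: all-M
    qual: int = 30
    quals: Optional[List[int]] = None
    bx: Optional[str] = None
    am: Optional[int] = None
    is_read1: bool = True
    unmapped: bool = False
    mate_contig: Optional[str] = None
    mate_pos: int = -1
    mate_unmapped: bool = False
    paired: bool = True
    secondary: bool = False
    no_qual: bool = False


def write_test_bam(path, reads: List[BamRead],
                   contigs: Dict[str, int] = None) -> str:
    contigs = contigs or {"chr1": 1_000_000, "chrUn_x": 100_000}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs.items()],
    })
    tid = {n: i for i, n in enumerate(contigs)}
    records = []
    for r in reads:
        rec = pysam.AlignedSegment(header)
        rec.query_name = r.name
        rec.query_sequence = r.seq
        if not r.no_qual:
            rec.query_qualities = r.quals if r.quals is not None \
                else [r.qual] * len(r.seq)
        flag = 0
        if r.paired:
            flag |= 0x1 | (0x40 if r.is_read1 else 0x80)
        if r.unmapped:
            flag |= 0x4
        if r.mate_unmapped:
            flag |= 0x8
        if r.secondary:
            flag |= 0x100
        rec.flag = flag
        if r.contig is not None:
            rec.reference_id = tid[r.contig]
            rec.reference_start = r.pos
        if not r.unmapped:
            rec.cigarstring = r.cigar or f"{len(r.seq)}M"
            rec.mapping_quality = 60
        if r.mate_contig is not None:
            rec.next_reference_id = tid[r.mate_contig]
            rec.next_reference_start = r.mate_pos
        elif r.contig is not None:
            rec.next_reference_id = tid[r.contig]
            rec.next_reference_start = r.pos
        if r.bx is not None:
            rec.set_tag("BX", r.bx)
        if r.am is not None:
            rec.set_tag("AM", r.am)
        records.append(rec)
    records.sort(key=lambda x: (x.reference_id if x.reference_id >= 0 else 1 << 30,
                                x.reference_start, x.query_name))
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(path)
    return path


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# session datasets
# ---------------------------------------------------------------------------

#: Study conditions of the end-to-end benchmark: 300 kbp genome, 30 SVs
#: (10 DEL, 10 random INS, 5 mobile-element-like, 5 tandem-like; half het),
#: 40x error-free linked reads.
BENCH_SEED = 1


@dataclass
class EndToEnd:
    sim: object
    calls: list
    truth: list
    call_seconds: float
    vcf_path: str


@pytest.fixture(scope="session")
def bench_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("bench")
    sim = simulate(SimConfig(seed=BENCH_SEED), str(out))
    return sim


@pytest.fixture(scope="session")
def bench_run(bench_dataset, tmp_path_factory) -> EndToEnd:
    out = tmp_path_factory.mktemp("bench_run")
    vcf = str(out / "calls.vcf")
    config = RunConfig(primary_contigs=["ctg1"])
    t0 = time.monotonic()
    run_call(bench_dataset.bam, bench_dataset.ref_fasta, vcf, config)
    elapsed = time.monotonic() - t0
    return EndToEnd(bench_dataset, read_vcf(vcf), read_vcf(bench_dataset.truth_vcf),
                    elapsed, vcf)


@dataclass
class HybridScenario:
    sim: object
    targets: list              # the three dropout-affected SV specs
    slr_calls: list
    hybrid_calls: list
    truth: list
    seconds: float


@pytest.fixture(scope="session")
def hybrid_run(tmp_path_factory) -> HybridScenario:
    """Benchmark genome with three 500 bp dropouts over homozygous SVs,
    plus 5x long reads (0.1-1 % error)."""
    out = tmp_path_factory.mktemp("hybrid")
    base = SimConfig(seed=BENCH_SEED)
    rng = np.random.default_rng(BENCH_SEED)
    ref = make_reference(base, rng)
    specs = sample_svs(base, ref, rng)
    targets = [s for s in specs
               if str(s.zygosity) == "hom" and s.length <= 2000][:3]
    drops = [("ctg1", s.pos - 100, s.pos + 400) for s in targets]
    cfg = dataclasses.replace(base, dropouts=drops, long_coverage=5.0)
    sim = simulate(cfg, str(out))
    config = RunConfig(primary_contigs=["ctg1"])
    t0 = time.monotonic()
    run_call(sim.bam, sim.ref_fasta, str(out / "slr.vcf"), config)
    run_call(sim.bam, sim.ref_fasta, str(out / "hyb.vcf"), config,
             long_bam_path=sim.long_bam)
    elapsed = time.monotonic() - t0
    return HybridScenario(sim, targets,
                          read_vcf(str(out / "slr.vcf")),
                          read_vcf(str(out / "hyb.vcf")),
                          read_vcf(sim.truth_vcf), elapsed)
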