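"""Fully synthetic, ground-truthed linked-read / long-read data.

The simulator emulates the data model the caller consumes:

* a random diploid genome with implanted insertions and deletions
  (50–10,000 bp), in three insertion classes — random sequence,
  mobile-element-like (a fixed synthetic 300 bp donor reused across events,
  so inserted copies are repetitive genome-wide, as Alu copies are; a 6 kbp
  donor is available for L1-like events) and tandem-repeat-like (a novel
  motif expanded to several copies);
* fragment-based linked reads: long fragments (5–100 kbp) sheared from one
  haplotype, one barcode per fragment, paired short reads sampled within
  the fragment at low per-fragment coverage;
* HiFi-like long reads (9,000–12,000 bp, 0.1–1 % per-base error split
  60/20/20 between substitutions, insertions and deletions).

Reads are emitted as an already-aligned, coordinate-sorted, indexed BAM via
a *projection aligner*: each read knows its true origin, and its alignment
is the projection of that origin onto reference coordinates.  Reads
crossing an SV breakpoint come out soft-clipped, and reads from inserted
sequence come out as placed-unmapped records — the alignment signatures the
bad-read rules key on.  Optional dropout intervals produce no reads at all,
emulating the coverage gaps of real SLR libraries.  A ``fastq`` option
additionally exports raw reads (BX in the comment) for use with a real
aligner.

Everything is driven by one seeded generator: identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
import yaml

from .dna import revcomp
from .segmentation import ReferenceGenome
from .sv_call import SVCall, write_vcf

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SVSpec:
    """A planned insertion or deletion on the original reference."""

    svtype: str                # 'DEL' | 'INS'
    contig: str
    pos: int                   # 0-based: start of deleted span / insertion point
    length: int
    insert_class: str = "random"   # 'random' | 'mobile' | 'tandem' (INS only)
    zygosity: str = "hom"          # 'hom' | 'het'
    hap: int = 0                   # haplotype carrying a het event
    seq: str = ""                  # inserted sequence (INS)

    def genotype(self) -> Tuple[int, int]:
        if self.zygosity == "hom":
            return (1, 1)
        return (1, 0) if self.hap == 0 else (0, 1)


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment (defaults = the
    end-to-end benchmark scenario; see docs/methods.md)."""

    # genome
    genome_length: int = 300_000
    n_contigs: int = 1
    gc: float = 0.5
    repeat_copies: int = 0          # implanted copies of one repeat donor
    repeat_unit_len: int = 2_000
    repeat_positions: Optional[List[int]] = None
    # SV mix
    n_del: int = 10
    n_ins_random: int = 10
    n_ins_mobile: int = 5
    n_ins_tandem: int = 5
    het_fraction: float = 0.5
    sv_len_min: int = 50
    sv_len_max: int = 5_000
    mobile_donor_len: int = 300
    tandem_motif_len: int = 60
    tandem_copies_min: int = 3
    tandem_copies_max: int = 8
    min_event_gap: int = 1_000
    placement_margin: int = 6_000
    fixed_svs: Optional[List[dict]] = None   # explicit SVSpec dicts instead of sampling
    # linked reads
    read_len: int = 150
    insert_mean: int = 350
    insert_sd: int = 35
    slr_coverage: float = 40.0
    slr_error_rate: float = 0.0
    fragment_len_min: int = 5_000
    fragment_len_max: int = 100_000
    fragment_read_coverage: float = 0.2     # read coverage within one fragment
    barcode_collision_rate: float = 0.0
    base_quality: int = 40
    # long reads
    long_read_len_min: int = 9_000
    long_read_len_max: int = 12_000
    long_error_min: float = 0.001
    long_error_max: float = 0.01
    long_coverage: float = 0.0
    # dropouts: (contig, start, end) reference intervals with zero linked reads
    dropouts: List[Tuple[str, int, int]] = field(default_factory=list)
    seed: int = 1

    def validate(self) -> None:
        if self.genome_length < 10_000 or self.n_contigs < 1:
            raise ValueError("genome too small")
        for r in (self.gc, self.het_fraction, self.slr_error_rate,
                  self.barcode_collision_rate, self.long_error_min,
                  self.long_error_max):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.slr_coverage < 0 or self.long_coverage < 0:
            raise ValueError("coverages must be >= 0")
        if not 0 < self.fragment_len_min <= self.fragment_len_max:
            raise ValueError("bad fragment length range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dropouts"] = [list(t) for t in self.dropouts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["dropouts"] = [tuple(t) for t in d.get("dropouts", [])]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# reference and haplotypes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def make_reference(config: SimConfig, rng: Optional[np.random.Generator] = None
                   ) -> ReferenceGenome:
    """Random reference; optionally with implanted identical repeat copies
    (to create assembly-hard regions).  Deterministic per seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_contig = config.genome_length // config.n_contigs
    seqs: Dict[str, str] = {}
    for i in range(config.n_contigs):
        seqs[f"ctg{i + 1}"] = _random_seq(rng, per_contig, config.gc)
    if config.repeat_copies > 0:
        donor = _random_seq(rng, config.repeat_unit_len, config.gc)
        name = "ctg1"
        seq = list(seqs[name])
        if config.repeat_positions is not None:
            positions = list(config.repeat_positions)
        else:
            margin = config.placement_margin
            low, high = margin, per_contig - margin - config.repeat_unit_len
            positions = sorted(
                int(p) for p in rng.integers(low, high, size=config.repeat_copies))
        for pos in positions:
            seq[pos:pos + config.repeat_unit_len] = donor
        seqs[name] = "".join(seq)
    return ReferenceGenome(seqs)


def sample_svs(config: SimConfig, reference: ReferenceGenome,
               rng: np.random.Generator) -> List[SVSpec]:
    """Draw the configured SV mix at non-overlapping positions.

    Events keep at least ``min_event_gap`` bp between their reference spans
    and stay ``placement_margin`` bp away from contig ends.
    """
    if config.fixed_svs is not None:
        return [SVSpec(**d) for d in config.fixed_svs]
    mobile_donor = _random_seq(rng, config.mobile_donor_len, config.gc)
    kinds = (["DEL"] * config.n_del + ["random"] * config.n_ins_random
             + ["mobile"] * config.n_ins_mobile + ["tandem"] * config.n_ins_tandem)
    n = len(kinds)
    zygosity = ["het" if i < round(config.het_fraction * n) else "hom"
                for i in range(n)]
    rng.shuffle(kinds)  # type: ignore[arg-type]
    zygosity = list(rng.permutation(zygosity))

    taken: Dict[str, List[Tuple[int, int]]] = {c: [] for c in reference.contigs}
    specs: List[SVSpec] = []
    contigs = reference.contigs
    hap_toggle = 0
    for kind, zyg in zip(kinds, zygosity):
        if kind == "DEL":
            svtype, length, seq = "DEL", int(rng.integers(config.sv_len_min,
                                                          config.sv_len_max + 1)), ""
            iclass = "random"
        elif kind == "random":
            svtype = "INS"
            length = int(rng.integers(config.sv_len_min, config.sv_len_max + 1))
            seq = _random_seq(rng, length, config.gc)
            iclass = "random"
        elif kind == "mobile":
            svtype, seq, iclass = "INS", mobile_donor, "mobile"
            length = len(seq)
        else:
            svtype, iclass = "INS", "tandem"
            motif = _random_seq(rng, config.tandem_motif_len, config.gc)
            copies = int(rng.integers(config.tandem_copies_min,
                                      config.tandem_copies_max + 1))
            seq = motif * copies
            length = len(seq)
        placed = False
        for _ in range(1000):
            contig = contigs[int(rng.integers(len(contigs)))]
            clen = reference.lengths[contig]
            span = length if svtype == "DEL" else 0
            lo = config.placement_margin
            hi = clen - config.placement_margin - span
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            window = (pos - config.min_event_gap, pos + span + config.min_event_gap)
            if any(a < window[1] and window[0] < b for a, b in taken[contig]):
                continue
            taken[contig].append((window[0], window[1]))
            hap = hap_toggle if zyg == "het" else 0
            if zyg == "het":
                hap_toggle ^= 1
            specs.append(SVSpec(svtype, contig, pos, length, iclass, zyg, hap, seq))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place all SVs; genome too crowded")
    specs.sort(key=lambda s: (s.contig, s.pos))
    return specs


@dataclass
class BlockMap:
    """Piecewise-collinear map from haplotype to reference coordinates.

    ``blocks`` are (hap_start, hap_end, ref_start) with
    hap[hap_start:hap_end] == ref[ref_start : ref_start + (hap_end-hap_start)].
    Haplotype positions between blocks are inserted sequence; their anchor
    is the ref_start of the following block.
    """

    blocks: List[Tuple[int, int, int]]

    def project(self, s: int, e: int) -> List[Tuple[str, int, int]]:
        """Decompose hap interval [s, e) into (op, length, ref_start) pieces.

        op 'M' pieces carry their reference start; 'I' pieces carry the
        anchor reference coordinate.  'D' pieces (deleted reference between
        consecutive M pieces, zero read bases) are included so a truthful
        CIGAR can be built.
        """
        starts = [b[0] for b in self.blocks]
        i = max(0, bisect_right(starts, s) - 1)
        out: List[Tuple[str, int, int]] = []
        cur = s
        prev_ref_end: Optional[int] = None
        while cur < e and i < len(self.blocks):
            h0, h1, r0 = self.blocks[i]
            if cur < h0:
                nxt = min(e, h0)
                out.append(("I", nxt - cur, r0))
                cur = nxt
                continue
            if cur >= h1:
                i += 1
                continue
            nxt = min(e, h1)
            rstart = r0 + (cur - h0)
            if prev_ref_end is not None and rstart > prev_ref_end:
                out.append(("D", rstart - prev_ref_end, prev_ref_end))
            out.append(("M", nxt - cur, rstart))
            prev_ref_end = rstart + (nxt - cur)
            cur = nxt
            if cur >= h1:
                i += 1
        if cur < e:
            # past the last block: inserted tail (or contig end)
            anchor = self.blocks[-1][2] + (self.blocks[-1][1] - self.blocks[-1][0])
            out.append(("I", e - cur, anchor))
        return out


def implant_svs(reference: ReferenceGenome, specs: Sequence[SVSpec]
                ) -> Tuple[Dict[str, Tuple[str, str]],
                           Dict[Tuple[str, int], BlockMap],
                           List[SVCall]]:
    """Apply the specs, returning haplotype pairs, coordinate maps and truth.

    Homozygous events go to both haplotypes, heterozygous ones to their
    designated haplotype.  Truth positions stay on the original reference.
    """
    by_contig: Dict[str, List[SVSpec]] = {c: [] for c in reference.contigs}
    for spec in specs:
        by_contig[spec.contig].append(spec)
    for contig, ss in by_contig.items():
        ss.sort(key=lambda s: s.pos)
        prev_end = -1
        for s in ss:
            span = s.length if s.svtype == "DEL" else 0
            if s.pos <= prev_end:
                raise ValueError(f"overlapping SV specs on {contig} at {s.pos}")
            prev_end = s.pos + span

    haplotypes: Dict[str, Tuple[str, str]] = {}
    maps: Dict[Tuple[str, int], BlockMap] = {}
    truth: List[SVCall] = []
    for contig in reference.contigs:
        refseq = reference[contig]
        haps: List[str] = []
        for hap in (0, 1):
            parts: List[str] = []
            blocks: List[Tuple[int, int, int]] = []
            ref_cursor = 0
            hap_cursor = 0
            for s in by_contig[contig]:
                if s.genotype()[hap] != 1:
                    continue
                chunk = refseq[ref_cursor:s.pos]
                if chunk:
                    blocks.append((hap_cursor, hap_cursor + len(chunk), ref_cursor))
                    parts.append(chunk)
                    hap_cursor += len(chunk)
                ref_cursor = s.pos
                if s.svtype == "DEL":
                    ref_cursor += s.length
                else:
                    parts.append(s.seq)
                    hap_cursor += s.length
            chunk = refseq[ref_cursor:]
            if chunk:
                blocks.append((hap_cursor, hap_cursor + len(chunk), ref_cursor))
                parts.append(chunk)
            haps.append("".join(parts))
            maps[(contig, hap)] = BlockMap(blocks)
        haplotypes[contig] = (haps[0], haps[1])
        for s in by_contig[contig]:
            seq = s.seq if s.svtype == "INS" else refseq[s.pos:s.pos + s.length]
            truth.append(SVCall(s.svtype, contig, s.pos, s.length, seq,
                                genotype=s.genotype(), phased=True))
    return haplotypes, maps, truth


def reconstruct_haplotypes(reference: ReferenceGenome, truth: Sequence[SVCall]
                           ) -> Dict[str, Tuple[str, str]]:
    """Apply a truth call set back to the reference (round-trip check)."""
    out: Dict[str, Tuple[str, str]] = {}
    for contig in reference.contigs:
        refseq = reference[contig]
        haps = []
        for hap in (0, 1):
            parts: List[str] = []
            cursor = 0
            for call in sorted((c for c in truth if c.chrom == contig),
                               key=lambda c: c.pos):
                gt = call.genotype or (1, 1)
                if gt[hap] != 1:
                    continue
                parts.append(refseq[cursor:call.pos])
                cursor = call.pos
                if call.svtype == "DEL":
                    cursor += call.length
                else:
                    parts.append(call.seq)
            parts.append(refseq[cursor:])
            haps.append("".join(parts))
        out[contig] = (haps[0], haps[1])
    return out


# ---------------------------------------------------------------------------
# linked reads
# ---------------------------------------------------------------------------

def _in_dropout(dropouts: Sequence[Tuple[str, int, int]], contig: str,
                start: int, end: int) -> bool:
    return any(c == contig and start < e and s < end
               for c, s, e in dropouts)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


@dataclass
class _ShortRead:
    name: str
    seq: str
    is_read1: bool
    is_unmapped: bool
    pos: int                   # alignment or placement position
    cigar: Optional[List[Tuple[int, int]]]   # pysam op codes
    barcode: str
    contig: str
    reverse: bool


def _project_short_read(bmap: BlockMap, s: int, e: int
                        ) -> Tuple[bool, int, Optional[List[Tuple[int, int]]], int, int]:
    """Emulate an aligner on one read: largest collinear piece aligns,
    the rest is soft-clipped; no collinear piece means placed-unmapped.

    Returns (unmapped, pos, cigar, ref_span_start, ref_span_end)."""
    pieces = bmap.project(s, e)
    m_pieces = [(n, r, idx) for idx, (op, n, r) in enumerate(pieces) if op == "M"]
    if not m_pieces:
        anchor = pieces[0][2] if pieces else 0
        return True, anchor, None, anchor, anchor + 1
    n, r, idx = max(m_pieces, key=lambda t: t[0])
    left = sum(x for op, x, _ in pieces[:idx] if op in "MI")
    right = sum(x for op, x, _ in pieces[idx + 1:] if op in "MI")
    cigar: List[Tuple[int, int]] = []
    if left:
        cigar.append((4, left))     # S
    cigar.append((0, n))            # M
    if right:
        cigar.append((4, right))
    # the dropout span covers everything the read touches on the reference
    # (both sides of a deletion junction), not just the aligned piece
    rs = min(r2 for _, n2, r2 in pieces)
    re_ = max(r2 + (n2 if op2 == "M" else 0) for op2, n2, r2 in pieces)
    return False, r, cigar, rs, max(re_, rs + 1)


@dataclass
class Fragment:
    """One sheared molecule: the unit sharing a barcode."""

    barcode: str
    contig: str
    hap: int
    start: int      # on the haplotype
    length: int     # after clipping to the contig
    drawn_length: int
    n_pairs: int = 0


def simulate_linked_reads(haplotypes: Dict[str, Tuple[str, str]],
                          maps: Dict[Tuple[str, int], BlockMap],
                          config: SimConfig, rng: np.random.Generator
                          ) -> Tuple[List[_ShortRead], List[Fragment]]:
    """Draw fragments and read pairs; project them onto the reference."""
    reads: List[_ShortRead] = []
    fragments: List[Fragment] = []
    barcode_serial = 0
    barcodes_used: List[str] = []
    read_serial = 0
    rl = config.read_len
    mean_flen = (config.fragment_len_min + config.fragment_len_max) / 2
    for contig in sorted(haplotypes):
        for hap in (0, 1):
            hseq = haplotypes[contig][hap]
            bmap = maps[(contig, hap)]
            cov_target = config.slr_coverage / 2
            # fragment starts range over [-(flen-1), L-1] and fragments are
            # clipped to the contig, so coverage is uniform right up to the
            # contig ends (a real chromosome is ~1000x longer than a
            # fragment; without clipping, a toy-scale contig would lose most
            # of its coverage within a fragment length of each end)
            n_frags = int(round(cov_target * (len(hseq) + mean_flen)
                                / (mean_flen * config.fragment_read_coverage)))
            for _ in range(n_frags):
                drawn = int(rng.integers(config.fragment_len_min,
                                         config.fragment_len_max + 1))
                flen = min(drawn, len(hseq))
                raw_start = int(rng.integers(-(flen - 1), len(hseq)))
                fstart = max(0, raw_start)
                fend = min(len(hseq), raw_start + flen)
                flen = fend - fstart
                if flen < config.fragment_len_min:
                    continue   # clipped below the shearing size floor
                if (config.barcode_collision_rate > 0 and barcodes_used
                        and rng.random() < config.barcode_collision_rate):
                    bx = barcodes_used[int(rng.integers(len(barcodes_used)))]
                else:
                    barcode_serial += 1
                    bx = f"BX{barcode_serial:07d}-1"
                    barcodes_used.append(bx)
                frag = Fragment(bx, contig, hap, fstart, flen, drawn)
                fragments.append(frag)
                n_pairs = rng.poisson(flen * config.fragment_read_coverage / (2 * rl))
                for _ in range(n_pairs):
                    insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
                    insert = max(2 * rl, min(insert, flen))
                    if flen - insert < 0:
                        continue
                    s = fstart + int(rng.integers(0, flen - insert + 1))
                    read_serial += 1
                    name = f"sim{read_serial:08d}"
                    r1 = (s, s + rl)
                    r2 = (s + insert - rl, s + insert)
                    pair: List[_ShortRead] = []
                    drop = False
                    for (a, b), is_read1 in ((r1, True), (r2, False)):
                        unmapped, pos, cigar, rs, re_ = _project_short_read(bmap, a, b)
                        if _in_dropout(config.dropouts, contig, rs, re_):
                            drop = True
                            break
                        seq = _mutate(hseq[a:b], config.slr_error_rate, rng)
                        pair.append(_ShortRead(name, seq, is_read1, unmapped, pos,
                                               cigar, bx, contig, not is_read1))
                    if not drop:
                        reads.extend(pair)
                        frag.n_pairs += 1
    return reads, fragments


def write_linked_bam(reads: List[_ShortRead], reference: ReferenceGenome,
                     out_path: str, base_quality: int = 40) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in reference.lengths.items()],
    }
    by_name: Dict[str, List[_ShortRead]] = {}
    for read in reads:
        by_name.setdefault(read.name, []).append(read)
    records = []
    hdr = pysam.AlignmentHeader.from_dict(header)
    tid_of = {name: i for i, name in enumerate(reference.lengths)}
    for name in sorted(by_name):
        mates = sorted(by_name[name], key=lambda r: not r.is_read1)
        if len(mates) != 2:
            continue
        for read, mate in ((mates[0], mates[1]), (mates[1], mates[0])):
            rec = pysam.AlignedSegment(hdr)
            rec.query_name = read.name
            rec.query_sequence = read.seq
            rec.query_qualities = [base_quality] * len(read.seq)
            flag = 0x1 | (0x40 if read.is_read1 else 0x80)
            if read.is_unmapped:
                flag |= 0x4
            elif read.reverse:
                flag |= 0x10
            if mate.is_unmapped:
                flag |= 0x8
            elif mate.reverse:
                flag |= 0x20
            if not (read.is_unmapped or mate.is_unmapped):
                flag |= 0x2
            rec.flag = flag
            rec.reference_id = tid_of[read.contig]
            rec.reference_start = read.pos if not read.is_unmapped else mate.pos
            rec.mapping_quality = 0 if read.is_unmapped else 60
            if not read.is_unmapped and read.cigar:
                rec.cigartuples = read.cigar
            rec.next_reference_id = tid_of[mate.contig]
            rec.next_reference_start = (mate.pos if not mate.is_unmapped
                                        else rec.reference_start)
            rec.set_tag("BX", read.barcode)
            records.append(rec)
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                not r.is_read1))
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(out_path)


def write_fastq(reads: List[_ShortRead], r1_path: str, r2_path: str,
                base_quality: int = 40) -> None:
    qual = chr(base_quality + 33)
    by_name: Dict[str, Dict[bool, _ShortRead]] = {}
    for read in reads:
        by_name.setdefault(read.name, {})[read.is_read1] = read
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name in sorted(by_name):
            mates = by_name[name]
            if len(mates) != 2:
                continue
            for is_read1, fh in ((True, f1), (False, f2)):
                read = mates[is_read1]
                seq = revcomp(read.seq) if read.reverse else read.seq
                fh.write(f"@{read.name} BX:Z:{read.barcode}\n{seq}\n+\n"
                         f"{qual * len(seq)}\n")


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def _apply_long_errors(seq: str, ops: List[Tuple[str, int]], rate: float,
                       rng: np.random.Generator) -> Tuple[str, List[Tuple[str, int]]]:
    """Introduce i.i.d. per-base errors (60 % sub, 20 % ins, 20 % del),
    keeping the truth CIGAR consistent with the mutated sequence."""
    expanded: List[Tuple[str, Optional[str]]] = []   # (op, base or None for D)
    qpos = 0
    for op, n in ops:
        if op in "MIS":
            for _ in range(n):
                expanded.append((op, seq[qpos]))
                qpos += 1
        elif op == "D":
            for _ in range(n):
                expanded.append(("D", None))
    out_ops: List[Tuple[str, str | None]] = []
    for op, base in expanded:
        if base is None:
            out_ops.append((op, None))
            continue
        if rng.random() >= rate:
            out_ops.append((op, base))
            continue
        kind = rng.random()
        if kind < 0.6:       # substitution
            choices = [b for b in "ACGT" if b != base]
            out_ops.append((op, choices[int(rng.integers(3))]))
        elif kind < 0.8:     # extra inserted base
            out_ops.append((op, base))
            out_ops.append(("I", "ACGT"[int(rng.integers(4))]))
        else:                # dropped base
            if op == "M":
                out_ops.append(("D", None))
            # dropped base inside I/S simply vanishes
    new_seq = "".join(b for _, b in out_ops if b is not None)
    merged: List[Tuple[str, int]] = []
    for op, base in out_ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + 1)
        else:
            merged.append((op, 1))
    return new_seq, merged


@dataclass
class _LongRead:
    name: str
    seq: str
    contig: str
    pos: int
    cigar: List[Tuple[int, int]]
    drawn_len: int = 0      # length before sequencing errors


_OPCODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def simulate_long_reads(haplotypes: Dict[str, Tuple[str, str]],
                        maps: Dict[Tuple[str, int], BlockMap],
                        config: SimConfig, rng: np.random.Generator
                        ) -> List[_LongRead]:
    out: List[_LongRead] = []
    if config.long_coverage <= 0:
        return out
    mean_len = (config.long_read_len_min + config.long_read_len_max) / 2
    serial = 0
    for contig in sorted(haplotypes):
        for hap in (0, 1):
            hseq = haplotypes[contig][hap]
            bmap = maps[(contig, hap)]
            n_reads = int(round(config.long_coverage / 2 * len(hseq) / mean_len))
            for _ in range(n_reads):
                length = int(rng.integers(config.long_read_len_min,
                                          config.long_read_len_max + 1))
                length = min(length, len(hseq))
                start = int(rng.integers(0, len(hseq) - length + 1))
                rate = rng.uniform(config.long_error_min, config.long_error_max)
                pieces = bmap.project(start, start + length)
                ops: List[Tuple[str, int]] = []
                ref_start = None
                for i, (op, n, r) in enumerate(pieces):
                    if op == "M" and ref_start is None:
                        ref_start = r
                    if op == "I" and (ref_start is None or i == len(pieces) - 1):
                        ops.append(("S", n))    # leading/trailing insertion -> clip
                    else:
                        ops.append((op, n))
                if ref_start is None:
                    continue     # entirely inserted sequence; cannot happen for
                                 # insertions shorter than the read, skip if it does
                seq = hseq[start:start + length]
                seq, ops = _apply_long_errors(seq, ops, rate, rng)
                serial += 1
                cigar = [(_OPCODE[op], n) for op, n in ops if n > 0]
                out.append(_LongRead(f"lr{serial:06d}", seq, contig, ref_start,
                                     cigar, length))
    return out


def write_long_bam(reads: List[_LongRead], reference: ReferenceGenome,
                   out_path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in reference.lengths.items()],
    }
    tid_of = {name: i for i, name in enumerate(reference.lengths)}
    records = []
    hdr = pysam.AlignmentHeader.from_dict(header)
    for read in reads:
        rec = pysam.AlignedSegment(hdr)
        rec.query_name = read.name
        rec.query_sequence = read.seq
        rec.query_qualities = [30] * len(read.seq)
        rec.flag = 0
        rec.reference_id = tid_of[read.contig]
        rec.reference_start = read.pos
        rec.mapping_quality = 60
        rec.cigartuples = read.cigar
        records.append(rec)
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(out_path)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    reference: ReferenceGenome
    haplotypes: Dict[str, Tuple[str, str]]
    maps: Dict[Tuple[str, int], BlockMap]
    truth: List[SVCall]
    specs: List[SVSpec]
    fragments: List[Fragment]
    long_read_lengths: List[int]
    ref_fasta: str
    bam: str
    long_bam: Optional[str]
    truth_vcf: str


def simulate(config: SimConfig, out_dir: str,
             fastq: bool = False) -> SimResult:
    """Run the full simulation and write all artifacts into ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config, rng)
    specs = sample_svs(config, reference, rng)
    haplotypes, maps, truth = implant_svs(reference, specs)

    ref_fasta = str(out / "ref.fa")
    with open(ref_fasta, "w") as fh:
        for name in reference.contigs:
            fh.write(f">{name}\n{reference[name]}\n")
    with open(out / "haplotypes.fa", "w") as fh:
        for name in reference.contigs:
            for hap in (0, 1):
                fh.write(f">{name}_hap{hap}\n{haplotypes[name][hap]}\n")

    reads, fragments = simulate_linked_reads(haplotypes, maps, config, rng)
    bam = str(out / "reads.bam")
    write_linked_bam(reads, reference, bam, config.base_quality)
    if fastq:
        write_fastq(reads, str(out / "reads_R1.fastq"), str(out / "reads_R2.fastq"),
                    config.base_quality)

    long_bam = None
    long_reads = simulate_long_reads(haplotypes, maps, config, rng)
    if long_reads:
        long_bam = str(out / "long_reads.bam")
        write_long_bam(long_reads, reference, long_bam)

    truth_vcf = str(out / "truth.vcf")
    # relative reference name keeps outputs byte-identical across directories
    write_vcf(truth, reference, truth_vcf, reference_path="ref.fa",
              params_line=f"simulated,seed={config.seed}")
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    log.info("simulated %d SVs, %d read pairs, %d long reads",
             len(specs), len(reads) // 2, len(long_reads))
    return SimResult(reference, haplotypes, maps, truth, specs, fragments,
                     [r.drawn_len for r in long_reads],
                     ref_fasta, bam, long_bam, truth_vcf)
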