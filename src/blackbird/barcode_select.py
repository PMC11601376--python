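"""Per-segment barcode selection and read gathering.

A barcode belongs to a segment when its fragment plausibly originated there:
at least ``min_pairs`` read pairs aligned inside the segment and an aligned
span (leftmost to rightmost alignment start) strictly greater than
``min_span``.  Spurious barcodes — a stray pair mismapped into a local
repeat — fail one of the two conditions.

Given the selected barcode list, the segment's read set is the union of
(1) reads of those barcodes aligned inside the segment, stored as pairs when
both mates are recoverable, and (2) the badly aligned pairs of those
barcodes from the genome-wide read map, which carry the sequence evidence
(unmapped or clipped mates) local alignment cannot provide.  In hybrid mode
long reads overlapping the segment are attached, capped to the configured
limit by descending segment overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import pysam

from .read_store import AlignedRead, ReadMap, ReadPair, ReadParseError
from .segmentation import Segment

log = logging.getLogger(__name__)


@dataclass
class BarcodeStat:
    """Alignment summary of one barcode within one segment."""

    barcode: str
    n_pairs: int    # pairs with both mates' alignment starts inside the segment
    span: int       # distance between leftmost and rightmost in-segment starts


@dataclass
class SegmentReadSet:
    """Everything the local assembler receives for one segment."""

    segment: Segment
    pairs: List[ReadPair] = field(default_factory=list)
    singles: List[AlignedRead] = field(default_factory=list)
    long_reads: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_short_reads(self) -> int:
        return 2 * len(self.pairs) + len(self.singles)

    def short_read_sequences(self) -> List[str]:
        out = []
        for pair in self.pairs:
            out.append(pair.read1.sequence)
            out.append(pair.read2.sequence)
        out.extend(read.sequence for read in self.singles)
        return out


def _primary(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_secondary or rec.is_supplementary)


def barcode_stats(segment: Segment, bam: pysam.AlignmentFile) -> List[BarcodeStat]:
    """One stat per BX value with >= 1 primary alignment overlapping the segment.

    Pair counting requires both mates' alignment starts inside the segment
    (the mate start is read from the record, no mate fetch needed); the span
    uses in-segment alignment starts only, so it never exceeds the segment
    length.
    """
    starts: Dict[str, List[int]] = {}
    pair_names: Dict[str, Set[str]] = {}
    seen: Dict[str, bool] = {}
    for rec in bam.fetch(segment.contig, segment.start, segment.end):
        if not _primary(rec) or rec.is_unmapped or not rec.has_tag("BX"):
            continue
        bx = rec.get_tag("BX")
        seen[bx] = True
        pos = rec.reference_start
        if segment.start <= pos < segment.end:
            starts.setdefault(bx, []).append(pos)
            mate_in = (rec.is_paired and not rec.mate_is_unmapped
                       and rec.next_reference_name == segment.contig
                       and segment.start <= rec.next_reference_start < segment.end)
            if mate_in:
                pair_names.setdefault(bx, set()).add(rec.query_name)
    out = []
    for bx in sorted(seen):
        pos_list = starts.get(bx, [])
        span = max(pos_list) - min(pos_list) if pos_list else 0
        out.append(BarcodeStat(bx, len(pair_names.get(bx, ())), span))
    return out


def select_barcodes(stats: List[BarcodeStat], min_pairs: int = 3,
                    min_span: int = 5_000) -> Set[str]:
    """Keep a barcode iff n_pairs >= min_pairs AND span > min_span (strict)."""
    return {s.barcode for s in stats
            if s.n_pairs >= min_pairs and s.span > min_span}


def _fetch_mate(bam: pysam.AlignmentFile, rec_name: str, is_read1_wanted: bool,
                contig: Optional[str], pos: int) -> Optional[AlignedRead]:
    """Locate the mate record by its indexed position."""
    if contig is None or pos < 0:
        return None
    for rec in bam.fetch(contig, pos, pos + 1):
        if (_primary(rec) and rec.query_name == rec_name
                and rec.reference_start == pos
                and rec.is_read1 == is_read1_wanted):
            try:
                return AlignedRead.from_pysam(rec)
            except ReadParseError:
                return None
    return None


def gather_reads(segment: Segment, barcodes: Set[str], bam: pysam.AlignmentFile,
                 read_map: ReadMap, long_bam: Optional[pysam.AlignmentFile] = None,
                 long_cap: int = 100) -> SegmentReadSet:
    """Build the segment's read set (see module docstring).

    Short reads are deduplicated by read name: a pair recruited both by
    alignment and through the read map appears once.  Output ordering is
    deterministic (sorted by read name).
    """
    by_name: Dict[str, Dict[bool, AlignedRead]] = {}
    for rec in bam.fetch(segment.contig, segment.start, segment.end):
        if not _primary(rec) or rec.is_unmapped or not rec.has_tag("BX"):
            continue
        if rec.get_tag("BX") not in barcodes:
            continue
        try:
            read = AlignedRead.from_pysam(rec)
        except ReadParseError as exc:
            log.warning("gather %s: %s", segment, exc)
            continue
        by_name.setdefault(read.name, {})[read.is_read1] = read

    pairs: Dict[str, ReadPair] = {}
    singles: Dict[str, AlignedRead] = {}
    for name, mates in by_name.items():
        if len(mates) == 2:
            pairs[name] = ReadPair(mates[True], mates[False])
            continue
        read = next(iter(mates.values()))
        mate = _fetch_mate(bam, name, not read.is_read1,
                           read.mate_contig, read.mate_pos)
        if mate is not None:
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            pairs[name] = ReadPair(r1, r2)
        else:
            singles[name] = read

    for pair in read_map.query(barcodes):
        if pair.name not in pairs:
            pairs[pair.name] = pair
            singles.pop(pair.name, None)

    long_reads: List[Tuple[str, str]] = []
    if long_bam is not None:
        candidates = []
        for rec in long_bam.fetch(segment.contig, segment.start, segment.end):
            if not _primary(rec) or rec.query_sequence is None:
                continue
            overlap = (min(rec.reference_end or rec.reference_start, segment.end)
                       - max(rec.reference_start, segment.start))
            candidates.append((-overlap, rec.query_name, rec.query_sequence))
        candidates.sort(key=lambda c: (c[0], c[1]))
        long_reads = [(name, seq) for _, name, seq in candidates[:long_cap]]

    return SegmentReadSet(
        segment,
        pairs=[pairs[name] for name in sorted(pairs)],
        singles=[singles[name] for name in sorted(singles)],
        long_reads=long_reads,
    )
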