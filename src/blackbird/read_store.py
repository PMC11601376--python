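"""The badly-aligned read set and its barcode index.

A single pass over the input BAM collects every *badly aligned* read pair —
pairs that are well sequenced (rule a) yet poorly placed (rules b/c).  Those
are exactly the reads an aligner cannot use but a local assembly can: reads
from inserted sequence absent from the reference, reads straddling
breakpoints, reads from collapsed repeats.  The store indexes them by their
fragment barcode (BX tag) so that segment assembly can later recruit the
badly aligned mates of any barcode list in O(result).

Classification rules for a pair (both mates primary records):

  (a) every base of both mates has Phred quality strictly above ``qual_min``;
  (b) at least one mate is unmapped, mapped to an unplaced contig, or has
      strictly more than ``clip_frac_max`` of its bases clipped;
  (c) at least one mate carries an AM tag with value 0 (the aligner could not
      cluster the read with same-barcode reads).

A pair is *badly aligned* iff (a) AND ((b) OR (c)).  An absent AM tag never
triggers (c): the tag is specific to one aligner family and other barcode
-preserving aligners do not emit it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import pysam

from .config import HUMAN_PRIMARY_CONTIGS

log = logging.getLogger(__name__)


class BamInputError(RuntimeError):
    """Unusable input BAM (missing index, not position-sorted, ...)."""


class ReadParseError(ValueError):
    """A record lacks fields the classification rules need (e.g. qualities)."""


@dataclass
class AlignedRead:
    """One primary short-read record with the attributes rules (a)-(c) test."""

    name: str
    sequence: str
    qualities: Tuple[int, ...]
    barcode: Optional[str]
    is_unmapped: bool
    contig: Optional[str]
    pos: int                      # 0-based leftmost aligned position (or placement)
    cigar: Tuple[Tuple[str, int], ...]   # ((op, length), ...) ops in MIDNSHP=X
    am: Optional[int]
    is_read1: bool
    mate_contig: Optional[str] = None
    mate_pos: int = -1

    def __post_init__(self) -> None:
        if self.qualities and len(self.qualities) != len(self.sequence):
            raise ReadParseError(
                f"read {self.name}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases")

    @property
    def clip_fraction(self) -> float:
        """Clipped bases / full read length.

        Hard clips count toward both numerator and denominator (the
        denominator is the pre-clipping read length), so the fraction does
        not depend on whether the aligner soft- or hard-clipped.
        """
        if not self.cigar:
            return 0.0
        clipped = sum(n for op, n in self.cigar if op in "SH")
        total = sum(n for op, n in self.cigar if op in "MIS=X") \
            + sum(n for op, n in self.cigar if op == "H")
        return clipped / total if total else 0.0

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedRead":
        if rec.query_qualities is None:
            raise ReadParseError(f"read {rec.query_name}: missing base qualities")
        cigar = tuple(("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or ()))
        return cls(
            name=rec.query_name,
            sequence=rec.query_sequence or "",
            qualities=tuple(rec.query_qualities),
            barcode=rec.get_tag("BX") if rec.has_tag("BX") else None,
            is_unmapped=rec.is_unmapped,
            contig=rec.reference_name if not rec.is_unmapped else None,
            pos=rec.reference_start if rec.reference_start is not None else -1,
            cigar=cigar,
            am=int(rec.get_tag("AM")) if rec.has_tag("AM") else None,
            is_read1=rec.is_read1,
            mate_contig=(rec.next_reference_name
                         if rec.next_reference_id >= 0 else None),
            mate_pos=rec.next_reference_start,
        )


@dataclass
class ReadPair:
    """Both primary mates of one read name."""

    read1: AlignedRead
    read2: AlignedRead

    def __post_init__(self) -> None:
        if self.read1.name != self.read2.name:
            raise ValueError("mates must share a read name")

    @property
    def name(self) -> str:
        return self.read1.name

    @property
    def barcode(self) -> Optional[str]:
        return self.read1.barcode or self.read2.barcode


def is_badly_aligned(pair: ReadPair, qual_min: int = 20,
                     clip_frac_max: float = 0.20,
                     primary_contigs: FrozenSet[str] = frozenset(HUMAN_PRIMARY_CONTIGS),
                     ) -> bool:
    """Apply rules (a)-(c); see the module docstring.

    Raises :class:`ReadParseError` when a mate has no quality values, so a
    malformed record is rejected loudly rather than silently classified.
    """
    reads = (pair.read1, pair.read2)
    for read in reads:
        if not read.qualities:
            raise ReadParseError(f"read {read.name}: missing base qualities")
    # (a) strictly above qual_min for every base of both mates
    if any(q <= qual_min for read in reads for q in read.qualities):
        return False
    # (b) unmapped / unplaced / over-clipped for at least one mate
    rule_b = any(
        read.is_unmapped
        or (read.contig is not None and read.contig not in primary_contigs)
        or read.clip_fraction > clip_frac_max
        for read in reads)
    # (c) AM tag present with value zero on at least one mate
    rule_c = any(read.am == 0 for read in reads)
    return rule_b or rule_c


@dataclass
class ReadMap:
    """The badly-aligned pair collection with its barcode index.

    ``pairs`` holds every badly aligned pair; ``_by_barcode`` only the
    barcoded ones (a pair without a BX tag cannot be recruited by barcode).
    """

    pairs: List[ReadPair] = field(default_factory=list)
    _by_barcode: Dict[str, List[ReadPair]] = field(default_factory=dict)

    def add(self, pair: ReadPair) -> None:
        self.pairs.append(pair)
        if pair.barcode is not None:
            self._by_barcode.setdefault(pair.barcode, []).append(pair)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def barcodes(self) -> Set[str]:
        return set(self._by_barcode)

    def query(self, barcodes: Iterable[str]) -> List[ReadPair]:
        """All pairs whose barcode is in ``barcodes``.

        Deterministic order: (barcode, read name).  Unknown barcodes yield
        nothing; duplicate names across buckets are collapsed.
        """
        seen: Set[str] = set()
        out: List[ReadPair] = []
        for bx in sorted(set(barcodes)):
            for pair in sorted(self._by_barcode.get(bx, ()), key=lambda p: p.name):
                if pair.name not in seen:
                    seen.add(pair.name)
                    out.append(pair)
        return out


def open_indexed_bam(path: str) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(path)
    if not bam.has_index():
        raise BamInputError(
            f"{path} has no index; sort and index it first "
            "(samtools sort / samtools index)")
    header = bam.header.to_dict()
    so = header.get("HD", {}).get("SO", "unknown")
    if so not in ("coordinate", "unknown"):
        raise BamInputError(f"{path} is {so}-sorted; position-sorted input required")
    return bam


def build_read_store(bam_path: str, qual_min: int = 20,
                     clip_frac_max: float = 0.20,
                     primary_contigs: FrozenSet[str] = frozenset(HUMAN_PRIMARY_CONTIGS),
                     cache_path: Optional[str] = None) -> ReadMap:
    """Single pass over the BAM building the badly-aligned read map.

    Mates are paired by name in memory; secondary and supplementary records
    never represent a read.  Orphan mates (name seen once) are logged and
    skipped.  With ``cache_path`` set, the collected pairs are additionally
    spilled to a name-sorted SAM for inspection or reuse.
    """
    read_map = ReadMap()
    pending: Dict[str, AlignedRead] = {}
    n_records = n_pairs = n_bad = n_malformed = 0
    with open_indexed_bam(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            n_records += 1
            try:
                read = AlignedRead.from_pysam(rec)
            except ReadParseError as exc:
                n_malformed += 1
                log.warning("rejected record: %s", exc)
                pending.pop(rec.query_name, None)
                continue
            mate = pending.pop(read.name, None)
            if mate is None:
                pending[read.name] = read
                continue
            n_pairs += 1
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            pair = ReadPair(r1, r2)
            try:
                bad = is_badly_aligned(pair, qual_min, clip_frac_max, primary_contigs)
            except ReadParseError as exc:
                n_malformed += 1
                log.warning("rejected pair: %s", exc)
                continue
            if bad:
                n_bad += 1
                read_map.add(pair)
    if pending:
        log.warning("skipped %d orphan mates (unpaired read names)", len(pending))
    log.info("read store: %d records, %d pairs, %d badly aligned (%d barcoded), "
             "%d malformed", n_records, n_pairs, n_bad,
             sum(1 for p in read_map.pairs if p.barcode), n_malformed)
    if cache_path is not None:
        _spill_to_sam(read_map, bam_path, cache_path)
    return read_map


def _spill_to_sam(read_map: ReadMap, bam_path: str, cache_path: str) -> None:
    """Write the collected pairs to a name-sorted SAM file."""
    with pysam.AlignmentFile(bam_path) as src:
        header = src.header
    with pysam.AlignmentFile(cache_path, "w", header=header) as out:
        for pair in sorted(read_map.pairs, key=lambda p: p.name):
            for read in (pair.read1, pair.read2):
                rec = pysam.AlignedSegment(header)
                rec.query_name = read.name
                rec.query_sequence = read.sequence
                rec.query_qualities = list(read.qualities)
                rec.flag = (1 | (4 if read.is_unmapped else 0)
                            | (64 if read.is_read1 else 128))
                if not read.is_unmapped and read.contig is not None:
                    rec.reference_id = header.get_tid(read.contig)
                    rec.reference_start = read.pos
                    rec.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar) or None
                if read.barcode is not None:
                    rec.set_tag("BX", read.barcode)
                if read.am is not None:
                    rec.set_tag("AM", read.am)
                out.write(rec)
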