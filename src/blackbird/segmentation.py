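"""Reference loading and tiling into overlapping segments.

The caller assembles the genome segment by segment.  Segments are
``segment_length`` bp windows whose consecutive starts differ by
``segment_length - segment_overlap``, so any event shorter than the overlap
is fully contained in at least one segment.  Coordinates are 0-based
half-open throughout the package; 1-based coordinates appear only in VCF
records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from pyfaidx import Fasta

from .config import ConfigError

_VALID = re.compile(r"^[ACGTN]*$")


@dataclass
class ReferenceGenome:
    """An in-memory reference: uppercase DNA keyed by contig name."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not _VALID.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"contig {name!r} contains non-ACGTN symbols: {bad}")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @property
    def contigs(self) -> List[str]:
        return list(self.sequences)


def load_reference(fasta_path: str) -> ReferenceGenome:
    """Read a (multi-record, possibly wrapped, mixed-case) FASTA into memory."""
    fa = Fasta(fasta_path, sequence_always_upper=True, as_raw=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return ReferenceGenome(seqs)


@dataclass(frozen=True)
class Segment:
    """A half-open reference window; the unit of local assembly and calling."""

    contig: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    index: int   # ordinal within the whole tiling

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def parse_region(region: str) -> Tuple[str, Optional[int], Optional[int]]:
    """Parse ``contig`` or ``contig:start-end`` (1-based inclusive, as in samtools)."""
    if ":" not in region:
        return region, None, None
    contig, _, span = region.rpartition(":")
    m = re.match(r"^(\d+)-(\d+)$", span.replace(",", ""))
    if not contig or not m:
        raise ConfigError(f"malformed region {region!r}")
    start, end = int(m.group(1)) - 1, int(m.group(2))
    if not 0 <= start < end:
        raise ConfigError(f"malformed region {region!r}")
    return contig, start, end


def tile_reference(lengths: Mapping[str, int], seg_len: int = 50_000,
                   overlap: int = 10_000,
                   region: Optional[str] = None) -> List[Segment]:
    """Tile every contig into overlapping segments.

    Segment starts are multiples of ``seg_len - overlap``; the last segment of
    a contig is clipped to the contig end and, if that would leave it shorter
    than the overlap, merged into its predecessor instead (the predecessor is
    extended to the contig end).  With ``region`` set, only segments
    intersecting the region (on that contig) are returned; the tiling itself
    is unchanged so coordinates stay comparable across runs.
    """
    if not 0 <= overlap < seg_len:
        raise ConfigError(f"overlap ({overlap}) must be >= 0 and < segment length ({seg_len})")
    want_contig = want_start = want_end = None
    if region is not None:
        want_contig, want_start, want_end = parse_region(region)
        if want_contig not in lengths:
            raise ConfigError(f"region contig {want_contig!r} not in reference")

    step = seg_len - overlap
    out: List[Segment] = []
    for contig, length in lengths.items():
        if length <= 0:
            continue
        if want_contig is not None and contig != want_contig:
            continue
        windows: List[List[int]] = []
        start = 0
        while start < length:
            if windows and windows[-1][1] >= length:
                break
            windows.append([start, min(start + seg_len, length)])
            start += step
        if len(windows) > 1 and windows[-1][1] - windows[-1][0] < overlap:
            windows[-2][1] = length
            windows.pop()
        for ordinal, (w_start, w_end) in enumerate(windows):
            if want_start is not None and not (w_start < want_end and want_start < w_end):
                continue
            out.append(Segment(contig, w_start, w_end, ordinal))
    if region is not None and not out:
        raise ConfigError(f"region {region!r} selects no segments")
    return out
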