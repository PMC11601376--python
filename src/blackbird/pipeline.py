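"""Pipeline orchestration: one BAM scan, then per-segment assembly and
calling, then global filtering, deduplication and VCF output.

Segments are independent work units; with ``threads > 1`` they are
processed in a process pool and merged in segment order, so the output is
identical for any worker count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pysam

from . import barcode_select, read_store, sv_call
from .assembler import assemble_segment
from .config import RunConfig
from .read_store import BamInputError, ReadMap
from .segmentation import ReferenceGenome, Segment, load_reference, tile_reference
from .sv_call import SVCall

log = logging.getLogger(__name__)


@dataclass
class SegmentStats:
    segment: str
    n_barcodes: int = 0
    n_pairs: int = 0
    n_singles: int = 0
    n_long_reads: int = 0
    n_contigs: int = 0
    n_raw_calls: int = 0
    failed: bool = False


@dataclass
class CallResult:
    calls: List[SVCall]
    stats: List[SegmentStats]
    n_segments: int
    n_failed: int


# module-level worker state (initialized per process)
_W: Dict[str, object] = {}


def _worker_init(bam_path: str, long_bam_path: Optional[str],
                 ref_path: str, cfg_dict: dict, read_map: ReadMap) -> None:
    _W["bam"] = pysam.AlignmentFile(bam_path)
    _W["long_bam"] = (pysam.AlignmentFile(long_bam_path)
                      if long_bam_path else None)
    _W["reference"] = load_reference(ref_path)
    _W["config"] = RunConfig.from_dict(cfg_dict)
    _W["read_map"] = read_map
    _W["anchor_index"] = (sv_call.build_anchor_index(_W["reference"])
                          if _W["config"].aligner == "builtin" else None)


def _process_segment(segment: Segment) -> Tuple[List[SVCall], SegmentStats]:
    bam: pysam.AlignmentFile = _W["bam"]                     # type: ignore[assignment]
    long_bam: Optional[pysam.AlignmentFile] = _W["long_bam"]  # type: ignore[assignment]
    reference: ReferenceGenome = _W["reference"]              # type: ignore[assignment]
    config: RunConfig = _W["config"]                          # type: ignore[assignment]
    read_map: ReadMap = _W["read_map"]                        # type: ignore[assignment]

    stats = SegmentStats(segment=str(segment))
    stats_list = barcode_select.barcode_stats(segment, bam)
    barcodes = barcode_select.select_barcodes(stats_list, config.min_pairs,
                                              config.min_span)
    stats.n_barcodes = len(barcodes)
    read_set = barcode_select.gather_reads(segment, barcodes, bam, read_map,
                                           long_bam, config.long_read_cap)
    stats.n_pairs = len(read_set.pairs)
    stats.n_singles = len(read_set.singles)
    stats.n_long_reads = len(read_set.long_reads)

    gfa_path = None
    if config.dump_graphs:
        os.makedirs(config.dump_graphs, exist_ok=True)
        gfa_path = str(Path(config.dump_graphs) /
                       f"seg{segment.index:04d}_{segment.contig}.gfa")
    contigs = assemble_segment(read_set, config.assembly, gfa_path)
    stats.n_contigs = len(contigs)
    if not contigs:
        return [], stats

    alignments = sv_call.align_contigs(contigs, reference, config.aligner,
                                       index=_W.get("anchor_index"))
    calls: List[SVCall] = []
    lo = segment.start - config.call_margin
    hi = segment.end + config.call_margin
    for aln in alignments:
        if aln.target_name != segment.contig:
            continue   # contig mismapped off its segment's chromosome
        for call in sv_call.calls_from_alignment(aln, reference):
            if lo <= call.pos <= hi:
                calls.append(call)
    stats.n_raw_calls = len(calls)
    log.info("segment %s: %d barcodes, %d pairs (+%d singles), %d long reads, "
             "%d contigs, %d raw calls", segment, stats.n_barcodes, stats.n_pairs,
             stats.n_singles, stats.n_long_reads, stats.n_contigs, stats.n_raw_calls)
    return calls, stats


def run_call(bam_path: str, ref_path: str, vcf_path: str,
             config: Optional[RunConfig] = None,
             long_bam_path: Optional[str] = None) -> CallResult:
    """Execute the full calling pipeline and write the VCF.

    Hybrid mode is active iff ``long_bam_path`` is given; an empty long-read
    BAM degrades to SLR-only behaviour with a warning.  Individual segment
    failures are logged and skipped; the result records how many failed.
    """
    config = config or RunConfig()
    config.validate()
    reference = load_reference(ref_path)
    segments = tile_reference(reference.lengths, config.segment_length,
                              config.segment_overlap, config.region)
    if not segments:
        raise BamInputError("reference produced zero segments")

    if long_bam_path is not None:
        with pysam.AlignmentFile(long_bam_path) as lb:
            if not lb.has_index():
                raise BamInputError(f"{long_bam_path} has no index")
            if lb.count(until_eof=True) == 0:
                log.warning("long-read BAM %s is empty; running in SLR-only mode",
                            long_bam_path)
                long_bam_path = None
    mode = "hybrid" if long_bam_path else "SLR-only"
    log.info("mode: %s; %d segments", mode, len(segments))

    primary = config.resolved_primary_contigs(reference.contigs)
    read_map = read_store.build_read_store(
        bam_path, config.qual_min, config.clip_frac_max, primary)

    results: List[Optional[Tuple[List[SVCall], SegmentStats]]] = [None] * len(segments)
    if config.threads == 1:
        _worker_init(bam_path, long_bam_path, ref_path, config.to_dict(), read_map)
        for i, segment in enumerate(segments):
            try:
                results[i] = _process_segment(segment)
            except Exception:
                log.exception("segment %s failed; skipped", segment)
    else:
        with ProcessPoolExecutor(
                max_workers=config.threads, initializer=_worker_init,
                initargs=(bam_path, long_bam_path, ref_path, config.to_dict(),
                          read_map)) as pool:
            futures = {i: pool.submit(_process_segment, seg)
                       for i, seg in enumerate(segments)}
            for i, fut in futures.items():
                try:
                    results[i] = fut.result()
                except Exception:
                    log.exception("segment %s failed; skipped", segments[i])

    all_calls: List[SVCall] = []
    stats: List[SegmentStats] = []
    n_failed = 0
    for i, res in enumerate(results):
        if res is None:
            n_failed += 1
            stats.append(SegmentStats(segment=str(segments[i]), failed=True))
            continue
        calls, st = res
        all_calls.extend(calls)
        stats.append(st)

    kept = sv_call.filter_calls(all_calls, config.min_sv, config.max_sv)
    deduped = sv_call.deduplicate(kept, config.dedup_slack)
    sv_call.write_vcf(deduped, reference, vcf_path, reference_path=ref_path,
                      params_line=config.parameter_line() + f",mode={mode}")
    log.info("%d raw calls -> %d in size window -> %d after dedup",
             len(all_calls), len(kept), len(deduped))
    return CallResult(deduped, stats, len(segments), n_failed)
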