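"""Run configuration for the caller pipeline.

All tunables of the pipeline live in :class:`RunConfig` (segmentation,
bad-read filtering, barcode selection, assembly, SV size window) so that a
single object can be validated once, serialized into the VCF header, and
round-tripped through YAML config files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of bounds."""


#: Primary (placed) contigs of a human reference; everything else counts as
#: "unplaced" for bad-read rule (b).  Overridable for non-human/toy genomes.
HUMAN_PRIMARY_CONTIGS = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
    + [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "M"]
)


@dataclass
class AssemblyParams:
    """Parameters of per-segment de Bruijn assembly and simplification.

    Lengths are in bp.  Coverage thresholds are ratios relative to either the
    alternative branch or the length-weighted median unitig coverage of the
    segment graph ("local median").
    """

    k: int = 55                      # k-mer size; auto-lowered to read length - 10, forced odd
    solid_threshold: int = 2         # min k-mer multiplicity to enter the graph
    tip_len_max: int = 110           # tips shorter than this may be clipped (default 2k)
    tip_cov_max: float = 0.5         # ... if coverage < tip_cov_max * local median
    bulge_len_max: int = 110         # bulge sides longer than this are never removed (default 2k)
    bulge_cov_ratio_max: float = 0.2  # weak side removed only if cov < ratio * strong side
    het_keep_ratio: float = 0.25     # ... and cov < het_keep_ratio * local median (het protection)
    long_tip_min: int = 550          # dead ends at least this long are "long tips" (default 10k)
    tip_vicinity: int = 5000         # graph-distance radius of the extension-halting search
    tip_vicinity_rule: bool = True   # halting rule on/off (off reproduces coverage-gap misjoins)
    fork_cap: int = 16               # max paths a single seed may fork into at bulges
    loop_unroll_max: int = 20        # cap on tandem-loop traversals
    tandem_period_max: int = 1000    # longest loop body treated as a collapsed tandem
    stub_cov_max: float = 0.5        # skippable dead stubs are below this x median coverage
    fork_meet_cov_max: float = 1.75  # bulge sides must reconverge below this x median coverage
    bulge_search_len: int = 12000    # how far branch chains are walked to find reconvergence
    cycle_search_len: int = 12000    # how far the loop-closure search may look (chained repeats)
    anchor_len: int = 21             # exact-match seed length for long-read gap closing
    end_window: int = 200            # contig-end window searched for gap-closing anchors
    max_gap_fill: int = 15000        # longest long-read stretch spliced into a join

    def validate(self) -> None:
        if self.k < 11 or self.k % 2 == 0:
            raise ConfigError(f"k must be odd and >= 11, got {self.k}")
        for name in ("tip_len_max", "bulge_len_max", "long_tip_min",
                     "tip_vicinity", "anchor_len", "end_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("tip_cov_max", "bulge_cov_ratio_max", "het_keep_ratio"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")

    def scaled_to(self, k: int) -> "AssemblyParams":
        """Return a copy with thresholds that default to multiples of k rescaled."""
        return dataclasses.replace(
            self, k=k, tip_len_max=2 * k, bulge_len_max=2 * k, long_tip_min=10 * k)


@dataclass
class RunConfig:
    """Everything the `call` pipeline needs besides the input paths."""

    segment_length: int = 50_000
    segment_overlap: int = 10_000
    # bad-read rules
    qual_min: int = 20               # rule (a): every base strictly above this
    clip_frac_max: float = 0.20      # rule (b): strictly more than this soft-clipped
    primary_contigs: Optional[Sequence[str]] = None   # None -> human allowlist
    # barcode selection
    min_pairs: int = 3               # at least this many read pairs in segment
    min_span: int = 5_000            # leftmost-rightmost distance strictly above this
    # long reads
    long_read_cap: int = 100
    # SV size window (inclusive)
    min_sv: int = 50
    max_sv: int = 10_000
    dedup_slack: int = 0             # 0 = exact breakpoint+length dedup
    # Calls are kept only within segment +- call_margin.  The overlap zone is
    # interior to the neighbouring segment, so a small margin (alignment
    # jitter only) suffices; a generous margin lets read-map-only "ghost"
    # assemblies of far-away loci emit partial-evidence duplicates.
    call_margin: int = 500
    aligner: str = "builtin"         # "builtin" | "minimap2"
    threads: int = 1
    seed: int = 0
    region: Optional[str] = None     # "contig" or "contig:start-end" (1-based)
    dump_graphs: Optional[str] = None
    assembly: AssemblyParams = field(default_factory=AssemblyParams)

    def validate(self) -> None:
        if not 0 <= self.segment_overlap < self.segment_length:
            raise ConfigError(
                f"segment overlap ({self.segment_overlap}) must be >= 0 and "
                f"smaller than segment length ({self.segment_length})")
        if self.min_sv < 1 or self.max_sv < self.min_sv:
            raise ConfigError("require 1 <= min_sv <= max_sv")
        if not 0 <= self.clip_frac_max <= 1:
            raise ConfigError("clip_frac_max must be in [0, 1]")
        if self.min_pairs < 0 or self.min_span < 0:
            raise ConfigError("barcode thresholds must be non-negative")
        if self.long_read_cap < 0:
            raise ConfigError("long_read_cap must be non-negative")
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")
        if self.aligner not in ("builtin", "minimap2"):
            raise ConfigError(f"unknown aligner backend {self.aligner!r}")
        self.assembly.validate()

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["primary_contigs"] is not None:
            d["primary_contigs"] = list(d["primary_contigs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        asm = d.pop("assembly", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"assembly"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d, assembly=AssemblyParams(**asm))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def parameter_line(self) -> str:
        """Compact ``key=value`` rendering for the VCF header."""
        d = self.to_dict()
        asm = d.pop("assembly")
        d.update({f"assembly.{k}": v for k, v in asm.items()})
        # thread count is an execution detail: identical results by contract
        return ",".join(f"{k}={v}" for k, v in sorted(d.items())
                        if v is not None and k not in ("dump_graphs", "threads"))

    def resolved_primary_contigs(self, reference_contigs: Sequence[str]) -> frozenset:
        """Contigs treated as 'placed'.

        When no allowlist is configured: if the reference looks human
        (intersects the standard chromosome names) use the human allowlist,
        otherwise treat every contig of the supplied reference as placed.
        """
        if self.primary_contigs is not None:
            return frozenset(self.primary_contigs)
        human = frozenset(HUMAN_PRIMARY_CONTIGS)
        if human & set(reference_contigs):
            return human
        return frozenset(reference_contigs)
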