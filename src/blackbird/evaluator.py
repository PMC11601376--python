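"""Benchmark-style comparison of a call set against a truth set.

Matching follows the positional protocol used for simulated benchmarks:
a call is a true positive when a truth event of the same type on the same
contig lies within ``max_dist`` bp of its breakpoint; matching is greedy
one-to-one by increasing breakpoint distance.  Both sets are size-filtered
with the same inclusive window before matching.  Precision, recall and F1
are reported per SV type and combined; an undefined ratio (zero
denominator) is reported as NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .sv_call import SVCall, filter_calls

SV_TYPES = ("DEL", "INS")


@dataclass
class TypeResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    matched: List[Tuple[SVCall, SVCall]] = field(default_factory=list)

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class MatchResult:
    per_type: Dict[str, TypeResult]
    max_dist: int

    @property
    def combined(self) -> TypeResult:
        out = TypeResult()
        for res in self.per_type.values():
            out.tp += res.tp
            out.fp += res.fp
            out.fn += res.fn
            out.matched.extend(res.matched)
        return out


def _match_one_type(calls: List[SVCall], truth: List[SVCall],
                    max_dist: int) -> TypeResult:
    pairs = []
    for ci, call in enumerate(calls):
        for ti, tru in enumerate(truth):
            if call.chrom != tru.chrom:
                continue
            dist = abs(call.pos - tru.pos)
            if dist <= max_dist:
                pairs.append((dist, ci, ti))
    pairs.sort()
    used_c: set = set()
    used_t: set = set()
    res = TypeResult()
    for dist, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        res.matched.append((calls[ci], truth[ti]))
    res.tp = len(res.matched)
    res.fp = len(calls) - res.tp
    res.fn = len(truth) - res.tp
    return res


def match(calls: Sequence[SVCall], truth: Sequence[SVCall],
          max_dist: int = 100, min_len: int = 50,
          max_len: int = 10_000) -> MatchResult:
    """Greedy one-to-one positional matching, per SV type."""
    calls = filter_calls(calls, min_len, max_len)
    truth = filter_calls(truth, min_len, max_len)
    per_type = {}
    for svtype in SV_TYPES:
        per_type[svtype] = _match_one_type(
            [c for c in calls if c.svtype == svtype],
            [t for t in truth if t.svtype == svtype],
            max_dist)
    return MatchResult(per_type, max_dist)


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.4f}"


def score(result: MatchResult) -> str:
    """Tab-separated report: one line per type plus the combined line."""
    lines = ["type\tTP\tFP\tFN\tprecision\trecall\tF1"]
    rows = list(result.per_type.items()) + [("ALL", result.combined)]
    for name, res in rows:
        lines.append(f"{name}\t{res.tp}\t{res.fp}\t{res.fn}\t"
                     f"{_fmt(res.precision)}\t{_fmt(res.recall)}\t{_fmt(res.f1)}")
    return "\n".join(lines) + "\n"


def split_by_type(calls: Sequence[SVCall]) -> Dict[str, List[SVCall]]:
    """Type-split call lists (e.g. for export to external benchmarking)."""
    return {t: [c for c in calls if c.svtype == t] for t in SV_TYPES}
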