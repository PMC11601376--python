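"""Per-segment de Bruijn assembly tuned for diploid SV discovery.

The assembler differs from an isolate-genome assembler in three deliberate
ways:

* **Relaxed simplification.**  Tips and bulge sides are removed only when
  their coverage is low both relative to the competing branch and relative
  to the (length-weighted median) segment coverage.  A balanced bulge — the
  graph signature of a heterozygous variant — is never collapsed.

* **No path deduplication, bulge forking instead.**  At a junction whose two
  branches reconverge, path extension *forks* and emits both traversals, so
  both alleles of a heterozygous SV appear as full-length contigs.  Redundant
  calls are collapsed later at the VCF level, where they are cheap.

* **Tip-aware extension halting.**  A coverage dropout inside a repeat can
  leave a single "obvious" continuation across a join that splices two
  different repeat copies together and fakes a deletion.  Before crossing a
  join (entering a unitig with several predecessors, or extending backwards
  out of a unitig with several successors), the extender searches the graph
  neighbourhood for long dead ends — the footprint of a dropout — and
  terminates the contig if it finds one.

Additionally, a collapsed tandem-repeat cycle is unrolled
``round(loop coverage / entry coverage)`` times during extension, so
tandem-repeat-like insertions produce a spanning contig (with an estimated,
not exact, copy number).

Long reads never contribute k-mers to the graph — at 0.1–1 % error they
would seed spurious parallel paths — and are used exclusively by
:func:`close_gaps`, which splices contigs across coverage gaps via exact
anchor seeds.

The graph is a plain directed de Bruijn graph over the read sequences as
stored in the BAM.  Aligners emit SEQ reference-forward, so the input is
assumed orientation-normalized; contigs come out in reference orientation.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .barcode_select import SegmentReadSet
from .config import AssemblyParams
from .segmentation import Segment

log = logging.getLogger(__name__)

_ACGT = "ACGT"


@dataclass
class Unitig:
    uid: int
    seq: str
    cov: float    # mean k-mer multiplicity
    nk: int       # number of k-mers


@dataclass
class AssemblyGraph:
    """Compressed de Bruijn graph: unitigs linked with k-1 overlaps."""

    k: int
    units: Dict[int, Unitig] = field(default_factory=dict)
    outs: Dict[int, List[int]] = field(default_factory=dict)
    ins: Dict[int, List[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.units)

    def median_coverage(self) -> float:
        """Length-weighted median unitig coverage ("local median")."""
        if not self.units:
            return 0.0
        items = sorted(((u.cov, u.nk) for u in self.units.values()))
        total = sum(nk for _, nk in items)
        acc = 0
        for cov, nk in items:
            acc += nk
            if 2 * acc >= total:
                return cov
        return items[-1][0]

    def remove(self, uid: int) -> None:
        for other in self.outs.pop(uid, ()):
            if other != uid:
                self.ins[other] = [x for x in self.ins[other] if x != uid]
        for other in self.ins.pop(uid, ()):
            if other != uid:
                self.outs[other] = [x for x in self.outs[other] if x != uid]
        del self.units[uid]

    def spell(self, path: Sequence[int]) -> str:
        if not path:
            return ""
        parts = [self.units[path[0]].seq]
        parts.extend(self.units[uid].seq[self.k - 1:] for uid in path[1:])
        return "".join(parts)


@dataclass
class Contig:
    id: str
    seq: str
    path: Tuple[int, ...]
    segment: Optional[Segment] = None

    def __len__(self) -> int:
        return len(self.seq)


def count_kmers(seqs: Iterable[str], k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for seq in seqs:
        n = len(seq) - k + 1
        for i in range(n):
            km = seq[i:i + k]
            counts[km] = counts.get(km, 0) + 1
    # k-mers containing N are never solid
    return {km: c for km, c in counts.items() if "N" not in km}


def build_graph(reads: SegmentReadSet | Sequence[str], k: int,
                solid_threshold: int = 2) -> AssemblyGraph:
    """Build the compressed graph from short-read k-mers of multiplicity
    >= ``solid_threshold``.  An empty read set yields an empty graph."""
    if isinstance(reads, SegmentReadSet):
        seqs: Sequence[str] = reads.short_read_sequences()
    else:
        seqs = reads
    counts = count_kmers(seqs, k)
    solid = {km: c for km, c in counts.items() if c >= solid_threshold}
    return _compress(solid, k)


def _compress(solid: Dict[str, int], k: int) -> AssemblyGraph:
    graph = AssemblyGraph(k=k)
    if not solid:
        return graph

    def succs(km: str) -> List[str]:
        suf = km[1:]
        return [suf + b for b in _ACGT if suf + b in solid]

    def preds(km: str) -> List[str]:
        pre = km[:-1]
        return [b + pre for b in _ACGT if b + pre in solid]

    # a k-mer starts a unitig unless it has exactly one predecessor whose
    # out-degree is one
    starts = []
    for km in solid:
        p = preds(km)
        if len(p) != 1 or len(succs(p[0])) != 1:
            starts.append(km)
    starts.sort()

    first_of: Dict[str, int] = {}
    assigned: Set[str] = set()
    uid = 0

    def walk(start: str) -> List[str]:
        chain = [start]
        assigned.add(start)
        cur = start
        while True:
            s = succs(cur)
            if len(s) != 1:
                break
            nxt = s[0]
            if nxt in assigned or len(preds(nxt)) != 1:
                break
            chain.append(nxt)
            assigned.add(nxt)
            cur = nxt
        return chain

    chains: List[List[str]] = []
    for km in starts:
        chains.append(walk(km))
    # isolated cycles have no start k-mer; sweep the leftovers
    for km in sorted(solid):
        if km not in assigned:
            chains.append(walk(km))

    for chain in chains:
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        cov = sum(solid[km] for km in chain) / len(chain)
        graph.units[uid] = Unitig(uid, seq, cov, len(chain))
        first_of[chain[0]] = uid
        uid += 1

    for u, chain in enumerate(chains):
        out = []
        for nxt in succs(chain[-1]):
            out.append(first_of[nxt])
        graph.outs[u] = sorted(out)
    graph.ins = {u: [] for u in graph.units}
    for u, targets in graph.outs.items():
        for t in targets:
            graph.ins[t].append(u)
    for u in graph.ins:
        graph.ins[u].sort()
    return graph


def _recompress(graph: AssemblyGraph) -> None:
    """Merge maximal non-branching unitig chains in place."""
    k = graph.k
    merged = True
    while merged:
        merged = False
        for uid in sorted(graph.units):
            if uid not in graph.units:
                continue
            outs = graph.outs[uid]
            if len(outs) != 1:
                continue
            w = outs[0]
            if w == uid or len(graph.ins[w]) != 1:
                continue
            # merge w into uid
            a, b = graph.units[uid], graph.units[w]
            a.seq = a.seq + b.seq[k - 1:]
            a.cov = (a.cov * a.nk + b.cov * b.nk) / (a.nk + b.nk)
            a.nk += b.nk
            graph.outs[uid] = [uid if x == w else x for x in graph.outs[w]]
            for t in graph.outs[uid]:
                graph.ins[t] = sorted(uid if x == w else x for x in graph.ins[t])
            del graph.units[w], graph.outs[w], graph.ins[w]
            merged = True


def simplify(graph: AssemblyGraph, params: AssemblyParams) -> AssemblyGraph:
    """Relaxed tip clipping and bulge resolution (in place; returns graph).

    Iterates to a fixpoint, so the operation is idempotent.  A tip is removed
    only when short *and* weak relative to the segment median; a bulge side
    only when dominated by its sibling *and* weak in absolute terms —
    balanced (heterozygous) bulges always survive.  Whole-path deduplication
    never happens.
    """
    changed = True
    while changed:
        changed = False
        median = graph.median_coverage()
        # tips: dead-ended on exactly one side
        for uid in sorted(graph.units):
            u = graph.units[uid]
            indeg, outdeg = len(graph.ins[uid]), len(graph.outs[uid])
            dead_in, dead_out = indeg == 0, outdeg == 0
            if dead_in == dead_out:   # isolated or internal
                continue
            if len(u.seq) < params.tip_len_max and u.cov < params.tip_cov_max * median:
                graph.remove(uid)
                changed = True
        # simple bulges: sides sharing one source and one sink
        for src in sorted(graph.units):
            groups: Dict[int, List[int]] = {}
            for c in graph.outs.get(src, ()):
                if c == src or graph.ins.get(c) != [src]:
                    continue
                outs_c = graph.outs.get(c, ())
                if len(outs_c) == 1 and outs_c[0] != c:
                    groups.setdefault(outs_c[0], []).append(c)
            for sides in groups.values():
                if len(sides) < 2:
                    continue
                sides.sort(key=lambda c: (-graph.units[c].cov, c))
                strong = graph.units[sides[0]]
                for c in sides[1:]:
                    weak = graph.units[c]
                    if (len(weak.seq) < params.bulge_len_max
                            and weak.cov < params.bulge_cov_ratio_max * strong.cov
                            and weak.cov < params.het_keep_ratio * median):
                        graph.remove(c)
                        changed = True
        if changed:
            _recompress(graph)
    return graph


# ---------------------------------------------------------------------------
# path extension
# ---------------------------------------------------------------------------

def _nbrs(graph: AssemblyGraph, uid: int, direction: int) -> List[int]:
    return graph.outs[uid] if direction > 0 else graph.ins[uid]


def _is_join(graph: AssemblyGraph, w: int, direction: int) -> bool:
    """Crossing into ``w`` merges paths: several predecessors ahead of it
    (forward) or several successors behind it (backward)."""
    back = graph.ins[w] if direction > 0 else graph.outs[w]
    return len(back) > 1


def _long_tip_nearby(graph: AssemblyGraph, cur: int, w: int, direction: int,
                     params: AssemblyParams) -> bool:
    """Is the *dead endpoint* of a long tip within tip_vicinity bp of the
    junction between ``cur`` and ``w``?

    Distances are endpoint-resolved: each unitig contributes two graph nodes
    (head, tail) joined by its internal length, links cost nothing.  A dead
    endpoint (a head with no predecessors or a tail with no successors)
    belonging to a unitig of length >= long_tip_min marks a coverage-dropout
    tip; a dead end whose endpoint lies beyond the radius — e.g. the far end
    of a long backbone unitig running to the segment boundary — does not.
    """
    H, T = 0, 1
    # junction point: cur's outgoing endpoint == w's incoming endpoint
    seeds = [(cur, T), (w, H)] if direction > 0 else [(cur, H), (w, T)]
    dist: Dict[Tuple[int, int], int] = {s: 0 for s in seeds}
    heap: List[Tuple[int, int, int]] = [(0, uid, end) for uid, end in seeds]
    heapq.heapify(heap)
    while heap:
        d, uid, end = heapq.heappop(heap)
        if d > dist.get((uid, end), 1 << 60) or d > params.tip_vicinity:
            continue
        u = graph.units[uid]
        dead = (end == H and not graph.ins[uid]) or (end == T and not graph.outs[uid])
        if dead and len(u.seq) >= params.long_tip_min \
                and (graph.ins[uid] or graph.outs[uid]):
            return True
        nbrs: List[Tuple[int, int, int]] = []
        internal = max(len(u.seq) - graph.k + 1, 1)
        nbrs.append((d + internal, uid, T if end == H else H))
        if end == T:
            nbrs.extend((d, v, H) for v in graph.outs[uid])
        else:
            nbrs.extend((d, v, T) for v in graph.ins[uid])
        for nd, vid, vend in nbrs:
            if nd < dist.get((vid, vend), 1 << 60):
                dist[(vid, vend)] = nd
                heapq.heappush(heap, (nd, vid, vend))
    return False


def _cycle_path(graph: AssemblyGraph, start: int, target: int, direction: int,
                max_bp: int) -> Optional[List[int]]:
    """Shortest (in bp) directed path start -> target, or None.

    Detects collapsed tandem cycles: a junction candidate that leads back to
    the current unitig closes a loop.  Bounded by ``max_bp`` of sequence.
    """
    if start == target:
        return [start]
    dist: Dict[int, int] = {start: len(graph.units[start].seq)}
    prev: Dict[int, int] = {}
    heap: List[Tuple[int, int]] = [(dist[start], start)]
    while heap:
        d, uid = heapq.heappop(heap)
        if d > dist.get(uid, 1 << 60):
            continue
        for nxt in _nbrs(graph, uid, direction):
            if nxt == target:
                chain = [uid]
                while chain[-1] != start:
                    chain.append(prev[chain[-1]])
                chain.reverse()
                return chain + [target]
            nd = d + len(graph.units[nxt].seq) - graph.k + 1
            if nd <= max_bp and nd < dist.get(nxt, 1 << 60):
                dist[nxt] = nd
                prev[nxt] = uid
                heapq.heappush(heap, (nd, nxt))
    return None


def _cycle_coverage(graph: AssemblyGraph, body: Sequence[int]) -> float:
    uids = set(body)
    total = sum(graph.units[u].nk for u in uids)
    return sum(graph.units[u].cov * graph.units[u].nk for u in uids) / total


def _cycle_info(graph: AssemblyGraph, cur: int, cands: List[int],
                direction: int, median: float, params: AssemblyParams
                ) -> Optional[Tuple[int, int, int, int]]:
    """Loop handling at a two-way junction: which branch closes a cycle,
    and how often to traverse it.

    When exactly one candidate leads back to ``cur``, the junction sits on a
    repeat and the path must decide between re-entering the loop and taking
    the exit.  Two regimes:

    * short loop body (period <= tandem_period_max): a collapsed tandem
      repeat; copy number = round(loop-body coverage / graph median).
    * long loop body: ``cur`` is a repeat occurring at several chained loci
      (e.g. a mobile-element donor inserted twice in one segment) and the
      loop body is the sequence between them; the locus count =
      round(coverage of the shared unitig / median), at least 2 (a cycle
      cannot exist with a single copy).  Unrolling the loop that many times
      visits every locus in genome order; exiting early would splice distant
      loci together and fake a deletion.

    Returns (loop candidate, exit candidate, total traversals m, marker
    unitig) or None when the junction has no unique cycle.  The median-based
    estimates are direction-independent, so overlapping paths spell the same
    sequence and their calls collapse in deduplication.
    """
    if len(cands) != 2:
        return None
    back = [(c, _cycle_path(graph, c, cur, direction, params.cycle_search_len))
            for c in cands]
    cyclic = [(c, b) for c, b in back if b is not None]
    if len(cyclic) != 1:
        return None
    c_loop, body = cyclic[0]
    c_exit = cands[0] if cands[1] == c_loop else cands[1]
    ref_cov = max(median, 1.0)
    loop_units = [u for u in body if u != cur] or [cur]
    period = sum(len(graph.units[u].seq) - graph.k + 1 for u in loop_units)
    if period <= params.tandem_period_max:
        cov = max(_cycle_coverage(graph, loop_units),
                  _cycle_coverage(graph, body + [cur]))
        m = max(1, int(cov / ref_cov + 0.5))
        m = min(m, params.loop_unroll_max)
        return c_loop, c_exit, m, body[0]
    # chained repeat: traverse the inter-locus body exactly once; a body
    # unitig already on the path means every locus is consumed, and looping
    # again would spell a duplication chimera
    return c_loop, c_exit, -1, -1


def _reconverge(chain1: List[int], chain2: List[int]
                ) -> Optional[Tuple[List[int], List[int], int]]:
    """Find the earliest common unitig of two branch chains.

    Returns (side1, side2, meet) with the sides truncated before the meeting
    unitig, or None when the branches never reconverge within the walked
    window."""
    set1 = {uid: i for i, uid in reversed(list(enumerate(chain1)))}
    best = None
    for j, uid in enumerate(chain2):
        if uid in set1:
            i = set1[uid]
            if best is None or i + j < best[0]:
                best = (i + j, i, j, uid)
    if best is None:
        return None
    _, i, j, uid = best
    return chain1[:i], chain2[:j], uid


class _Extender:
    """Greedy, forking path extension over a simplified graph.

    Junction policy, in order:

    * a candidate closing a cycle back to the current unitig is a collapsed
      tandem loop: unroll by coverage, then exit;
    * short dead branches (< long_tip_min bp) never block extension: they
      are artifact stubs (e.g. junction fragments of a repeat's other copies
      recruited via the read map) and are skipped when exactly one
      continuing branch remains;
    * two continuing branches that reconverge are a bulge (the two alleles
      of a heterozygous variant): extension forks and emits both;
    * crossing a *join* (a unitig with other predecessors ahead, or other
      successors behind when extending backwards) is refused when the
      tip-vicinity rule finds a long dead end nearby (coverage-dropout
      signature) or when the current path is itself shorter than
      long_tip_min (an artifact stub must not be spliced through a repeat);
    * anything else terminates the contig.
    """

    def __init__(self, graph: AssemblyGraph, params: AssemblyParams,
                 max_bp: int) -> None:
        self.g = graph
        self.p = params
        self.max_bp = max_bp
        self.median = graph.median_coverage()
        self._cycle_cache: Dict[Tuple[int, Tuple[int, ...], int],
                                Optional[Tuple[int, int, int, int]]] = {}
        self._walk_cache: Dict[Tuple[int, int, int], Tuple[List[int], bool]] = {}
        self._tip_cache: Dict[Tuple[int, int, int], bool] = {}

    def _cycle_step(self, path: List[int], cur: int, cands: List[int],
                    direction: int) -> Optional[int]:
        key = (cur, tuple(cands), direction)
        if key not in self._cycle_cache:
            self._cycle_cache[key] = _cycle_info(self.g, cur, cands, direction,
                                                 self.median, self.p)
        info = self._cycle_cache[key]
        if info is None:
            return None
        c_loop, c_exit, m, marker = info
        if m < 0:    # chained repeat regime
            body = _cycle_path(self.g, c_loop, cur, direction,
                               self.p.cycle_search_len) or []
            used = (set(body) - {cur}) & set(path)
            return c_exit if used else c_loop
        done = path.count(marker)
        target = m if marker == cur else m - 1
        return c_loop if done < target else c_exit

    def _path_bp(self, path: List[int]) -> int:
        k = self.g.k
        return sum(len(self.g.units[u].seq) - k + 1 for u in path) + k - 1

    # -- bounded branch exploration ------------------------------------

    def _walk(self, start: int, direction: int, depth: int
              ) -> Tuple[List[int], bool]:
        """Forced walk from ``start`` (with loop unrolling and tip skipping);
        returns (chain, ended_at_dead_end)."""
        key = (start, direction, depth)
        if key in self._walk_cache:
            return self._walk_cache[key]
        g, p = self.g, self.p
        chain = [start]
        bp = len(g.units[start].seq)
        dead = False
        while bp < p.bulge_search_len:
            cur = chain[-1]
            cands = _nbrs(g, cur, direction)
            if not cands:
                dead = True
                break
            nxt: Optional[int] = None
            if len(cands) == 1:
                c = cands[0]
                if c in chain and chain.count(c) >= p.loop_unroll_max:
                    break
                nxt = c
            elif depth > 0:
                non_tips = self._non_tips(cands, direction, depth - 1)
                if len(non_tips) == 1:
                    nxt = non_tips[0]
                elif len(non_tips) == 2:
                    nxt = self._cycle_step(chain, cur, non_tips, direction)
            else:
                nxt = self._cycle_step(chain, cur, cands, direction)
            if nxt is None:
                break
            chain.append(nxt)
            bp += len(g.units[nxt].seq) - g.k + 1
        self._walk_cache[key] = (chain, dead)
        return chain, dead

    def _non_tips(self, cands: List[int], direction: int,
                  depth: int) -> List[int]:
        """Candidates whose bounded walk is not a low-coverage short dead
        branch.  Such branches are artifact stubs — junction fragments of a
        repeat's other loci recruited through the read map — recognizable by
        being dead-ended, short, *and* thinly covered; a short dead branch
        at normal coverage (e.g. backbone truncated at the segment boundary)
        is a real continuation."""
        out = []
        for c in cands:
            chain, dead = self._walk(c, direction, depth)
            bp = sum(len(self.g.units[u].seq) - self.g.k + 1 for u in chain)
            cov = _cycle_coverage(self.g, chain)
            stub = (dead and bp < self.p.long_tip_min
                    and cov < self.p.stub_cov_max * self.median)
            if not stub:
                out.append(c)
        return out

    # -- main extension -------------------------------------------------

    def grow(self, seed: int) -> List[List[int]]:
        rights = self._extend([seed], +1, budget=[self.p.fork_cap])
        finals: List[List[int]] = []
        budget = [self.p.fork_cap]
        for path in rights:
            finals.extend(self._extend(path, -1, budget=budget))
        return finals

    def _may_cross_join(self, path: List[int], cur: int, w: int,
                        direction: int) -> bool:
        if not _is_join(self.g, w, direction):
            return True
        if self._path_bp(path) < self.p.long_tip_min:
            return False
        if self.p.tip_vicinity_rule:
            key = (cur, w, direction)
            if key not in self._tip_cache:
                self._tip_cache[key] = _long_tip_nearby(self.g, cur, w,
                                                        direction, self.p)
            if self._tip_cache[key]:
                return False
        return True

    def _extend(self, path: List[int], direction: int,
                budget: List[int]) -> List[List[int]]:
        g, p = self.g, self.p
        path = list(path)
        while self._path_bp(path) < self.max_bp:
            cur = path[-1] if direction > 0 else path[0]
            cands = _nbrs(g, cur, direction)
            step: Optional[int] = None
            if len(cands) == 0:
                break
            elif len(cands) == 1:
                w = cands[0]
                if w in path and path.count(w) >= p.loop_unroll_max:
                    break   # exitless cycle; stop rather than spin
                if not self._may_cross_join(path, cur, w, direction):
                    break
                step = w
            else:
                non_tips = self._non_tips(cands, direction, depth=2)
                if len(non_tips) == 1:
                    w = non_tips[0]
                    if w in path and path.count(w) >= p.loop_unroll_max:
                        break
                    if not self._may_cross_join(path, cur, w, direction):
                        break
                    step = w
                elif len(non_tips) == 2:
                    step = self._cycle_step(path, cur, non_tips, direction)
                    if step is None:
                        if budget[0] > 0:
                            fork = self._try_fork(path, non_tips, direction, budget)
                            if fork is not None:
                                return fork
                        break
                else:
                    break
            if step is None:
                break
            if direction > 0:
                path.append(step)
            else:
                path.insert(0, step)
        return [path]

    def _try_fork(self, path: List[int], cands: List[int], direction: int,
                  budget: List[int]) -> Optional[List[List[int]]]:
        c1, c2 = sorted(cands)
        chain1, _ = self._walk(c1, direction, depth=2)
        chain2, _ = self._walk(c2, direction, depth=2)
        rec = _reconverge(chain1, chain2)
        if rec is None:
            return None
        side1, side2, meet = rec
        cur = path[-1] if direction > 0 else path[0]
        # "reconvergence" through the junction unitig itself means one branch
        # loops around a repeat back to where we stand; the branches are not
        # alleles.  The looping side is the parsimonious traversal of the
        # intervening sequence; the skipping side would assert a deletion
        # from repeat topology alone (the classic false-join mode), so only
        # the looping side is continued and no fork is emitted.
        loops1, loops2 = cur in side1, cur in side2
        if loops1 or loops2:
            # "reconvergence" through the junction unitig itself means one
            # branch loops around a repeat back to where we stand; continue
            # along the looping side only (the parsimonious traversal) and
            # never emit the skipping side, which would assert a deletion
            # from repeat topology alone
            if loops1 and loops2:
                return None
            side = side1 if loops1 else side2
            if direction > 0:
                new_path = path + side + [meet]
            else:
                new_path = [meet] + side[::-1] + path
            return self._extend(new_path, direction, budget)
        # a true allelic bulge reconverges on near-median backbone; a meet
        # at twice-median coverage is a repeat shared by several homozygous
        # loci, where forking would splice distant loci together
        if self.g.units[meet].cov > self.p.fork_meet_cov_max * self.median:
            return None
        budget[0] -= 1
        out: List[List[int]] = []
        for side in (side1, side2):
            if direction > 0:
                new_path = path + side + [meet]
            else:
                new_path = [meet] + side[::-1] + path
            out.extend(self._extend(new_path, direction, budget))
        return out


def extend_paths(graph: AssemblyGraph, params: AssemblyParams,
                 max_bp: Optional[int] = None) -> List[List[int]]:
    """Emit unitig paths covering the graph.

    Seeds are unvisited unitigs in descending length order (backbone first);
    every unitig ends up in at least one path.  Returns paths of unitig ids;
    use :meth:`AssemblyGraph.spell` for sequences.
    """
    if max_bp is None:
        max_bp = 2_000_000
    ext = _Extender(graph, params, max_bp)
    order = sorted(graph.units, key=lambda u: (-len(graph.units[u].seq), u))
    visited: Set[int] = set()
    paths: List[List[int]] = []
    for seed in order:
        if seed in visited:
            continue
        for path in ext.grow(seed):
            paths.append(path)
            visited.update(path)
    return paths


# ---------------------------------------------------------------------------
# long-read gap closing
# ---------------------------------------------------------------------------

def close_gaps(contigs: List[Contig], long_reads: List[Tuple[str, str]],
               params: AssemblyParams, _round: int = 0) -> List[Contig]:
    """Join contig ends across coverage gaps using spanning long reads.

    A long read supports the join (A, B) when an exact ``anchor_len``-mer
    from A's tail window and one from B's head window both occur in the read
    in the right order; the read's intervening sequence fills the gap.
    Within each conflict group the best-supported join wins; ties between
    joins whose gap-adjacent sequence is identical are *variants* of the
    same junction (bulge forks of one locus) and are all performed; genuine
    ties are abstained from.  Chains of joins resolve over a few recursive
    rounds.
    """
    if not long_reads or len(contigs) < 2 or _round >= 3:
        return contigs
    a_len, win = params.anchor_len, params.end_window

    read_index: List[Tuple[str, str, Dict[str, int]]] = []
    for name, seq in sorted(long_reads):
        idx: Dict[str, int] = {}
        for i in range(len(seq) - a_len + 1):
            km = seq[i:i + a_len]
            if km not in idx:
                idx[km] = i
        read_index.append((name, seq, idx))

    def tail_anchor(seq: str, idx: Dict[str, int]) -> Optional[Tuple[int, int]]:
        lo = max(0, len(seq) - win)
        for p in range(len(seq) - a_len, lo - 1, -1):
            r = idx.get(seq[p:p + a_len])
            if r is not None:
                return p, r
        return None

    def head_anchor(seq: str, idx: Dict[str, int]) -> Optional[Tuple[int, int]]:
        hi = min(len(seq) - a_len, win)
        for p in range(0, hi + 1):
            r = idx.get(seq[p:p + a_len])
            if r is not None:
                return p, r
        return None

    support: Dict[Tuple[int, int], int] = {}
    splice: Dict[Tuple[int, int], Tuple[int, int, int, int, str]] = {}
    for name, rseq, idx in read_index:
        tails = {}
        heads = {}
        for ci, contig in enumerate(contigs):
            t = tail_anchor(contig.seq, idx)
            if t:
                tails[ci] = t
            h = head_anchor(contig.seq, idx)
            if h:
                heads[ci] = h
        for i, (pa, ra) in tails.items():
            for j, (pb, rb) in heads.items():
                if i == j or rb <= ra or rb - ra > params.max_gap_fill:
                    continue
                key = (i, j)
                support[key] = support.get(key, 0) + 1
                if key not in splice:
                    splice[key] = (pa, ra, rb, pb, rseq)
    if not support:
        return contigs

    ctx = 300   # bp of gap-adjacent sequence compared to spot junction variants

    def winners(keys: List[Tuple[int, int]], side: int) -> List[Tuple[int, int]]:
        best = max(support[k] for k in keys)
        top = sorted(k for k in keys if support[k] == best)
        if len(top) == 1:
            return top
        # identical gap-adjacent sequence on the varying side -> variants of
        # one junction, all joinable; otherwise a genuine conflict
        sigs = set()
        for k in top:
            pa, ra, rb, pb, _ = splice[k]
            if side == 0:      # same tail, several heads: compare head starts
                sigs.add(contigs[k[1]].seq[pb:pb + ctx])
            else:              # same head, several tails: compare tail ends
                sigs.add(contigs[k[0]].seq[max(0, pa - ctx):pa])
        if len(sigs) == 1:
            return top
        log.info("gap closing: %d conflicting joins with equal support; abstaining",
                 len(top))
        return []

    by_tail: Dict[int, List[Tuple[int, int]]] = {}
    by_head: Dict[int, List[Tuple[int, int]]] = {}
    for key in support:
        by_tail.setdefault(key[0], []).append(key)
        by_head.setdefault(key[1], []).append(key)
    tail_ok = {k for keys in by_tail.values() for k in winners(keys, 0)}
    head_ok = {k for keys in by_head.values() for k in winners(keys, 1)}
    chosen = sorted(tail_ok & head_ok)

    if not chosen:
        return contigs
    merged: List[Contig] = []
    used: Set[int] = set()
    seen_seq: Set[str] = set()
    for i, j in chosen:
        pa, ra, rb, pb, rseq = splice[(i, j)]
        seq = contigs[i].seq[:pa] + rseq[ra:rb] + contigs[j].seq[pb:]
        if seq in seen_seq:
            continue
        seen_seq.add(seq)
        merged.append(Contig(
            id=contigs[i].id + "+",
            seq=seq,
            path=contigs[i].path + contigs[j].path,
            segment=contigs[i].segment))
        used.update((i, j))
    out = [c for n, c in enumerate(contigs) if n not in used]
    out.extend(merged)
    out.sort(key=lambda c: c.id)
    if used:
        out = close_gaps(out, long_reads, params, _round + 1)
    return out


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def effective_k(params: AssemblyParams, min_read_len: int) -> int:
    k = min(params.k, min_read_len - 10)
    if k % 2 == 0:
        k -= 1
    return max(k, 15)


def assemble_segment(reads: SegmentReadSet, params: AssemblyParams,
                     gfa_path: Optional[str] = None) -> List[Contig]:
    """build -> simplify -> extend -> (hybrid) close gaps, deterministically."""
    seqs = reads.short_read_sequences()
    if not seqs:
        log.info("segment %s: no reads, skipped", reads.segment)
        return []
    k = effective_k(params, min(len(s) for s in seqs))
    if k != params.k:
        params = params.scaled_to(k)
    graph = build_graph(seqs, k, params.solid_threshold)
    if not len(graph):
        log.info("segment %s: no solid k-mers, skipped", reads.segment)
        return []
    simplify(graph, params)
    if gfa_path is not None:
        write_gfa(graph, gfa_path)
    seg = reads.segment
    max_bp = 3 * len(seg) + 200_000
    paths = extend_paths(graph, params, max_bp=max_bp)
    contigs = []
    seen_seqs: Set[str] = set()
    for n, path in enumerate(paths):
        seq = graph.spell(path)
        if len(seq) < k or seq in seen_seqs:
            continue
        seen_seqs.add(seq)
        contigs.append(Contig(f"seg{seg.index:04d}_{seg.contig}_c{n:03d}",
                              seq, tuple(path), seg))
    if reads.long_reads:
        contigs = close_gaps(contigs, reads.long_reads, params)
    log.debug("segment %s: %d unitigs -> %d contigs", seg, len(graph), len(contigs))
    return contigs


def write_gfa(graph: AssemblyGraph, path: str) -> None:
    """Dump the simplified graph as GFA1 for forensics."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for uid in sorted(graph.units):
            u = graph.units[uid]
            fh.write(f"S\tu{uid}\t{u.seq}\tdp:f:{u.cov:.2f}\n")
        for uid in sorted(graph.outs):
            for t in graph.outs[uid]:
                fh.write(f"L\tu{uid}\t+\tu{t}\t+\t{graph.k - 1}M\n")
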