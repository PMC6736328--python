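"""Isoform reconstruction by iterative path extension.

Paths are grown through the simplified graph edge by edge.  At every step
the read-pair extender scores all candidate edges leaving the path's
terminal vertex and keeps *all* candidates whose score is close to the
maximum (within a factor C) and above an absolute floor Θ — unlike genome
assembly, several extensions can be simultaneously correct because of
alternative splicing, so the path forks and each fork is extended
independently.  When the pair extender fails on a two-way branch, a
coverage-ratio fallback (or its strand-specific variant on stranded
libraries) breaks the tie.  Seeding starts from the longest edge not yet in
any path and repeats until every edge is covered; exact duplicate paths and
contiguous subpaths are then removed, and each surviving path is emitted in
a deterministic orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .graph import CondensedGraph
from .mapping import PairedLinkIndex
from .params import AssemblyParams
from .sequence import revcomp

#: hard cap on simultaneously alive forks per seed; purely a guard against
#: pathological tangles, never reached on ordinary transcript graphs
_MAX_FORKS_PER_SEED = 64

_DEFAULT_INSERT_WINDOW = 1000.0


@dataclass
class Path:
    """Ordered, adjacency-consistent list of edge ids."""

    edges: List[int]
    graph: CondensedGraph
    seed: int

    def seq(self) -> str:
        k = self.graph.k
        parts = [self.graph.edges[self.edges[0]].seq]
        for eid in self.edges[1:]:
            parts.append(self.graph.edges[eid].seq[k - 1:])
        return "".join(parts)

    def terminal_vertex(self) -> int:
        return self.graph.edges[self.edges[-1]].end

    def cov(self) -> float:
        mass = sum(self.graph.edges[e].mass for e in self.edges)
        nk = sum(self.graph.edge_len_kmers(e) for e in self.edges)
        return mass / nk if nk else 0.0

    def cov_plus(self) -> float:
        vals = [self.graph.cov_plus(e) for e in self.edges]
        return sum(vals) / len(vals) if vals else 0.0

    def cov_minus(self) -> float:
        vals = [self.graph.cov_minus(e) for e in self.edges]
        return sum(vals) / len(vals) if vals else 0.0

    def strand_class(self) -> Optional[bool]:
        """True for a library-forward (sense) path, False for antisense,
        None when there is no strand annotation or no signal."""
        if all(self.graph.edges[e].pos_plus is None for e in self.edges):
            return None
        cp, cm = self.cov_plus(), self.cov_minus()
        if cp > cm:
            return True
        if cm > cp:
            return False
        return None

    def twin_edges(self) -> List[int]:
        return [self.graph.twin(e) for e in reversed(self.edges)]


@dataclass
class ExtensionScore:
    edge_id: int
    score: float


@dataclass
class Contig:
    """An output transcript: sequence with coverage and graph provenance."""

    seq: str
    cov: float
    edges: List[int] = field(default_factory=list)
    isolated: bool = False
    name: str = ""

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _insert_window(links: PairedLinkIndex) -> float:
    if links.insert_mean is None:
        return _DEFAULT_INSERT_WINDOW
    return links.insert_mean + 3.0 * (links.insert_sd or 0.0)


def _cone(graph: CondensedGraph, candidate: int, window: float) -> Dict[int, float]:
    """Edges reachable through ``candidate`` within ``window`` bp of the
    branch point, mapped to their minimal start distance beyond it."""
    k = graph.k
    cone: Dict[int, float] = {}
    stack: List[Tuple[int, float]] = [(candidate, 0.0)]
    while stack:
        eid, d = stack.pop()
        if d >= window:
            continue
        if eid in cone and cone[eid] <= d:
            continue
        cone[eid] = d
        e = graph.edges[eid]
        d2 = d + len(e.seq) - (k - 1)
        if d2 < window:
            for nxt in graph.out_edges(e.end):
                stack.append((nxt, d2))
    return cone


def score_extension(
    path: Path,
    candidate: int,
    links: PairedLinkIndex,
    sense: Optional[bool] = None,
) -> ExtensionScore:
    """Read-pair support for extending ``path`` with ``candidate``.

    The score is the number of mapped fragments whose upstream mate lies on
    the path within one insert-size window of the path's end and whose
    downstream mate lies on the candidate edge — or on any edge reachable
    through the candidate within the window, since condensed-graph edges are
    frequently shorter than the insert size and the downstream mate then
    overshoots the candidate itself.  Orientation consistency is guaranteed
    by the fragment-forward link convention.
    """
    if len(links) == 0:
        return ExtensionScore(candidate, 0.0)
    graph = path.graph
    window = _insert_window(links)
    cone = _cone(graph, candidate, window)
    n = _count_pairs_into(path, cone, links, window, sense)
    return ExtensionScore(candidate, n)


def _count_pairs_into(
    path: Path,
    allowed: Dict[int, float],
    links: PairedLinkIndex,
    window: float,
    sense: Optional[bool] = None,
) -> float:
    """Pairs whose upstream mate sits near the path end and whose
    downstream mate lands on an ``allowed`` edge (at its given distance
    beyond the path end).

    A downstream mate on an edge the path already contains is ignored:
    such a pair was consumed by the earlier traversal, and counting it
    again would make the extender orbit cycles (e.g. residual chimeric
    loops) indefinitely.

    ``sense`` restricts to one orientation class of the link index: on
    stranded libraries a sense path must only be supported by sense
    fragments (an antisense path by their mirrors), otherwise fragments
    of an opposite-strand transcript sharing a reverse-complement region
    would vouch for chimeric extensions.
    """
    graph = path.graph
    k = graph.k
    on_path = set(path.edges)
    frags: Set[int] = set()
    tail = 0.0
    for eid in reversed(path.edges):
        elen = len(graph.edges[eid].seq)
        for _, off1, _, e2, off2, _, fid, s in links.links_from(eid):
            if sense is not None and s != sense:
                continue
            d_beyond = allowed.get(e2)
            if d_beyond is None or e2 in on_path:
                continue
            if (elen - off1) + tail <= window and d_beyond + off2 <= window:
                frags.add(fid)
        tail += elen - (k - 1)
        if tail > window:
            break
    return float(len(frags))


def apply_extension_rule(
    scores: Dict[int, float], params: AssemblyParams
) -> Set[int]:
    """The multi-extension selection rule on precomputed scores: keep every
    candidate scoring above ``max_score / C`` and above Θ."""
    if not scores:
        return set()
    best = max(scores.values())
    if best <= params.theta:
        return set()
    cutoff = best / params.extension_c
    return {c for c, s in scores.items() if s > cutoff and s > params.theta}


def select_extensions(
    path: Path,
    candidates: Sequence[int],
    links: PairedLinkIndex,
    params: AssemblyParams,
    sense: Optional[bool] = None,
) -> Set[int]:
    """Multi-extension rule: keep every candidate scoring within a factor
    C of the best and above Θ; the path forks into one copy per survivor.

    With several candidates, each is scored on its *exclusive* evidence —
    pairs landing on edges reachable only through that candidate.  Shared
    downstream evidence cannot distinguish the branches (they reconverge
    within an insert), so counting it for every sibling would fork the path
    on every spurious bubble.  When no candidate has exclusive support the
    pair extender reports failure (empty set) and the coverage-based
    fallback takes over.
    """
    if not candidates:
        return set()
    if len(candidates) == 1:
        c = candidates[0]
        return apply_extension_rule(
            {c: score_extension(path, c, links, sense).score}, params
        )
    if len(links) == 0:
        return set()
    graph = path.graph
    window = _insert_window(links)
    cones = {c: _cone(graph, c, window) for c in candidates}
    raw: Dict[int, float] = {}
    for c in candidates:
        shared = set()
        for o in candidates:
            if o != c:
                shared.update(cones[o])
        exclusive = {e: d for e, d in cones[c].items() if e not in shared}
        raw[c] = _count_pairs_into(path, exclusive, links, window, sense)
    return apply_extension_rule(raw, params)


# ---------------------------------------------------------------------------
# Coverage-based fallbacks
# ---------------------------------------------------------------------------

def _last_alternative_vertex(path: Path) -> Optional[Tuple[int, int]]:
    """(on-path in-edge, off-path in-edge) at the vertex closest to the
    path end that has exactly two incoming edges, one of them on the path."""
    graph = path.graph
    for i in range(len(path.edges) - 1, 0, -1):
        v = graph.edges[path.edges[i]].start
        incoming = graph.in_edges(v)
        if len(incoming) == 2 and path.edges[i - 1] in incoming:
            on = path.edges[i - 1]
            off = incoming[0] if incoming[1] == on else incoming[1]
            if off != on:
                return on, off
    return None


def _ratio_extend(path: Path, params: AssemblyParams, covf) -> Optional[int]:
    graph = path.graph
    cands = graph.out_edges(path.terminal_vertex())
    if len(cands) != 2:
        return None
    a, b = cands
    e, e_alt = (a, b) if covf(a) >= covf(b) else (b, a)
    back = _last_alternative_vertex(path)
    if back is None:
        return None
    e2, e2_alt = back
    if not covf(e) > params.delta * covf(e_alt):
        return None
    if not covf(e2) > params.delta * covf(e2_alt):
        return None
    if covf(e) <= 0:
        return None
    ratio = covf(e2) / covf(e)
    if not (params.omega > ratio > 1.0 / params.omega):
        return None
    if not covf(e) > params.c_min:
        return None
    return e


def coverage_extend(path: Path, params: AssemblyParams) -> Optional[int]:
    """Resolve a two-way branch by conventional coverage depth.

    Requires a significant (> Δ-fold) coverage difference both at the
    branch ahead and at the last alternative junction behind, coverage
    persistence along the path (within a factor Ω) and an absolute floor
    C_min on the chosen extension; otherwise declines.
    """
    return _ratio_extend(path, params, path.graph.cov)


def strand_extend(path: Path, params: AssemblyParams) -> Optional[int]:
    """Coverage fallback using library-forward strand coverage instead.

    Resolves reverse-complement repeats between opposite-strand transcripts
    that conventional coverage cannot (requires strand annotation; returns
    None when the graph carries none)."""
    graph = path.graph
    if all(graph.edges[e].pos_plus is None for e in path.edges):
        return None
    return _ratio_extend(path, params, graph.cov_plus)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _grow_forward(
    path: Path,
    links: PairedLinkIndex,
    params: AssemblyParams,
    stranded: bool,
) -> List[Path]:
    """Extend a path forward, forking on multi-extensions; returns all
    completed forks."""
    graph = path.graph
    k = graph.k
    window = _insert_window(links)
    work = [path]
    done: List[Path] = []
    while work:
        p = work.pop()
        cands = [
            c for c in graph.out_edges(p.terminal_vertex())
            if p.edges.count(c) < params.max_edge_multiplicity
        ]
        if not cands:
            done.append(p)
            continue
        sense = p.strand_class() if stranded else None
        chosen = select_extensions(p, cands, links, params, sense)
        if (
            not chosen
            and len(cands) == 1
            and cands[0] not in p.edges
            and p.cov() > params.c_min
        ):
            # a path shorter than one insert cannot anchor enough upstream
            # mates to be judged by pairs; a single fresh outgoing edge is
            # topologically forced, so take it — but only for credibly
            # covered paths (chimeric junk edges must not bootstrap)
            plen = sum(len(graph.edges[e].seq) for e in p.edges) - (
                (len(p.edges) - 1) * (k - 1)
            )
            if plen < window:
                chosen = set(cands)
        if not chosen and len(cands) == 2:
            fb = (
                strand_extend(p, params) if stranded
                else coverage_extend(p, params)
            )
            if fb is not None:
                chosen = {fb}
        if not chosen:
            done.append(p)
            continue
        room = _MAX_FORKS_PER_SEED - len(work) - len(done)
        for c in sorted(chosen)[:max(1, room)]:
            work.append(Path(p.edges + [c], graph, p.seed))
    return done


def extend_all(
    graph: CondensedGraph,
    links: PairedLinkIndex,
    params: Optional[AssemblyParams] = None,
    stranded: bool = False,
) -> List[Path]:
    """Reconstruct isoform paths covering every edge of the graph.

    Seeds are taken longest-first among edges not yet covered by any path
    (an edge and its twin count as covered together).  Each seed grows
    forward, then each fork grows backward by extending its twin path and
    splicing, so genes are recovered regardless of where the seed sits.
    """
    if params is None:
        params = AssemblyParams()
    covered: Set[int] = set()
    paths: List[Path] = []
    order = sorted(
        graph.edges, key=lambda e: (-len(graph.edges[e].seq), e)
    )
    for seed in order:
        if seed in covered:
            continue
        # alternate forward and backward (twin) growth to a fixed point:
        # a short path may be unjudgeable by pairs in one direction until
        # the opposite direction has given it anchorage
        frontier = [Path([seed], graph, seed)]
        for _ in range(8):
            grown: List[Path] = []
            changed = False
            for p in frontier:
                for q in _grow_forward(p, links, params, stranded):
                    tq = Path(q.twin_edges(), graph, seed)
                    for b in _grow_forward(tq, links, params, stranded):
                        final = Path(b.twin_edges(), graph, seed)
                        if len(final.edges) != len(p.edges):
                            changed = True
                        grown.append(final)
            # drop duplicate forks early
            seen = set()
            frontier = []
            for p in grown:
                key = tuple(p.edges)
                if key not in seen:
                    seen.add(key)
                    frontier.append(p)
            frontier = frontier[:_MAX_FORKS_PER_SEED]
            if not changed:
                break
        for p in frontier:
            paths.append(p)
            for e in p.edges:
                covered.add(e)
                covered.add(graph.twin(e))
    return paths


# ---------------------------------------------------------------------------
# Deduplication and orientation
# ---------------------------------------------------------------------------

def _is_sublist(small: Sequence[int], big: Sequence[int]) -> bool:
    n, m = len(small), len(big)
    if n > m:
        return False
    small = list(small)
    return any(list(big[i : i + n]) == small for i in range(m - n + 1))


def remove_duplicate_paths(paths: List[Path], stranded: bool) -> List[Path]:
    """Drop exact duplicate paths and contiguous subpaths, nothing else.

    When the library is unstranded a path and its twin describe the same
    molecule, so the twin-reversed edge list is also checked.
    """
    ordered = sorted(paths, key=lambda p: (-len(p.edges), p.edges))
    kept: List[Path] = []
    for p in ordered:
        dup = False
        for r in kept:
            if _is_sublist(p.edges, r.edges):
                dup = True
                break
            if not stranded and _is_sublist(p.twin_edges(), r.edges):
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept


def orient_paths(
    paths: List[Path], graph: CondensedGraph, stranded: bool
) -> List[Contig]:
    """Emit one contig per path in a deterministic orientation.

    Stranded libraries: the orientation with the higher library-forward
    strand coverage wins (the original transcript's strand); ties and
    unstranded libraries fall back to the lexicographically smaller
    sequence.
    """
    contigs: List[Contig] = []
    for p in paths:
        fwd_seq = p.seq()
        twin = Path(p.twin_edges(), graph, p.seed)
        rev_seq = twin.seq()
        use_fwd = fwd_seq <= rev_seq
        if stranded:
            cp, cm = p.cov_plus(), twin.cov_plus()
            if cp > cm:
                use_fwd = True
            elif cm > cp:
                use_fwd = False
        chosen = p if use_fwd else twin
        isolated = len(chosen.edges) == 1 and _edge_is_isolated(
            graph, chosen.edges[0]
        )
        contigs.append(
            Contig(
                seq=chosen.seq(),
                cov=chosen.cov(),
                edges=list(chosen.edges),
                isolated=isolated,
            )
        )
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    for i, c in enumerate(contigs, start=1):
        c.name = f"NODE_{i}_length_{len(c.seq)}_cov_{c.cov:.6f}"
    return contigs


def _edge_is_isolated(graph: CondensedGraph, eid: int) -> bool:
    e = graph.edges[eid]
    return (
        graph.in_degree(e.start) == 0
        and graph.out_degree(e.start) == 1
        and graph.out_degree(e.end) == 0
        and graph.in_degree(e.end) == 1
    )
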