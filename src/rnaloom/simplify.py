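"""RNA-specific cleaning of the condensed de Bruijn graph.

A graph built from RNA-seq reads mixes genuine transcript structure
(terminal exons appear as tips, exon skipping as bulges) with artefacts
(error tips, error bulges, chimeric loops and hairpins, isolated junk
edges).  Genome-style aggressive cleaning would destroy isoforms, so every
rule here is deliberately conservative: tips are clipped only when short and
weak, highly similar to an alternative, or poly-A/T; bulges are collapsed on
length similarity alone (never on coverage); chimeric connections are
recognised purely from topology.

All procedures preserve twin symmetry and re-condense the graph, and
:func:`simplify` iterates them to a fixed point.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .graph import CondensedGraph
from .params import AssemblyParams
from .sequence import at_fraction, hamming


def _protected(graph: CondensedGraph, eid: int) -> bool:
    """Edges mostly made of carried-over connectivity k-mers are shielded
    from coverage-based removal (two-iteration assembly support)."""
    e = graph.edges[eid]
    return e.prot > 0.5 * graph.edge_len_kmers(eid)


# ---------------------------------------------------------------------------
# Tips
# ---------------------------------------------------------------------------

def _tip_candidates(graph: CondensedGraph) -> List[Tuple[int, bool]]:
    """(edge id, is_dead_end) for every tip edge that has an anchored side.

    Isolated edges (dead at both sides) are not tips; they are handled by
    :func:`remove_isolated_edges`.
    """
    out = []
    for e in graph.edges.values():
        dead_end = graph.out_degree(e.end) == 0
        dead_start = graph.in_degree(e.start) == 0
        if dead_end and dead_start:
            continue
        if dead_end:
            out.append((e.id, True))
        elif dead_start:
            out.append((e.id, False))
    return out


def _best_alternative(
    graph: CondensedGraph, eid: int, dead_end: bool
) -> Optional[int]:
    """Highest-coverage sibling edge sharing the tip's anchored vertex."""
    e = graph.edges[eid]
    sibs = (
        [x for x in graph.out_edges(e.start) if x != eid]
        if dead_end
        else [x for x in graph.in_edges(e.end) if x != eid]
    )
    if not sibs:
        return None
    return max(sibs, key=lambda x: (graph.cov(x), -x))


def clip_tips(
    graph: CondensedGraph, read_length: int, params: AssemblyParams
) -> CondensedGraph:
    """Remove erroneous tips; keep tips that look like transcript termini.

    A tip of graph length ``l`` (k-mers) and coverage ``c_T`` is removed if:

    1. ``l < 2k`` and ``c_T <= 1`` (short, barely covered);
    2. ``l < 4k``, ``c_T < c_A / 2`` and Hamming distance to the best
       alternative edge ``<= 3`` (sequencing-error copy of a real edge);
    3. the tip is more than 80% A/T (poly-A artefact).

    Tips from alternative first/last exons fail all three tests (long
    enough, dissimilar, mixed composition) and survive.
    """
    k = graph.k
    doomed = set()
    for eid, dead_end in _tip_candidates(graph):
        if eid in doomed or graph.edges[eid].twin_id in doomed:
            continue
        e = graph.edges[eid]
        l = graph.edge_len_kmers(eid)
        c_t = graph.cov(eid)
        # condition 3: low-complexity tail
        if at_fraction(e.seq) > params.tip_at_frac:
            doomed.add(eid)
            continue
        # condition 1: short and weak (skipped for protected edges)
        if (
            l < params.tip_short_len_factor * k
            and c_t <= params.tip_short_cov_max
            and not _protected(graph, eid)
        ):
            doomed.add(eid)
            continue
        # condition 2: error copy of an alternative edge
        if l < params.tip_err_len_factor * k:
            alt = _best_alternative(graph, eid, dead_end)
            if alt is not None:
                c_a = graph.cov(alt)
                alt_seq = graph.edges[alt].seq
                if dead_end:
                    dist = hamming(e.seq, alt_seq)
                else:
                    dist = hamming(e.seq[::-1], alt_seq[::-1])
                if c_t < params.tip_err_cov_ratio * c_a and (
                    dist <= params.tip_err_hamming_max
                ):
                    doomed.add(eid)
    for eid in doomed:
        graph.remove_edge_pair(eid)
    if doomed:
        graph.recondense()
    return graph


# ---------------------------------------------------------------------------
# Bulges
# ---------------------------------------------------------------------------

def collapse_bulges(graph: CondensedGraph, params: AssemblyParams) -> CondensedGraph:
    """Collapse simple error bulges; keep exon-skipping bulges.

    Only bulges of exactly two parallel edges whose lengths differ by less
    than 10% are merged (no coverage threshold — isoform expression levels
    legitimately differ).  The kept edge absorbs the removed edge's k-mer
    mass; higher coverage wins, exact ties go to the lexicographically
    smaller sequence.
    """
    groups = {}
    for e in graph.edges.values():
        if e.start == e.end:
            continue  # self-loop, not a bulge
        groups.setdefault((e.start, e.end), []).append(e.id)
    changed = False
    removed = set()
    for (_, _), eids in groups.items():
        if len(eids) != 2:
            continue  # only simple bulges
        a, b = eids
        if a in removed or b in removed:
            continue
        ea, eb = graph.edges[a], graph.edges[b]
        if ea.twin_id == b:
            continue  # parallel twin pair (palindromic structure), keep
        la, lb = len(ea.seq), len(eb.seq)
        if abs(la - lb) / max(la, lb) >= params.bulge_len_diff_max:
            continue
        ca, cb = graph.cov(a), graph.cov(b)
        if ca > cb or (ca == cb and ea.seq <= eb.seq):
            keep, drop = a, b
        else:
            keep, drop = b, a
        kept = graph.edges[keep]
        dropped = graph.edges[drop]
        kept.mass += dropped.mass
        if kept.twin_id != keep:
            graph.edges[kept.twin_id].mass += dropped.mass
        removed.add(drop)
        removed.add(dropped.twin_id)
        graph.remove_edge_pair(drop)
        changed = True
    if changed:
        graph.recondense()
    return graph


# ---------------------------------------------------------------------------
# Chimeric connections
# ---------------------------------------------------------------------------

def remove_chimeric_loops(graph: CondensedGraph) -> CondensedGraph:
    """Remove short chimeric self-loops hanging off the end of a long edge.

    The predicate is purely topological: a self-loop at a vertex whose only
    other adjacency is a single long edge (> 2k in k-mers).  Loops at
    internal, well-connected vertices (genuine tandem repeats) are kept.
    The loop itself must be short (< 2k): a chimeric jump lands close to
    the break point, so the loop holds little more than the junction — an
    unbounded predicate would amputate long stretches of genuine transcript
    3' end that condense into the loop together with the junction.
    """
    k = graph.k
    doomed = []
    for e in graph.edges.values():
        if e.start != e.end:
            continue
        v = e.start
        others = [
            x for x in graph.in_edges(v) + graph.out_edges(v)
            if x != e.id and x != e.twin_id
        ]
        if len(others) != 1:
            continue
        if graph.edge_len_kmers(e.id) >= 2 * k:
            continue
        if graph.edge_len_kmers(others[0]) > 2 * k:
            doomed.append(e.id)
    changed = False
    for eid in doomed:
        if eid in graph.edges:
            graph.remove_edge_pair(eid)
            changed = True
    if changed:
        graph.recondense()
    return graph


def remove_hairpins(graph: CondensedGraph) -> CondensedGraph:
    """Remove chimeric edges joining a vertex to its own twin.

    Such an edge glues a sequence onto its reverse complement (its twin
    connects the same two vertices), producing palindromic chimeras.  An
    incident anchor edge is required, so a bare inverted repeat whose
    endpoints are not twins is untouched.
    """
    doomed = []
    for e in graph.edges.values():
        if e.start == e.end:
            continue  # self-loop: the loop remover's business
        v = graph.vertices[e.start]
        if v.twin_id != e.end:
            continue
        anchors = [
            x for x in graph.in_edges(e.start) + graph.out_edges(e.start)
            if x != e.id and x != e.twin_id
        ]
        if anchors:
            doomed.append(e.id)
    changed = False
    for eid in doomed:
        if eid in graph.edges:
            graph.remove_edge_pair(eid)
            changed = True
    if changed:
        graph.recondense()
    return graph


# ---------------------------------------------------------------------------
# Isolated edges
# ---------------------------------------------------------------------------

def remove_isolated_edges(
    graph: CondensedGraph, read_length: int, params: AssemblyParams
) -> CondensedGraph:
    """Drop isolated edges that are both weak (cov < 2) and short (<= read length)."""
    doomed = []
    for e in graph.edges.values():
        if e.start == e.end:
            continue
        if graph.in_degree(e.start) > 0 or graph.out_degree(e.start) > 1:
            continue
        if graph.out_degree(e.end) > 0 or graph.in_degree(e.end) > 1:
            continue
        if _protected(graph, e.id):
            continue
        if graph.cov(e.id) < params.iso_edge_cov_max and len(e.seq) <= read_length:
            doomed.append(e.id)
    for eid in doomed:
        if eid in graph.edges:
            graph.remove_edge_pair(eid)
    return graph


# ---------------------------------------------------------------------------
# Strand-based edge splitting
# ---------------------------------------------------------------------------

def _find_strand_split(
    plus: np.ndarray, minus: np.ndarray, k: int, params: AssemblyParams
) -> Optional[int]:
    """Best nucleotide split position, or None.

    Position ``sp`` splits the edge into seq[:sp] / seq[sp:]; the prefix
    must be dominated by one strand and the suffix by the other, each with
    ratio >= ``strand_split_ratio`` and dominant coverage >=
    ``strand_split_min_cov``.
    """
    n = len(plus)
    if n < k + 1:
        return None
    cp = np.concatenate([[0.0], np.cumsum(plus)])
    cm = np.concatenate([[0.0], np.cumsum(minus)])
    best: Tuple[float, int] | None = None
    for sp in range(k, n):  # suffix k-mers [sp, n); prefix k-mers [0, sp-k+1)
        np_pre = sp - k + 1
        p_pre = cp[np_pre] / np_pre
        m_pre = cm[np_pre] / np_pre
        p_suf = (cp[n] - cp[sp]) / (n - sp)
        m_suf = (cm[n] - cm[sp]) / (n - sp)
        for dom_pre, oth_pre, dom_suf, oth_suf in (
            (p_pre, m_pre, m_suf, p_suf),
            (m_pre, p_pre, p_suf, m_suf),
        ):
            if dom_pre < params.strand_split_min_cov:
                continue
            if dom_suf < params.strand_split_min_cov:
                continue
            if dom_pre < params.strand_split_ratio * max(oth_pre, 1e-12):
                continue
            if dom_suf < params.strand_split_ratio * max(oth_suf, 1e-12):
                continue
            score = min(
                dom_pre / max(oth_pre, 1e-12), dom_suf / max(oth_suf, 1e-12)
            )
            if best is None or score > best[0]:
                best = (score, sp)
    return None if best is None else best[1]


def split_edges_by_strand(
    graph: CondensedGraph, params: AssemblyParams
) -> CondensedGraph:
    """Split edges whose two ends are dominated by opposite strands.

    Such edges arise when transcripts from opposite strands share sequence
    at their 3' ends and would otherwise be collapsed into one contig.  The
    two pieces share no vertex (the junction k-mers are discarded); the twin
    graph is updated symmetrically.  No-op on unstranded data (no
    strand-coverage annotation present).
    """
    k = graph.k
    todo = []
    for e in graph.edge_pairs():
        if e.pos_plus is None:
            continue
        sp = _find_strand_split(e.pos_plus, e.pos_minus, k, params)
        if sp is not None:
            todo.append((e.id, sp))
    for eid, sp in todo:
        e = graph.edges[eid]
        n = len(e.seq) - k + 1
        cov = graph.cov(eid)
        seq_a, seq_b = e.seq[:sp], e.seq[sp:]
        arr_pa = e.pos_plus[: sp - k + 1].copy()
        arr_ma = e.pos_minus[: sp - k + 1].copy()
        arr_pb = e.pos_plus[sp:].copy()
        arr_mb = e.pos_minus[sp:].copy()
        graph.remove_edge_pair(eid)
        for seq, ap, am in ((seq_a, arr_pa, arr_ma), (seq_b, arr_pb, arr_mb)):
            new = graph.add_edge_pair(seq, cov * (len(seq) - k + 1))
            new.pos_plus = ap
            new.pos_minus = am
            if not new.self_rc:
                tw = graph.edges[new.twin_id]
                tw.pos_plus = am[::-1].copy()
                tw.pos_minus = ap[::-1].copy()
    return graph


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def simplify(
    graph: CondensedGraph, read_length: int, params: Optional[AssemblyParams] = None
) -> CondensedGraph:
    """Iterate all cleaning procedures to a fixed point.

    Order per round: tips, bulges, chimeric loops, hairpins, isolated
    edges; the graph is re-condensed inside each step.  Rounds repeat while
    anything changes; termination is guaranteed because a productive round
    strictly shrinks the graph's k-mer content.
    """
    if params is None:
        params = AssemblyParams()

    def signature() -> tuple:
        return (
            graph.n_edges(),
            sum(len(e.seq) for e in graph.edges.values()),
            round(graph.total_mass(), 6),
        )

    prev = None
    cur = signature()
    while cur != prev:
        prev = cur
        clip_tips(graph, read_length, params)
        collapse_bulges(graph, params)
        remove_chimeric_loops(graph)
        remove_hairpins(graph)
        remove_isolated_edges(graph, read_length, params)
        cur = signature()
    return graph
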