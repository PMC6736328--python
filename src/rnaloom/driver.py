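"""Assembly orchestration: k-mer size selection, two-iteration graph
construction, paired-read gap closing and the end-to-end pipeline.

Two k-mer sizes are used: a small one (``~read_length/3``, floored at 29)
restores low-covered regions where read overlaps are short, and a large one
(``largest odd <= read_length/2 - 1``) untangles the graph.  Edges of the
small-k graph enter the large-k iteration as protected connectivity
sequences — their k-mers cannot be deleted by coverage-based cleaning, but
coverage is still measured from the reads alone.  Remaining coverage gaps
between tips are closed with exact overlaps backed by read pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import CondensedGraph, KmerTable, build_condensed_graph, count_kmers
from .mapping import PairedLinkIndex, annotate_strand_coverage, map_read_pairs
from .params import AssemblyParams
from .paths import (
    Contig,
    extend_all,
    orient_paths,
    remove_duplicate_paths,
)
from .sequence import canonical, kmers_of
from .simplify import simplify, split_edges_by_strand


@dataclass
class KPlan:
    """The two k-mer sizes of an assembly run."""

    k_low: int
    k_high: int
    single_k: bool = False

    def __post_init__(self) -> None:
        if self.k_low % 2 == 0 or self.k_high % 2 == 0:
            raise ValueError("k values must be odd")
        if not self.single_k and self.k_low > self.k_high:
            raise ValueError("k_low must not exceed k_high")


def _largest_odd_leq(x: float) -> int:
    m = int(np.floor(x))
    return m if m % 2 == 1 else m - 1


def select_kmer_sizes(read_length: int, k_low_min: int = 29) -> KPlan:
    """Derive the k plan from the read length.

    ``k_high`` is the largest odd number not exceeding ``read_length/2 - 1``;
    ``k_low`` the largest odd number not exceeding ``read_length/3``, floored
    at 29 (smaller values sharply raise the chance of two transcripts
    sharing a k-mer and thus of chimeric contigs).  When the floor pushes
    ``k_low`` to or past ``k_high``, a single iteration at ``k_high`` is run.
    """
    if read_length < 35:
        raise ValueError(f"read length {read_length} too short (< 35)")
    k_high = _largest_odd_leq(read_length / 2 - 1)
    k_low = max(k_low_min, _largest_odd_leq(read_length / 3))
    if k_low >= k_high:
        return KPlan(k_low=k_high, k_high=k_high, single_k=True)
    return KPlan(k_low=k_low, k_high=k_high)


# ---------------------------------------------------------------------------
# Gap closing
# ---------------------------------------------------------------------------

def _exact_overlap(a: str, b: str, min_len: int, max_len: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap in [min_len, max_len], or 0."""
    top = min(len(a), len(b), max_len)
    for ov in range(top, min_len - 1, -1):
        if a[-ov:] == b[:ov]:
            return ov
    return 0


def _gluepoint(graph: CondensedGraph, eid: int, side: str) -> Tuple[int, str]:
    """Canonical identifier of a tip's free end (same point on both strands)."""
    t = graph.twin(eid)
    if eid <= t:
        return (eid, side)
    return (t, "start" if side == "end" else "end")


def close_gaps(
    graph: CondensedGraph,
    links: PairedLinkIndex,
    params: Optional[AssemblyParams] = None,
) -> CondensedGraph:
    """Glue dead-end tips to dead-start tips across coverage gaps.

    Two tips are glued when (a) they share an exact suffix-prefix overlap of
    at least ``l_ov`` bp and at least ``n_ov`` read pairs connect them, or
    (b) at least ``n_min`` read pairs connect them.  Under (a) the overlap
    is merged once; under (b) the pair-implied gap decides: a negative gap
    retries the overlap search with a relaxed floor, a non-negative gap
    concatenates the tips directly.  A tip with several eligible partners is
    left alone (ambiguity), and a tip is never glued to its own twin.
    """
    if params is None:
        params = AssemblyParams()
    k = graph.k
    window = int(
        (links.insert_mean or 1000.0) + 3.0 * (links.insert_sd or 0.0)
    )

    dead_ends = graph.dead_end_tips()
    dead_starts = set(graph.dead_start_tips())
    junctions: Dict[Tuple, Tuple[int, int, int, int]] = {}
    for d in dead_ends:
        dseq = graph.edges[d].seq
        for s in dead_starts:
            if s == d or s == graph.twin(d):
                continue
            npairs = links.count_connecting(
                d, s,
                a_tail=(max(0, len(dseq) - window), len(dseq)),
                b_head=(0, window),
            )
            ov = _exact_overlap(dseq, graph.edges[s].seq, params.l_ov, k - 1)
            cond_a = ov >= params.l_ov and npairs >= params.n_ov
            cond_b = npairs >= params.n_min
            if not (cond_a or cond_b):
                continue
            key = min((d, s), (graph.twin(s), graph.twin(d)))
            junctions.setdefault(key, (d, s, ov, npairs))

    # ambiguity: each free tip end may take part in at most one junction
    usage: Dict[Tuple[int, str], int] = {}
    for d, s, _, _ in junctions.values():
        for gp in (_gluepoint(graph, d, "end"), _gluepoint(graph, s, "start")):
            usage[gp] = usage.get(gp, 0) + 1

    remap: Dict[int, int] = {}

    def resolve(eid: int) -> int:
        while eid in remap:
            eid = remap[eid]
        return eid

    for d, s, ov, npairs in junctions.values():
        if usage[_gluepoint(graph, d, "end")] > 1:
            continue
        if usage[_gluepoint(graph, s, "start")] > 1:
            continue
        d2, s2 = resolve(d), resolve(s)
        if d2 not in graph.edges or s2 not in graph.edges:
            continue
        dseq = graph.edges[d2].seq
        sseq = graph.edges[s2].seq
        if ov >= params.l_ov and npairs >= params.n_ov:
            joined = dseq + sseq[ov:]
        else:
            by_frag: Dict[int, float] = {}
            for e1, off1, _, e2, off2, len2, fid, _sense in links.links_from(d):
                if e2 == s and fid not in by_frag:
                    by_frag[fid] = (
                        (links.insert_mean or 0.0)
                        - (len(dseq) - off1)
                        - (off2 + len2)
                    )
            gap = float(np.median(list(by_frag.values()))) if by_frag else 0.0
            if gap < 0:
                ov2 = _exact_overlap(dseq, sseq, params.l_ov_relaxed, k - 1)
                if ov2 == 0:
                    continue
                joined = dseq + sseq[ov2:]
            else:
                joined = dseq + sseq
        mass = graph.edges[d2].mass + graph.edges[s2].mass
        prot = graph.edges[d2].prot + graph.edges[s2].prot
        td, ts = graph.twin(d2), graph.twin(s2)
        graph.remove_edge_pair(d2)
        graph.remove_edge_pair(s2)
        new = graph.add_edge_pair(joined, mass, prot=prot)
        for old in (d2, s2):
            remap[old] = new.id
        for old in (td, ts):
            remap[old] = new.twin_id
    graph.recondense()
    return graph


# ---------------------------------------------------------------------------
# Two-iteration construction
# ---------------------------------------------------------------------------

def two_stage_assemble(
    read_pairs: Sequence[Tuple[str, str]],
    plan: KPlan,
    params: Optional[AssemblyParams] = None,
    read_length: Optional[int] = None,
    stage_sink: Optional[Dict[str, CondensedGraph]] = None,
) -> CondensedGraph:
    """Build and clean the assembly graph with the two-k strategy.

    Iteration 1 assembles at ``k_low`` and simplifies; iteration 2 rebuilds
    at ``k_high`` from the reads plus the iteration-1 edge sequences, whose
    k-mers are protected from coverage-based removal (coverage itself comes
    from the reads only).  Read pairs are then mapped and gaps between tips
    closed, followed by a final cleaning pass.
    """
    if params is None:
        params = AssemblyParams()
    reads = [r for pair in read_pairs for r in pair]
    if not reads:
        return CondensedGraph(plan.k_high)
    if read_length is None:
        read_length = max(len(r) for r in reads)

    protected: set = set()
    if not plan.single_k:
        t1 = count_kmers(reads, plan.k_low)
        if t1.counts:
            g1 = build_condensed_graph(t1)
            simplify(g1, read_length, params)
            for e in g1.edge_pairs():
                for km in kmers_of(e.seq, plan.k_high):
                    protected.add(canonical(km))

    t2 = count_kmers(reads, plan.k_high)
    for km in protected:
        if km not in t2.counts:
            t2.counts[km] = 1  # connectivity pseudo-count
    if not t2.counts:
        return CondensedGraph(plan.k_high)
    g2 = build_condensed_graph(t2, protected=protected or None)
    if stage_sink is not None:
        stage_sink["raw"] = g2.copy()
    simplify(g2, read_length, params)
    if stage_sink is not None:
        stage_sink["simplified"] = g2.copy()
    links = map_read_pairs(g2, read_pairs)
    close_gaps(g2, links, params)
    simplify(g2, read_length, params)
    return g2


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    contigs: List[Contig]
    graph: CondensedGraph
    plan: KPlan
    links: PairedLinkIndex
    params: AssemblyParams
    log: List[str] = field(default_factory=list)
    #: populated when the pipeline is asked to keep debug stage graphs
    stage_graphs: Dict[str, CondensedGraph] = field(default_factory=dict)


def assemble(
    read_pairs: Sequence[Tuple[str, str]],
    strandedness: Optional[str] = None,
    plan: Optional[KPlan] = None,
    params: Optional[AssemblyParams] = None,
    save_stages: bool = False,
) -> AssemblyResult:
    """Run the full pipeline: graph, simplification, gap closing, path
    extension, orientation — returning unfiltered contigs.

    ``strandedness`` is None (unstranded), "rf" or "fr".  With
    ``save_stages`` the raw and freshly simplified large-k graphs are kept
    on the result for debugging dumps.
    """
    if params is None:
        params = AssemblyParams()
    reads = [r for pair in read_pairs for r in pair]
    log: List[str] = []
    if not reads:
        g = CondensedGraph(plan.k_high if plan else 29)
        return AssemblyResult([], g, plan or KPlan(29, 29, True), PairedLinkIndex(), params, log)
    read_length = max(len(r) for r in reads)
    if plan is None:
        plan = select_kmer_sizes(read_length, params.k_low_min)
    log.append(f"k plan: low={plan.k_low} high={plan.k_high} single={plan.single_k}")

    stages: Optional[Dict[str, CondensedGraph]] = {} if save_stages else None
    graph = two_stage_assemble(read_pairs, plan, params, read_length, stages)
    log.append(f"graph after construction+cleaning: {graph.n_edges()} edges")

    stranded = strandedness is not None
    if stranded:
        annotate_strand_coverage(graph, read_pairs, strandedness)
        split_edges_by_strand(graph, params)
        graph.recondense()
        annotate_strand_coverage(graph, read_pairs, strandedness)
        log.append(f"after strand splitting: {graph.n_edges()} edges")

    links = map_read_pairs(graph, read_pairs, strandedness)
    log.append(
        f"mapped fragments: {links.n_fragments}, insert "
        f"{links.insert_mean if links.insert_mean is None else round(links.insert_mean, 1)}"
        f" +/- {links.insert_sd if links.insert_sd is None else round(links.insert_sd, 1)}"
    )
    paths = extend_all(graph, links, params, stranded=stranded)
    paths = remove_duplicate_paths(paths, stranded)
    contigs = orient_paths(paths, graph, stranded)
    log.append(f"paths: {len(paths)}; contigs: {len(contigs)}")
    return AssemblyResult(contigs, graph, plan, links, params, log,
                          stage_graphs=stages or {})
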