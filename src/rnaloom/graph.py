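"""Condensed bidirected de Bruijn graph.

The graph stores both strands explicitly: every edge has a reverse-complement
*twin* (an edge may be its own twin when its sequence is a perfect
reverse-complement palindrome, flagged ``self_rc``), and every structural
operation keeps the twin relation intact.  Vertices are (k-1)-mers, edges are
maximal non-branching nucleotide sequences annotated with k-mer coverage.

k must be odd: this forbids reverse-complement-palindromic k-mers, so a
k-mer and its reverse complement are always distinct and each one belongs to
exactly one edge orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .sequence import canonical, clean_fragments, kmers_of, revcomp


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

@dataclass
class KmerTable:
    """Canonical k-mer counts.

    Keys are canonical k-mers (lexicographic minimum of the k-mer and its
    reverse complement); values are strictly positive occurrence counts.
    """

    k: int
    counts: Dict[str, int] = field(default_factory=dict)

    def total_mass(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Count canonical k-mers over a read collection.

    Reads are split at ambiguous (non-ACGT) bases and each fragment of
    length >= k is counted separately.

    Parameters
    ----------
    reads : iterable of str
        Nucleotide sequences; lower case and IUPAC ambiguity codes accepted.
    k : int
        Odd k-mer size >= 3.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    counts: Dict[str, int] = {}
    for read in reads:
        for frag in clean_fragments(read):
            if len(frag) < k:
                continue
            for km in kmers_of(frag, k):
                key = canonical(km)
                counts[key] = counts.get(key, 0) + 1
    return KmerTable(k=k, counts=counts)


# ---------------------------------------------------------------------------
# Graph primitives
# ---------------------------------------------------------------------------

class Vertex:
    __slots__ = ("id", "kmer", "twin_id")

    def __init__(self, vid: int, kmer: str, twin_id: int):
        self.id = vid
        self.kmer = kmer
        self.twin_id = twin_id

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Vertex({self.id}, {self.kmer})"


class Edge:
    """A maximal non-branching sequence with coverage annotation.

    ``mass`` is the summed count of the edge's constituent k-mers, so the
    mean k-mer coverage is ``mass / n_kmers``.  ``prot`` counts k-mers that
    are protected from coverage-based removal (connectivity sequences carried
    over from a previous, smaller-k assembly iteration).  ``pos_plus`` /
    ``pos_minus`` are optional per-k-mer strand-specific coverage arrays.
    """

    __slots__ = (
        "id", "start", "end", "seq", "mass", "twin_id", "self_rc", "prot",
        "pos_plus", "pos_minus",
    )

    def __init__(self, eid: int, start: int, end: int, seq: str, mass: float,
                 twin_id: int, self_rc: bool = False, prot: int = 0):
        self.id = eid
        self.start = start
        self.end = end
        self.seq = seq
        self.mass = mass
        self.twin_id = twin_id
        self.self_rc = self_rc
        self.prot = prot
        self.pos_plus: Optional[np.ndarray] = None
        self.pos_minus: Optional[np.ndarray] = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Edge({self.id}, len={len(self.seq)}, twin={self.twin_id})"


class CondensedGraph:
    """Bidirected condensed de Bruijn graph over odd k."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.vertices: Dict[int, Vertex] = {}
        self.edges: Dict[int, Edge] = {}
        self._vertex_by_kmer: Dict[str, int] = {}
        self._out: Dict[int, List[int]] = {}
        self._in: Dict[int, List[int]] = {}
        self._next_vid = 0
        self._next_eid = 0

    # -- basic queries -------------------------------------------------

    def n_edges(self) -> int:
        return len(self.edges)

    def n_vertices(self) -> int:
        return len(self.vertices)

    def twin(self, eid: int) -> int:
        return self.edges[eid].twin_id

    def out_edges(self, vid: int) -> List[int]:
        return self._out.get(vid, [])

    def in_edges(self, vid: int) -> List[int]:
        return self._in.get(vid, [])

    def out_degree(self, vid: int) -> int:
        return len(self._out.get(vid, ()))

    def in_degree(self, vid: int) -> int:
        return len(self._in.get(vid, ()))

    def edge_len_kmers(self, eid: int) -> int:
        return len(self.edges[eid].seq) - self.k + 1

    def cov(self, eid: int) -> float:
        e = self.edges[eid]
        return e.mass / (len(e.seq) - self.k + 1)

    def cov_plus(self, eid: int) -> float:
        e = self.edges[eid]
        if e.pos_plus is None:
            return 0.0
        return float(np.mean(e.pos_plus))

    def cov_minus(self, eid: int) -> float:
        e = self.edges[eid]
        if e.pos_minus is None:
            return 0.0
        return float(np.mean(e.pos_minus))

    def edge_pairs(self) -> Iterator[Edge]:
        """One edge per twin pair (the lower id; self-RC edges once)."""
        for e in self.edges.values():
            if e.id <= e.twin_id:
                yield e

    def total_mass(self) -> float:
        """Summed k-mer count mass over one edge per twin pair."""
        return sum(e.mass for e in self.edge_pairs())

    # -- construction helpers ------------------------------------------

    def _get_vertex(self, kmer: str) -> int:
        vid = self._vertex_by_kmer.get(kmer)
        if vid is not None:
            return vid
        rc = revcomp(kmer)
        vid = self._next_vid
        if rc == kmer:
            self.vertices[vid] = Vertex(vid, kmer, vid)
            self._vertex_by_kmer[kmer] = vid
            self._next_vid += 1
        else:
            tid = vid + 1
            self.vertices[vid] = Vertex(vid, kmer, tid)
            self.vertices[tid] = Vertex(tid, rc, vid)
            self._vertex_by_kmer[kmer] = vid
            self._vertex_by_kmer[rc] = tid
            self._next_vid += 2
        return vid

    def add_edge_pair(self, seq: str, mass: float, prot: int = 0) -> Edge:
        """Insert an edge and its twin (or a single self-RC edge).

        Returns the forward-orientation edge.
        """
        if len(seq) < self.k:
            raise ValueError("edge sequence shorter than k")
        rc = revcomp(seq)
        u = self._get_vertex(seq[: self.k - 1])
        v = self._get_vertex(seq[-(self.k - 1):])
        eid = self._next_eid
        if rc == seq:
            edge = Edge(eid, u, v, seq, mass, eid, self_rc=True, prot=prot)
            self.edges[eid] = edge
            self._next_eid += 1
            self._out.setdefault(u, []).append(eid)
            self._in.setdefault(v, []).append(eid)
            return edge
        tid = eid + 1
        ru = self._get_vertex(rc[: self.k - 1])
        rv = self._get_vertex(rc[-(self.k - 1):])
        edge = Edge(eid, u, v, seq, mass, tid, prot=prot)
        tw = Edge(tid, ru, rv, rc, mass, eid, prot=prot)
        self.edges[eid] = edge
        self.edges[tid] = tw
        self._next_eid += 2
        self._out.setdefault(u, []).append(eid)
        self._in.setdefault(v, []).append(eid)
        self._out.setdefault(ru, []).append(tid)
        self._in.setdefault(rv, []).append(tid)
        return edge

    def remove_edge_pair(self, eid: int) -> None:
        """Remove an edge together with its twin; prune orphaned vertices."""
        if eid not in self.edges:
            return
        for rid in {eid, self.edges[eid].twin_id}:
            e = self.edges.pop(rid)
            self._out[e.start].remove(rid)
            self._in[e.end].remove(rid)
        self._prune_vertices()

    def _prune_vertices(self) -> None:
        dead = [
            vid for vid in self.vertices
            if not self._out.get(vid) and not self._in.get(vid)
        ]
        # only prune a vertex when its twin is also unused, so the twin
        # involution never dangles
        for vid in dead:
            if vid not in self.vertices:
                continue
            v = self.vertices[vid]
            tid = v.twin_id
            if tid == vid:
                del self.vertices[vid]
                del self._vertex_by_kmer[v.kmer]
                self._out.pop(vid, None)
                self._in.pop(vid, None)
            elif not self._out.get(tid) and not self._in.get(tid):
                tw = self.vertices[tid]
                for w in (v, tw):
                    del self.vertices[w.id]
                    del self._vertex_by_kmer[w.kmer]
                    self._out.pop(w.id, None)
                    self._in.pop(w.id, None)

    # -- condensation ---------------------------------------------------

    def _is_junction(self, vid: int) -> bool:
        return self.in_degree(vid) != 1 or self.out_degree(vid) != 1

    def recondense(self) -> None:
        """Contract every maximal non-branching chain into a single edge.

        Works at the edge level: chains of edges joined through vertices of
        in-degree 1 and out-degree 1 are merged, twin chains symmetrically.
        Attributes (mass, protected-k-mer count, positional strand arrays)
        are concatenated.
        """
        used: set[int] = set()
        chains: List[List[int]] = []

        def walk(start_eid: int) -> List[int]:
            chain = [start_eid]
            cur = self.edges[start_eid].end
            while not self._is_junction(cur):
                nxt = self._out[cur][0]
                if nxt in used or nxt == start_eid or nxt in chain:
                    break
                # never merge an edge with its own twin through a
                # palindromic vertex boundary mid-walk; the pairing step
                # handles self-twin chains
                chain.append(nxt)
                cur = self.edges[nxt].end
            return chain

        for eid in sorted(self.edges):
            if eid in used:
                continue
            e = self.edges[eid]
            if self._is_junction(e.start):
                chain = walk(eid)
                twin_chain = [self.edges[x].twin_id for x in reversed(chain)]
                used.update(chain)
                used.update(twin_chain)
                chains.append(chain)
        # leftover edges belong to perfect cycles
        for eid in sorted(self.edges):
            if eid in used:
                continue
            chain = [eid]
            used.add(eid)
            cur = self.edges[eid].end
            while True:
                nxt = self._out[cur][0]
                if nxt in used:
                    break
                chain.append(nxt)
                used.add(nxt)
                cur = self.edges[nxt].end
            twin_chain = [self.edges[x].twin_id for x in reversed(chain)]
            used.update(twin_chain)
            chains.append(chain)

        for chain in chains:
            if len(chain) == 1:
                continue  # nothing to merge; edge kept as-is
            self._merge_chain(chain)

    def _merge_chain(self, chain: List[int]) -> None:
        k = self.k
        first = self.edges[chain[0]]
        parts = [first.seq]
        mass = first.mass
        prot = first.prot
        pos_p = [first.pos_plus] if first.pos_plus is not None else None
        pos_m = [first.pos_minus] if first.pos_minus is not None else None
        for eid in chain[1:]:
            e = self.edges[eid]
            parts.append(e.seq[k - 1:])
            mass += e.mass
            prot += e.prot
            if pos_p is not None and e.pos_plus is not None:
                pos_p.append(e.pos_plus)
                pos_m.append(e.pos_minus)
            else:
                pos_p = pos_m = None
        seq = "".join(parts)
        twin_chain = [self.edges[x].twin_id for x in reversed(chain)]
        doomed = set(chain) | set(twin_chain)
        for eid in doomed:
            e = self.edges.pop(eid)
            self._out[e.start].remove(eid)
            self._in[e.end].remove(eid)
        new = self.add_edge_pair(seq, mass, prot=prot)
        if pos_p is not None:
            new.pos_plus = np.concatenate(pos_p)
            new.pos_minus = np.concatenate(pos_m)
            if not new.self_rc:
                tw = self.edges[new.twin_id]
                tw.pos_plus = new.pos_minus[::-1].copy()
                tw.pos_minus = new.pos_plus[::-1].copy()
        self._prune_vertices()

    def copy(self) -> "CondensedGraph":
        """Structural copy (sequences, coverage, protection; strand arrays
        are not carried over)."""
        g = CondensedGraph(self.k)
        for e in self.edge_pairs():
            g.add_edge_pair(e.seq, e.mass, prot=e.prot)
        return g

    # -- indices --------------------------------------------------------

    def kmer_index(self) -> Dict[str, Tuple[int, int]]:
        """Map every k-mer (both orientations) to its (edge id, offset).

        In a condensed graph each oriented k-mer occurs in exactly one edge.
        """
        idx: Dict[str, Tuple[int, int]] = {}
        k = self.k
        for e in self.edges.values():
            seq = e.seq
            for i in range(len(seq) - k + 1):
                idx[seq[i : i + k]] = (e.id, i)
        return idx

    # -- tips -----------------------------------------------------------

    def dead_end_tips(self) -> List[int]:
        """Edges whose end vertex has no outgoing edges."""
        return [
            e.id for e in self.edges.values()
            if self.out_degree(e.end) == 0
        ]

    def dead_start_tips(self) -> List[int]:
        return [
            e.id for e in self.edges.values()
            if self.in_degree(e.start) == 0
        ]

    # -- integrity (used heavily by the test suite) ---------------------

    def assert_valid(self) -> None:
        """Check twin involution, adjacency symmetry and condensation."""
        k = self.k
        for e in self.edges.values():
            tw = self.edges[e.twin_id]
            assert tw.twin_id == e.id, "twin relation is not an involution"
            assert tw.seq == revcomp(e.seq), "twin sequence mismatch"
            assert abs(tw.mass - e.mass) < 1e-6, "twin coverage mismatch"
            assert e.seq[: k - 1] == self.vertices[e.start].kmer
            assert e.seq[-(k - 1):] == self.vertices[e.end].kmer
            assert e.self_rc == (e.seq == revcomp(e.seq))
        for v in self.vertices.values():
            tw = self.vertices[v.twin_id]
            assert tw.twin_id == v.id
            assert tw.kmer == revcomp(v.kmer)
        for vid, eids in self._out.items():
            for eid in eids:
                assert self.edges[eid].start == vid
        for vid, eids in self._in.items():
            for eid in eids:
                assert self.edges[eid].end == vid
        for vid in self.vertices:
            if self.in_degree(vid) == 1 and self.out_degree(vid) == 1:
                ein = self._in[vid][0]
                eout = self._out[vid][0]
                ok = (
                    ein == eout  # self-loop
                    or self.edges[ein].twin_id == eout  # palindromic fold
                )
                assert ok, f"vertex {vid} should have been condensed"

    def spelled_kmer_counts(self) -> Dict[str, int]:
        """Multiset of canonical k-mers spelled by one edge per twin pair.

        A self-RC edge spells both orientations of each of its k-mers, so
        its positions are counted at half weight.
        """
        out: Dict[str, float] = {}
        for e in self.edge_pairs():
            w = 0.5 if e.self_rc else 1
            for km in kmers_of(e.seq, self.k):
                key = canonical(km)
                out[key] = out.get(key, 0) + w
        return {km: int(round(n)) for km, n in out.items()}


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_condensed_graph(
    table: KmerTable, protected: Optional[set] = None
) -> CondensedGraph:
    """Build the condensed bidirected de Bruijn graph from a k-mer table.

    Each canonical k-mer is expanded into both orientations; maximal
    non-branching walks become edges whose mass is the summed count of their
    k-mers.  The twin of every walked unitig is emitted as its exact reverse
    complement, which keeps the two orientations structurally identical.

    ``protected`` is an optional set of canonical k-mers to shield from
    coverage-based cleaning (connectivity carried over from a previous
    assembly iteration); edges record how many of their k-mers it covers.
    """
    if not table.counts:
        raise ValueError("empty k-mer table")
    k = table.k
    protected = protected or set()
    counts: Dict[str, int] = {}
    for km, n in table.counts.items():
        counts[km] = n
        counts[revcomp(km)] = n

    out_deg: Dict[str, int] = {}
    in_deg: Dict[str, int] = {}
    for km in counts:
        pre = km[:-1]
        suf = km[1:]
        out_deg[pre] = out_deg.get(pre, 0) + 1
        in_deg[suf] = in_deg.get(suf, 0) + 1
        out_deg.setdefault(suf, 0)
        in_deg.setdefault(pre, 0)

    def is_junction(node: str) -> bool:
        return in_deg[node] != 1 or out_deg[node] != 1

    def single_successor(node: str) -> str:
        for b in "ACGT":
            nxt = node + b
            if nxt in counts:
                return nxt
        raise AssertionError("no successor for non-junction node")

    graph = CondensedGraph(k)
    used: set[str] = set()

    def emit(seq: str, mass: float) -> None:
        prot = 0
        if protected:
            prot = sum(1 for km in kmers_of(seq, k) if canonical(km) in protected)
        graph.add_edge_pair(seq, mass, prot=prot)
        for km in kmers_of(seq, k):
            used.add(km)
            used.add(revcomp(km))

    for start_km in sorted(counts):
        if start_km in used or not is_junction(start_km[:-1]):
            continue
        seq_parts = [start_km]
        mass = counts[start_km]
        walk_set = {start_km}
        cur = start_km[1:]
        while not is_junction(cur):
            nxt = single_successor(cur)
            if nxt in used or nxt in walk_set:
                break
            seq_parts.append(nxt[-1])
            mass += counts[nxt]
            walk_set.add(nxt)
            cur = nxt[1:]
        emit("".join(seq_parts), mass)

    # leftovers are perfect cycles of non-junction nodes
    for start_km in sorted(counts):
        if start_km in used:
            continue
        seq_parts = [start_km]
        mass = counts[start_km]
        walk_set = {start_km}
        cur = start_km[1:]
        while True:
            nxt = single_successor(cur)
            if nxt in walk_set or nxt in used:
                break
            seq_parts.append(nxt[-1])
            mass += counts[nxt]
            walk_set.add(nxt)
            cur = nxt[1:]
        emit("".join(seq_parts), mass)

    return graph
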