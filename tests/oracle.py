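"""Brute-force condensed de Bruijn graph oracle.

Builds the (k-1)-overlap graph one k-mer at a time and condenses it by
naive walking — independent of the package's construction path.  The graph
is represented as a canonical frozenset of (edge sequence, mass) pairs with
one entry per twin pair, which makes equality checks representation-free.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Tuple

from rnaloom.sequence import canonical, kmers_of, revcomp


def oracle_condensed(table: Dict[str, int], k: int) -> FrozenSet[Tuple[str, float]]:
    """Naive condensation of a canonical k-mer count table."""
    counts: Dict[str, int] = {}
    for km, n in table.items():
        counts[km] = n
        counts[revcomp(km)] = n

    succ = {km: [] for km in counts}
    pred = {km: [] for km in counts}
    for km in counts:
        for b in "ACGT":
            nxt = km[1:] + b
            if nxt in counts:
                succ[km].append(nxt)
                pred[nxt].append(km)

    def node_out(node):
        return [node + b for b in "ACGT" if node + b in counts]

    def node_in(node):
        return [a + node for a in "ACGT" if a + node in counts]

    def branching(node):
        return len(node_out(node)) != 1 or len(node_in(node)) != 1

    unitigs = []
    used = set()

    def walk(start):
        seq = start
        mass = counts[start]
        cur = start
        used.add(start)
        while True:
            node = cur[1:]
            if branching(node):
                break
            nxt = node_out(node)[0]
            if nxt in used:
                break
            seq += nxt[-1]
            mass += counts[nxt]
            used.add(nxt)
            cur = nxt
        return seq, mass

    for km in sorted(counts):
        if km in used or not branching(km[:-1]):
            continue
        unitigs.append(walk(km))
    for km in sorted(counts):  # leftover cycles
        if km not in used:
            unitigs.append(walk(km))

    # one representative per twin pair, canonicalised
    reps = {}
    for seq, mass in unitigs:
        key = _canon_seq(seq, k)
        reps.setdefault(key, mass)
    return frozenset((s, m) for s, m in reps.items())


def _canon_seq(seq: str, k: int) -> str:
    """Orientation- (and, for closed walks, rotation-) independent form."""
    forms = [seq, revcomp(seq)]
    if len(seq) > k - 1 and seq[: k - 1] == seq[-(k - 1):]:
        core = seq[: len(seq) - (k - 1)]  # the cycle of length n k-mers
        forms = []
        for s in (core, revcomp(seq)[: len(seq) - (k - 1)]):
            for i in range(len(s)):
                rot = s[i:] + s[:i]
                forms.append(rot + rot[: k - 1])
    return min(forms)


def canonical_graph_form(graph) -> FrozenSet[Tuple[str, float]]:
    """The same canonical form for a package-built CondensedGraph."""
    reps = {}
    for e in graph.edge_pairs():
        key = _canon_seq(e.seq, graph.k)
        reps.setdefault(key, e.mass)
    return frozenset((s, m) for s, m in reps.items())
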