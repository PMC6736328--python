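"""Shared fixtures and micro-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from rnaloom.graph import KmerTable, build_condensed_graph, count_kmers
from rnaloom.params import AssemblyParams
from rnaloom.sequence import revcomp

BASES = np.array(list("ACGT"))


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def graph_from(seqs_with_mult, k):
    """Condensed graph from (sequence, multiplicity) pairs.

    Multiplicity sets the k-mer coverage of the sequence's private regions.
    """
    reads = []
    for seq, mult in seqs_with_mult:
        reads.extend([seq] * mult)
    return build_condensed_graph(count_kmers(reads, k))


def find_edge(graph, subseq):
    """Id of the edge containing ``subseq`` (forward orientation)."""
    hits = [e.id for e in graph.edges.values() if subseq in e.seq]
    assert hits, f"no edge contains {subseq[:30]}..."
    assert len(hits) == 1, "subsequence is not edge-unique"
    return hits[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params():
    return AssemblyParams()


def make_pairs(transcript, starts, frag_len, read_len):
    """Error-free read pairs from given fragment start positions."""
    pairs = []
    for s in starts:
        frag = transcript[s : s + frag_len]
        if len(frag) < read_len:
            continue
        pairs.append((frag[:read_len], revcomp(frag[-read_len:])))
    return pairs
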