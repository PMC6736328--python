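"""RNA-specific graph cleaning rules and their printed thresholds."""

import numpy as np
import pytest

from rnaloom.graph import build_condensed_graph, count_kmers
from rnaloom.params import AssemblyParams
from rnaloom.sequence import revcomp
from rnaloom.simplify import (
    clip_tips,
    collapse_bulges,
    remove_chimeric_loops,
    remove_hairpins,
    remove_isolated_edges,
    simplify,
    split_edges_by_strand,
)
from rnaloom.simulate import SimConfig, generate_transcriptome, simulate_reads, as_tuples

from conftest import graph_from, rand_seq
from oracle import canonical_graph_form

K = 21
RL = 100


def _tip_fixture(rng, tip_tail, tip_mult, trunk_mult=10):
    """Trunk S1+S2 with a dead-end tip diverging after S1."""
    s1 = rand_seq(rng, 150)
    s2 = rand_seq(rng, 150)
    trunk = s1 + s2
    tip_read = s1 + tip_tail
    g = graph_from([(trunk, trunk_mult), (tip_read, tip_mult)], K)
    return g, s1, s2


class TestClipTips:
    def test_short_weak_tip_removed(self, rng):
        """l < 2k with coverage <= 1: gone."""
        tail = rand_seq(rng, int(1.5 * K))
        g, s1, s2 = _tip_fixture(rng, tail, tip_mult=1)
        clip_tips(g, RL, AssemblyParams())
        assert not any(tail[-K:] in e.seq or tail[-K:] in revcomp(e.seq)
                       for e in g.edges.values())
        assert any(s2[-50:] in e.seq or s2[-50:] in revcomp(e.seq)
                   for e in g.edges.values())

    @staticmethod
    def _mutated_tail(trunk_tail, positions):
        comp = {"A": "C", "C": "A", "G": "T", "T": "G"}
        tail = list(trunk_tail)
        for pos in positions:
            tail[pos] = comp[tail[pos]]
        return "".join(tail)

    def test_error_copy_tip_removed(self, rng):
        """l < 4k, c_T < c_A/2, Hamming <= 3 to the alternative: gone.

        Substitutions sit near the tail end so the tip does not reconverge
        into the trunk.
        """
        s1 = rand_seq(rng, 150)
        s2 = rand_seq(rng, 150)
        tail = self._mutated_tail(s2[: 3 * K], (44, 56))
        g = graph_from([(s1 + s2, 10), (s1 + tail, 4)], K)
        clip_tips(g, RL, AssemblyParams())
        assert not any(tail[-K:] in e.seq or tail[-K:] in revcomp(e.seq)
                       for e in g.edges.values())

    def test_dissimilar_low_cov_tip_retained(self, rng):
        """Boundary: right coverage ratio but Hamming 4 > 3: kept."""
        s1 = rand_seq(rng, 150)
        s2 = rand_seq(rng, 150)
        tail = self._mutated_tail(s2[: 3 * K], (38, 44, 50, 56))
        g = graph_from([(s1 + s2, 10), (s1 + tail, 4)], K)
        clip_tips(g, RL, AssemblyParams())
        assert any(tail[-K:] in e.seq or tail[-K:] in revcomp(e.seq)
                   for e in g.edges.values())

    def test_low_complexity_tip_removed_at_any_coverage(self, rng):
        at = "".join(np.random.default_rng(5).choice(list("AT"), size=200))
        g, s1, s2 = _tip_fixture(rng, at, tip_mult=10)
        clip_tips(g, RL, AssemblyParams())
        assert not any(at[-K:] in e.seq or at[-K:] in revcomp(e.seq)
                       for e in g.edges.values())

    def test_alternative_terminal_exon_tips_survive(self, rng):
        """Two isoforms differing only by last exon keep both termini."""
        shared = rand_seq(rng, 400)
        last_a = rand_seq(rng, 150)
        last_b = rand_seq(rng, 150)
        g = graph_from([(shared + last_a, 8), (shared + last_b, 5)], K)
        simplify(g, RL, AssemblyParams())
        for tail in (last_a, last_b):
            assert any(tail[-K:] in e.seq or tail[-K:] in revcomp(e.seq)
                       for e in g.edges.values())


class TestCollapseBulges:
    def _bulge(self, rng, len1, len2, mult1, mult2):
        p = rand_seq(rng, 150)
        s = rand_seq(rng, 150)
        b1 = rand_seq(rng, len1)
        b2 = rand_seq(rng, len2)
        g = graph_from([(p + b1 + s, mult1), (p + b2 + s, mult2)], K)
        return g, p, s, b1, b2

    def test_similar_length_bulge_collapsed_to_higher_coverage(self, rng):
        g, p, s, b1, b2 = self._bulge(rng, 100, 105, 7, 3)
        before = g.total_mass()
        collapse_bulges(g, AssemblyParams())
        g.assert_valid()
        assert sum(1 for _ in g.edge_pairs()) == 1  # fully linear now
        (e,) = g.edge_pairs()
        assert b1[40:60] in e.seq or b1[40:60] in revcomp(e.seq)
        assert b2[40:60] not in e.seq and b2[40:60] not in revcomp(e.seq)
        # removed k-mer mass is projected onto the kept edge
        assert g.total_mass() == pytest.approx(before)

    def test_exon_length_difference_preserved(self, rng):
        """100 vs 130 bp differs by >10%: the isoform bulge stays."""
        g, p, s, b1, b2 = self._bulge(rng, 100, 130, 7, 3)
        n_before = g.n_edges()
        collapse_bulges(g, AssemblyParams())
        assert g.n_edges() == n_before

    def test_equal_tie_broken_deterministically(self, rng):
        results = []
        for _ in range(2):
            r = np.random.default_rng(77)
            p = rand_seq(r, 150)
            s = rand_seq(r, 150)
            b1 = rand_seq(r, 100)
            b2 = rand_seq(r, 100)
            g = graph_from([(p + b1 + s, 5), (p + b2 + s, 5)], K)
            collapse_bulges(g, AssemblyParams())
            (e,) = g.edge_pairs()
            results.append(e.seq)
        assert results[0] == results[1]
        assert sum(1 for _ in [results[0]]) == 1

    def test_no_coverage_threshold_applied(self, rng):
        """Even a 100:1 coverage imbalance collapses on length alone."""
        g, p, s, b1, b2 = self._bulge(rng, 100, 102, 100, 1)
        collapse_bulges(g, AssemblyParams())
        assert sum(1 for _ in g.edge_pairs()) == 1


class TestChimericConnections:
    def test_terminal_loop_removed_transcript_intact(self, rng):
        t = rand_seq(rng, 600)
        loop_read = t[-50:] + (t[-30:] * 4)[:50]
        g = graph_from([(t, 10), (loop_read, 1)], K)
        assert any(e.start == e.end for e in g.edges.values())
        remove_chimeric_loops(g)
        g.assert_valid()
        assert not any(e.start == e.end for e in g.edges.values())
        assert any(t[100:300] in e.seq or t[100:300] in revcomp(e.seq)
                   for e in g.edges.values())

    def test_loop_next_to_short_edge_retained(self, rng):
        """The anchor edge must be long (> 2k): a loop hanging off a short
        fragment is not confidently chimeric."""
        t = rand_seq(rng, 60)
        loop_read = t[-50:] + (t[-30:] * 4)[:50]
        g = graph_from([(t, 10), (loop_read, 1)], K)
        assert any(e.start == e.end for e in g.edges.values())
        remove_chimeric_loops(g)
        assert any(e.start == e.end for e in g.edges.values())

    def test_long_loop_retained(self, rng):
        """A self-loop holding a long stretch (>= 2k) of sequence is kept:
        it contains genuine transcript tail, not just a chimeric junction."""
        t = rand_seq(rng, 600)
        loop_read = t[-50:] + t[-60:][:50]  # re-copies a 60 bp terminal unit
        g = graph_from([(t, 10), (loop_read, 1)], K)
        loops = [e for e in g.edges.values() if e.start == e.end]
        assert loops and all(len(e.seq) - K + 1 >= 2 * K for e in loops)
        remove_chimeric_loops(g)
        assert any(e.start == e.end for e in g.edges.values())

    def test_loop_free_graph_unchanged(self, rng):
        g = graph_from([(rand_seq(rng, 400), 5)], K)
        before = canonical_graph_form(g)
        remove_chimeric_loops(g)
        assert canonical_graph_form(g) == before

    def test_hairpin_edge_removed(self, rng):
        t = rand_seq(rng, 600)
        a = 400
        h = 50
        hairpin_read = t[a : a + h] + revcomp(t[a : a + h])  # fold-back
        g = graph_from([(t, 10), (hairpin_read, 2)], K)
        had_hairpin = any(
            g.vertices[e.start].twin_id == e.end and e.start != e.end
            for e in g.edges.values()
        )
        assert had_hairpin
        remove_hairpins(g)
        g.assert_valid()
        assert not any(
            g.vertices[e.start].twin_id == e.end and e.start != e.end
            for e in g.edges.values()
        )
        assert any(t[100:300] in e.seq or t[100:300] in revcomp(e.seq)
                   for e in g.edges.values())

    def test_cross_transcript_inverted_repeat_retained(self, rng):
        """rc-shared sequence between two transcripts is not a hairpin."""
        x = rand_seq(rng, 120)
        t1 = rand_seq(rng, 200) + x + rand_seq(rng, 200)
        t2 = rand_seq(rng, 200) + revcomp(x) + rand_seq(rng, 200)
        g = graph_from([(t1, 5), (t2, 5)], K)
        before = canonical_graph_form(g)
        remove_hairpins(g)
        assert canonical_graph_form(g) == before


class TestIsolatedEdges:
    @pytest.mark.parametrize(
        "mult,length,removed",
        [
            (1, RL, True),       # low coverage, length == read length
            (1, RL + 1, False),  # one base too long
            (2, RL, False),      # coverage not strictly below 2
        ],
    )
    def test_boundaries(self, mult, length, removed, rng):
        g = graph_from([(rand_seq(rng, length), mult)], K)
        remove_isolated_edges(g, RL, AssemblyParams())
        assert (g.n_edges() == 0) == removed


class TestStrandSplitting:
    def _annotated_single_edge(self, rng, plus, minus):
        seq = rand_seq(rng, len(plus) + K - 1)
        g = build_condensed_graph(count_kmers([seq], K))
        (e,) = g.edge_pairs()
        e.pos_plus = np.asarray(plus, dtype=float)
        e.pos_minus = np.asarray(minus, dtype=float)
        tw = g.edges[e.twin_id]
        tw.pos_plus = e.pos_minus[::-1].copy()
        tw.pos_minus = e.pos_plus[::-1].copy()
        return g

    def test_opposite_strand_halves_split(self, rng):
        n = 400
        plus = [12.0] * (n // 2) + [0.3] * (n // 2)
        minus = [0.3] * (n // 2) + [12.0] * (n // 2)
        g = self._annotated_single_edge(rng, plus, minus)
        split_edges_by_strand(g, AssemblyParams())
        g.assert_valid()
        assert sum(1 for _ in g.edge_pairs()) == 2
        # pieces share no vertex: both are isolated
        for e in g.edge_pairs():
            assert g.in_degree(e.start) == 0 or g.out_degree(e.end) == 0

    def test_uniform_edge_not_split(self, rng):
        g = self._annotated_single_edge(rng, [10.0] * 300, [0.2] * 300)
        split_edges_by_strand(g, AssemblyParams())
        assert sum(1 for _ in g.edge_pairs()) == 1

    def test_ratio_below_threshold_not_split(self, rng):
        n = 400
        plus = [3.0] * (n // 2) + [1.0] * (n // 2)
        minus = [1.0] * (n // 2) + [3.0] * (n // 2)
        g = self._annotated_single_edge(rng, plus, minus)
        split_edges_by_strand(g, AssemblyParams())
        assert sum(1 for _ in g.edge_pairs()) == 1


class TestSimplify:
    def _reads(self, error_rate, seed=42):
        cfg = SimConfig(n_genes=1, single_isoform_fraction=1.0, seed=seed,
                        error_rate=error_rate, chimera_rate=0.0, depth=20.0)
        tr, truth = generate_transcriptome(cfg)
        pairs = as_tuples(simulate_reads(tr, truth, cfg))
        return tr[0][1], [r for p in pairs for r in p]

    def test_clean_reads_give_single_transcript_edge(self):
        t, reads = self._reads(0.0)
        g = build_condensed_graph(count_kmers(reads, 49))
        simplify(g, RL, AssemblyParams())
        (e,) = g.edge_pairs()
        # uniform fragmentation leaves the extreme ends slightly uncovered
        assert e.seq in t or e.seq in revcomp(t)
        assert len(e.seq) > 0.97 * len(t)

    def test_errors_are_denoised_to_clean_graph(self):
        """0.5% substitution errors leave the same final graph."""
        t, clean = self._reads(0.0)
        _, noisy = self._reads(0.005)
        g_clean = simplify(
            build_condensed_graph(count_kmers(clean, 49)), RL, AssemblyParams()
        )
        g_noisy = simplify(
            build_condensed_graph(count_kmers(noisy, 49)), RL, AssemblyParams()
        )
        clean_pairs = list(g_clean.edge_pairs())
        noisy_pairs = list(g_noisy.edge_pairs())
        assert len(clean_pairs) == len(noisy_pairs) == 1
        a, b = clean_pairs[0].seq, noisy_pairs[0].seq
        if b[100:140] not in a:
            b = revcomp(b)
        # identical up to a few terminal bases (end-coverage noise)
        assert b[5:-5] in a or a[5:-5] in b
        assert abs(len(a) - len(b)) <= 10

    def test_idempotent(self):
        _, noisy = self._reads(0.01, seed=7)
        g = simplify(
            build_condensed_graph(count_kmers(noisy, 49)), RL, AssemblyParams()
        )
        once = canonical_graph_form(g)
        simplify(g, RL, AssemblyParams())
        assert canonical_graph_form(g) == once

    def test_monotone_destruction(self):
        """Simplification never invents k-mers."""
        _, noisy = self._reads(0.01, seed=9)
        table = count_kmers(noisy, 49)
        g = build_condensed_graph(table)
        simplify(g, RL, AssemblyParams())
        assert set(g.spelled_kmer_counts()) <= set(table.counts)

    def test_empty_graph_passthrough(self):
        from rnaloom.graph import CondensedGraph
        g = CondensedGraph(21)
        simplify(g, RL, AssemblyParams())
        assert g.n_edges() == 0
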