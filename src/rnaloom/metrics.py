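"""Assembly evaluation against a known reference transcriptome.

Contigs are aligned to reference transcripts by exact k-mer anchor chaining
(k = 31): anchors on the same transcript and strand with consistent
diagonals are chained into alignment blocks.  From the blocks the headline
metrics are computed:

* X%-assembled — a reference transcript with at least X% of its length
  covered by a *single* contig alignment block;
* database coverage — fraction of reference bases covered by any block;
* duplication ratio — aligned contig bases / covered reference bases;
* misassemblies — contigs whose alignment decomposes into blocks from
  different transcripts, or strand-discordant / distant (> 1 kb) positions
  of one transcript.

This is a deliberately small re-statement of the standard reference-based
metrics for synthetic desk-scale data; it does not reimplement a spliced
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from .paths import Contig
from .sequence import revcomp

_K_EVAL = 31
_DIAG_TOL = 30          # max diagonal drift within one chain
_CHAIN_GAP = 500        # max anchor gap (bp) bridged inside one chain
_MIN_CHAIN = 62         # ignore chains shorter than two anchors
_MIN_MIS_BLOCK = 100    # a misassembly block must be substantial
_DIST_CUTOFF = 1000     # distant-position cutoff within one transcript


@dataclass
class Block:
    """One chained alignment block of a contig on a reference transcript."""

    rid: str
    strand: str  # '+' or '-'
    c_start: int
    c_end: int
    r_start: int
    r_end: int

    def c_len(self) -> int:
        return self.c_end - self.c_start


@dataclass
class EvalReport:
    n_transcripts: int
    n_reference: int
    n_assembled_50: int
    n_assembled_95: int
    database_coverage: float
    duplication_ratio: float
    n_misassemblies: int
    n_unaligned: int
    misassembled: List[str] = field(default_factory=list)
    per_reference: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_transcripts": self.n_transcripts,
            "n_reference": self.n_reference,
            "n_assembled_50": self.n_assembled_50,
            "n_assembled_95": self.n_assembled_95,
            "database_coverage": self.database_coverage,
            "duplication_ratio": self.duplication_ratio,
            "n_misassemblies": self.n_misassemblies,
            "n_unaligned": self.n_unaligned,
        }


def _ref_index(reference: Sequence[Tuple[str, str]]) -> Dict[str, List[Tuple[str, int]]]:
    idx: Dict[str, List[Tuple[str, int]]] = {}
    for rid, seq in reference:
        for i in range(len(seq) - _K_EVAL + 1):
            idx.setdefault(seq[i : i + _K_EVAL], []).append((rid, i))
    return idx


def _chain_hits(points: List[Tuple[int, int]]) -> List[Tuple[int, int, int, int]]:
    """Chain (contig_pos, ref_pos) anchors into colinear blocks."""
    points.sort()
    blocks = []
    cs, ce, rs, re_ = None, None, None, None
    prev_c, prev_r = None, None
    for c, r in points:
        if cs is None:
            cs, ce, rs, re_ = c, c, r, r
        else:
            diag_drift = abs((r - c) - (prev_r - prev_c))
            if (
                c >= prev_c
                and r > prev_r - _DIAG_TOL
                and diag_drift <= _DIAG_TOL
                and c - prev_c <= _CHAIN_GAP
            ):
                ce, re_ = max(ce, c), max(re_, r)
            else:
                blocks.append((cs, ce + _K_EVAL, rs, re_ + _K_EVAL))
                cs, ce, rs, re_ = c, c, r, r
        prev_c, prev_r = c, r
    if cs is not None:
        blocks.append((cs, ce + _K_EVAL, rs, re_ + _K_EVAL))
    return blocks


def align_contig(
    seq: str, idx: Dict[str, List[Tuple[str, int]]]
) -> List[Block]:
    """All chained alignment blocks of one contig, both strands."""
    blocks: List[Block] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        per_ref: Dict[str, List[Tuple[int, int]]] = {}
        for i in range(len(s) - _K_EVAL + 1):
            for rid, rpos in idx.get(s[i : i + _K_EVAL], ()):
                per_ref.setdefault(rid, []).append((i, rpos))
        for rid, pts in per_ref.items():
            for cs, ce, rs, re_ in _chain_hits(pts):
                if ce - cs >= _MIN_CHAIN:
                    if strand == "-":
                        cs, ce = len(s) - ce, len(s) - cs
                    blocks.append(Block(rid, strand, cs, ce, rs, re_))
    return blocks


def _union_len(intervals: List[Tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _select_primary(blocks: List[Block]) -> List[Block]:
    """Greedy non-redundant decomposition of a contig's alignment.

    Blocks are taken longest-first; a block is kept when it explains enough
    contig sequence not already covered by the blocks chosen before it.
    Counting *novel* span (rather than fractional overlap) matters for
    chimeras whose halves share a repeat: both alignments overlap heavily on
    the repeat yet each one alone leaves part of the contig unexplained.
    """
    chosen: List[Block] = []
    covered: List[Tuple[int, int]] = []
    for b in sorted(blocks, key=lambda x: -x.c_len()):
        base = _union_len(covered)
        novel = _union_len(covered + [(b.c_start, b.c_end)]) - base
        if novel >= max(_MIN_MIS_BLOCK, 0.1 * b.c_len()) or not chosen:
            chosen.append(b)
            covered.append((b.c_start, b.c_end))
    return chosen


def _is_misassembled(primary: List[Block]) -> bool:
    big = [b for b in primary if b.c_len() >= _MIN_MIS_BLOCK]
    if len(big) < 2:
        return False
    rids = {b.rid for b in big}
    if len(rids) > 1:
        return True
    strands = {b.strand for b in big}
    if len(strands) > 1:
        return True
    spans = sorted((b.r_start, b.r_end) for b in big)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 - e1 > _DIST_CUTOFF:
            return True
    return False


def evaluate(
    contigs: Union[Sequence[Contig], Sequence[Tuple[str, str]]],
    reference: Sequence[Tuple[str, str]],
    thresholds: Iterable[float] = (0.50, 0.95),
) -> EvalReport:
    """Score an assembly against reference transcripts.

    ``contigs`` may be :class:`~rnaloom.paths.Contig` objects or plain
    ``(name, seq)`` tuples; ``reference`` is ``(id, seq)`` tuples.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    items: List[Tuple[str, str]] = []
    for c in contigs:
        if isinstance(c, Contig):
            items.append((c.name or f"contig_{len(items)}", c.seq))
        else:
            items.append((c[0], c[1]))
    thresholds = sorted(thresholds)
    idx = _ref_index(reference)
    ref_len = {rid: len(seq) for rid, seq in reference}

    best_single: Dict[str, float] = {rid: 0.0 for rid in ref_len}
    ref_cov: Dict[str, List[Tuple[int, int]]] = {rid: [] for rid in ref_len}
    aligned_contig_bases = 0
    n_mis = 0
    n_unaligned = 0
    mis_names: List[str] = []

    for name, seq in items:
        blocks = align_contig(seq, idx)
        if not blocks:
            n_unaligned += 1
            continue
        for b in blocks:
            ref_cov[b.rid].append((b.r_start, min(b.r_end, ref_len[b.rid])))
            frac = (min(b.r_end, ref_len[b.rid]) - b.r_start) / ref_len[b.rid]
            best_single[b.rid] = max(best_single[b.rid], frac)
        aligned_contig_bases += _union_len(
            [(b.c_start, b.c_end) for b in blocks]
        )
        primary = _select_primary(blocks)
        if _is_misassembled(primary):
            n_mis += 1
            mis_names.append(name)

    covered_ref_bases = sum(_union_len(v) for v in ref_cov.values())
    total_ref_bases = sum(ref_len.values())
    counts = {
        t: sum(1 for f in best_single.values() if f >= t) for t in thresholds
    }
    return EvalReport(
        n_transcripts=len(items),
        n_reference=len(ref_len),
        n_assembled_50=counts.get(0.50, 0),
        n_assembled_95=counts.get(0.95, 0),
        database_coverage=covered_ref_bases / total_ref_bases,
        duplication_ratio=(
            aligned_contig_bases / covered_ref_bases if covered_ref_bases else 0.0
        ),
        n_misassemblies=n_mis,
        n_unaligned=n_unaligned,
        misassembled=mis_names,
        per_reference=best_single,
    )
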