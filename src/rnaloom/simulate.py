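"""Ground-truthed transcriptome and paired-end RNA-seq read simulator.

The generator emits every structure the assembler is designed to handle:
multi-exon genes with alternatively spliced isoform pairs (skipped exons,
alternative first/last exons), optional diverged paralogs, poly-A tails
(exercising the low-complexity tip rule), log-normal expression, uniform
fragmentation with normally distributed insert sizes, i.i.d. substitution
errors and, on request, injected chimeric reads of the two classes seen in
real libraries: same-strand loops (a junction from a transcript's end back
into itself) and opposite-strand hairpins.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .sequence import revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class GeneModel:
    gene_id: str
    exons: List[str]
    isoforms: List[List[int]]  # exon-index lists, strictly increasing
    expression: List[float]

    def transcript(self, iso: int, polya: int) -> str:
        return "".join(self.exons[i] for i in self.isoforms[iso]) + "A" * polya


@dataclass
class TruthRecord:
    transcript_id: str
    gene_id: str
    structure: str  # comma-joined exon indices
    weight: float
    length: int


@dataclass
class ReadPair:
    r1: str
    r2: str
    tid: str
    frag_start: int
    frag_end: int
    chimera: Optional[str] = None  # None | "loop" | "hairpin"


@dataclass
class SimConfig:
    """Study conditions for the simulator (all stochastic calls are seeded)."""

    n_genes: int = 50
    #: probability of each isoform-pair event for two-isoform genes
    event_mix: Dict[str, float] = field(
        default_factory=lambda: {"skipped_exon": 1.0, "alt_first": 0.0, "alt_last": 0.0}
    )
    single_isoform_fraction: float = 0.0
    n_exons_range: Tuple[int, int] = (5, 7)
    exon_len_range: Tuple[int, int] = (180, 350)
    #: the skippable internal exon; longer than any assembly k so both
    #: isoforms are structurally distinguishable in the graph
    skip_exon_len_range: Tuple[int, int] = (60, 160)
    #: chimeric-loop jump distance back from the transcript end (bp)
    loop_jump_range: Tuple[int, int] = (10, 35)
    paralog_rate: float = 0.0
    paralog_divergence: float = 0.05
    expression_mu: float = 0.0
    expression_sigma: float = 0.6
    depth: float = 20.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.005
    strandedness: Optional[str] = None  # None | "rf" | "fr"
    chimera_rate: float = 0.01
    chimera_mix: Dict[str, float] = field(
        default_factory=lambda: {"loop": 0.5, "hairpin": 0.5}
    )
    polya_len: int = 15
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.paralog_rate, self.error_rate, self.chimera_rate,
                  self.single_isoform_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.exon_len_range[0] < 1 or self.skip_exon_len_range[0] < 1:
            raise ValueError("exons must be at least 1 bp")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(
    config: SimConfig,
) -> Tuple[List[Tuple[str, str]], List[TruthRecord]]:
    """Generate transcripts and their truth table.

    Returns ``(records, truth)`` where records are ``(transcript_id, seq)``
    pairs.  Two-isoform genes differ by one event from ``event_mix``:
    a skipped internal exon, or an alternative first/last exon.  Paralogs
    are diverged whole-gene copies.
    """
    rng = np.random.default_rng(config.seed)
    genes: List[GeneModel] = []
    event_names = sorted(config.event_mix)
    event_p = np.array([config.event_mix[e] for e in event_names], dtype=float)
    if event_p.sum() <= 0:
        raise ValueError("event_mix must have positive total weight")
    event_p = event_p / event_p.sum()

    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        lens = [
            int(rng.integers(config.exon_len_range[0], config.exon_len_range[1] + 1))
            for _ in range(n_ex)
        ]
        single = rng.random() < config.single_isoform_fraction
        event = event_names[rng.choice(len(event_names), p=event_p)]
        exons: List[str] = []
        if single:
            exons = [_rand_seq(rng, L) for L in lens]
            isoforms = [list(range(n_ex))]
        elif event == "skipped_exon":
            skip_idx = int(rng.integers(1, n_ex - 1))
            lens[skip_idx] = int(
                rng.integers(config.skip_exon_len_range[0],
                             config.skip_exon_len_range[1] + 1)
            )
            exons = [_rand_seq(rng, L) for L in lens]
            isoforms = [
                list(range(n_ex)),
                [i for i in range(n_ex) if i != skip_idx],
            ]
        elif event == "alt_first":
            # two distinct first exons, shared remainder
            exons = [_rand_seq(rng, L) for L in lens]
            exons.append(_rand_seq(rng, lens[0]))
            isoforms = [
                list(range(n_ex)),
                [n_ex] + list(range(1, n_ex)),
            ]
        elif event == "alt_last":
            exons = [_rand_seq(rng, L) for L in lens]
            exons.append(_rand_seq(rng, lens[-1]))
            isoforms = [
                list(range(n_ex)),
                list(range(n_ex - 1)) + [n_ex],
            ]
        else:
            raise ValueError(f"unknown isoform event: {event}")
        expr = list(
            np.exp(rng.normal(config.expression_mu, config.expression_sigma,
                              size=len(isoforms)))
        )
        genes.append(GeneModel(f"gene_{gi}", exons, isoforms, expr))

    # paralogs: diverged copies of existing genes
    n_par = int(round(config.paralog_rate * config.n_genes))
    for pi in range(n_par):
        src = genes[int(rng.integers(0, config.n_genes))]
        exons = [
            _mutate(rng, ex, config.paralog_divergence) for ex in src.exons
        ]
        expr = list(
            np.exp(rng.normal(config.expression_mu, config.expression_sigma,
                              size=len(src.isoforms)))
        )
        genes.append(
            GeneModel(f"{src.gene_id}_par{pi}", exons,
                      [list(iso) for iso in src.isoforms], expr)
        )

    records: List[Tuple[str, str]] = []
    truth: List[TruthRecord] = []
    for g in genes:
        for ii, iso in enumerate(g.isoforms):
            tid = f"{g.gene_id}_iso{ii}"
            seq = g.transcript(ii, config.polya_len)
            records.append((tid, seq))
            truth.append(
                TruthRecord(
                    transcript_id=tid,
                    gene_id=g.gene_id,
                    structure=",".join(map(str, iso)),
                    weight=g.expression[ii],
                    length=len(seq),
                )
            )
    return records, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    transcripts: List[Tuple[str, str]],
    truth: List[TruthRecord],
    config: SimConfig,
) -> List[ReadPair]:
    """Simulate paired-end reads.

    Fragment counts are proportional to expression weight times transcript
    length (mean k-mer depth across transcripts equals ``config.depth``);
    fragment starts are uniform and lengths normal(insert_mean, insert_sd).
    Mates of ``read_length`` bp are taken from the fragment ends;
    orientation follows the protocol (unstranded: random fragment strand,
    FR: mate 1 sense, RF: mate 1 antisense).  Substitution errors are
    i.i.d. at ``error_rate``.
    """
    rng = np.random.default_rng((config.seed + 1) % 2**31)
    weights = {t.transcript_id: t.weight for t in truth}
    mean_w = float(np.mean([t.weight for t in truth])) if truth else 1.0
    rl = config.read_length
    pairs: List[ReadPair] = []
    min_len = config.insert_mean - 3 * config.insert_sd
    for tid, seq in transcripts:
        if len(seq) < min_len:
            warnings.warn(
                f"transcript {tid} shorter than insert mean - 3 sd; skipped",
                stacklevel=2,
            )
            continue
        depth_t = config.depth * weights.get(tid, 1.0) / mean_w
        n_frag = int(round(depth_t * len(seq) / (2 * rl)))
        for _ in range(n_frag):
            frag_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            frag_len = max(rl, min(frag_len, len(seq)))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            sense1 = frag[:rl]
            sense2 = revcomp(frag[-rl:])
            if config.strandedness is None:
                if rng.random() < 0.5:
                    r1, r2 = sense1, sense2
                else:
                    # fragment sequenced from the opposite strand
                    r1, r2 = revcomp(frag[-rl:]), frag[:rl]
            elif config.strandedness.lower() == "fr":
                r1, r2 = sense1, sense2
            elif config.strandedness.lower() == "rf":
                r1, r2 = revcomp(frag[-rl:]), frag[:rl]
            else:
                raise ValueError(f"unknown strandedness {config.strandedness!r}")
            r1 = _mutate(rng, r1, config.error_rate)
            r2 = _mutate(rng, r2, config.error_rate)
            pairs.append(ReadPair(r1, r2, tid, start, start + frag_len))
    return pairs


# ---------------------------------------------------------------------------
# Chimeras
# ---------------------------------------------------------------------------

def inject_chimeras(
    read_pairs: List[ReadPair],
    transcripts: List[Tuple[str, str]],
    config: SimConfig,
) -> Tuple[List[ReadPair], List[Tuple[int, str]]]:
    """Replace a random subset of first mates with chimeric reads.

    Loop chimeras jump from near a transcript's 3' end back to an earlier
    position on the same strand; hairpin chimeras jump onto the opposite
    strand close by.  Returns the new pair list plus a log of
    ``(pair index, chimera type)``.
    """
    rng = np.random.default_rng((config.seed + 2) % 2**31)
    seqs = dict(transcripts)
    mix_names = sorted(config.chimera_mix)
    mix_p = np.array([config.chimera_mix[m] for m in mix_names], dtype=float)
    if mix_p.sum() <= 0:
        mix_p = np.ones(len(mix_names))
    mix_p = mix_p / mix_p.sum()
    rl = config.read_length
    out: List[ReadPair] = []
    log: List[Tuple[int, str]] = []
    for i, p in enumerate(read_pairs):
        if config.chimera_rate <= 0 or rng.random() >= config.chimera_rate:
            out.append(p)
            continue
        t = seqs.get(p.tid)
        if t is None or len(t) < 2 * rl:
            out.append(p)
            continue
        kind = mix_names[rng.choice(len(mix_names), p=mix_p)]
        h = rl // 2
        if kind == "loop":
            # the polymerase runs to the transcript end and jumps back a
            # few tens of bases on the same strand
            a = len(t) - h
            jump = int(rng.integers(config.loop_jump_range[0],
                                    config.loop_jump_range[1] + 1))
            b = max(0, len(t) - jump)
            unit = t[b:]  # the re-copied terminal stretch
            chim = t[a : a + h] + (unit * (rl // max(len(unit), 1) + 2))[: rl - h]
        else:
            # hairpin: the polymerase folds back onto the opposite strand
            # at the break point, copying back over what it just made
            a = int(rng.integers(rl, len(t) - h + 1))
            fold = a + h
            chim = t[a : a + h] + revcomp(t[fold - (rl - h) : fold])
        chim = _mutate(rng, chim, config.error_rate)
        out.append(ReadPair(chim, p.r2, p.tid, p.frag_start, p.frag_end, kind))
        log.append((i, kind))
    return out, log


def as_tuples(pairs: List[ReadPair]) -> List[Tuple[str, str]]:
    """Strip provenance: plain (mate 1, mate 2) tuples for the assembler."""
    return [(p.r1, p.r2) for p in pairs]
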