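"""File formats: FASTQ/FASTA (gzip-transparent), GFA 1.0, TSV, YAML config."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Dict, Iterable, List, Optional, Tuple, Union

import yaml
from Bio import SeqIO

from .graph import CondensedGraph
from .paths import Contig

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> List[str]:
    """Read sequences from a (possibly gzipped) FASTQ file.

    Qualities are parsed (format validation) but discarded — the assembler
    does not use them.
    """
    try:
        with _open_text(path) as fh:
            return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]
    except (ValueError, EOFError) as exc:
        raise ValueError(f"malformed or truncated FASTQ {path}: {exc}") from exc


def read_fastq_pairs(path1: PathLike, path2: PathLike) -> List[Tuple[str, str]]:
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files differ in read count: {len(r1)} vs {len(r2)}"
        )
    return list(zip(r1, r2))


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(
    records: Iterable[Union[Tuple[str, str], Contig]],
    path: PathLike,
    width: int = 80,
) -> None:
    """Write records (``(id, seq)`` tuples or contigs) wrapped at 80 columns."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, Contig):
                name, seq = rec.name, rec.seq
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    reads: Iterable[Tuple[str, str]], path: PathLike, quality_char: str = "I"
) -> None:
    """Write (id, seq) reads as FASTQ with constant placeholder qualities."""
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_gfa(graph: CondensedGraph, path: PathLike) -> None:
    """Dump the graph as GFA 1.0.

    One S-line per edge twin pair (KC = k-mer count mass, km = mean k-mer
    coverage); L-lines carry the (k-1)M overlap.  Orientation '-' refers to
    the twin of the named segment.
    """
    k = graph.k

    def seg(eid: int) -> Tuple[str, str]:
        t = graph.twin(eid)
        rep = min(eid, t)
        return f"e{rep}", "+" if eid == rep else "-"

    with _open_text(path, "wt") as fh:
        fh.write(f"H\tVN:Z:1.0\tkk:i:{k}\n")
        for e in graph.edge_pairs():
            fh.write(
                f"S\te{e.id}\t{e.seq}\tKC:i:{int(round(e.mass))}"
                f"\tkm:f:{graph.cov(e.id):.4f}\n"
            )
        seen = set()
        for vid in graph.vertices:
            for ein in graph.in_edges(vid):
                for eout in graph.out_edges(vid):
                    a, ao = seg(ein)
                    b, bo = seg(eout)
                    flip = {"+": "-", "-": "+"}
                    key = min(
                        (a, ao, b, bo), (b, flip[bo], a, flip[ao])
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{k - 1}M\n")


def read_gfa(
    path: PathLike,
) -> Tuple[Dict[str, Tuple[str, float]], List[Tuple[str, str, str, str]]]:
    """Parse a GFA 1.0 file.

    Returns ``(segments, links)``: segments map name -> (sequence, KC mass);
    links are (seg_a, orient_a, seg_b, orient_b) tuples.
    """
    segments: Dict[str, Tuple[str, float]] = {}
    links: List[Tuple[str, str, str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            if fields[0] == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S-line")
                name, seq = fields[1], fields[2]
                mass = 0.0
                for tag in fields[3:]:
                    if tag.startswith("KC:i:"):
                        mass = float(tag[5:])
                segments[name] = (seq, mass)
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed L-line")
                links.append((fields[1], fields[2], fields[3], fields[4]))
    return segments, links


# ---------------------------------------------------------------------------
# Tables and config
# ---------------------------------------------------------------------------

def write_tsv(rows: Iterable[Iterable], header: List[str], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def dump_params_yaml(data: dict, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: Optional[PathLike] = None, **overrides) -> dict:
    """Merge a YAML config file with keyword overrides (flags win)."""
    cfg: dict = {}
    if path is not None:
        with _open_text(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
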