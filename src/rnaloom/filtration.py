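"""Output filtration: soft / normal / hard contig filters.

Non-mRNA contamination (intergenic fragments, unspliced leftovers) tends to
be short, weakly covered and to sit on isolated graph edges, but so do some
genuine low-expressed transcripts — hence three presets trading sensitivity
(soft) against specificity (hard).  Filtration is a pure function of contig
length, coverage and the isolated-edge provenance flag, and the three
outputs always nest: hard ⊆ normal ⊆ soft.
"""

from __future__ import annotations

from typing import List, Optional, Union

from .params import AssemblyParams, FiltrationPreset
from .paths import Contig


def filter_transcripts(
    contigs: List[Contig],
    preset: Union[str, FiltrationPreset],
    read_length: int,
    params: Optional[AssemblyParams] = None,
) -> List[Contig]:
    """Apply one filtration preset to a contig list.

    A contig is kept when its length reaches ``min_len``, its mean k-mer
    coverage reaches ``min_cov``, and — if it derives from a single isolated
    graph edge — its length exceeds ``drop_isolated_below_len_factor`` times
    the read length.
    """
    if isinstance(preset, str):
        if params is None:
            params = AssemblyParams()
        try:
            preset = params.presets[preset]
        except KeyError:
            raise ValueError(f"unknown filtration preset: {preset!r}") from None
    iso_cut = preset.drop_isolated_below_len_factor * read_length
    kept = []
    for c in contigs:
        if len(c.seq) < preset.min_len:
            continue
        if c.cov < preset.min_cov:
            continue
        if c.isolated and len(c.seq) <= iso_cut:
            continue
        kept.append(c)
    return kept
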