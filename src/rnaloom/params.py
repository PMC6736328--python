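"""Assembly parameters.

Every tunable constant of the pipeline lives in :class:`AssemblyParams` so
that each cleaning rule, the gap closer and the path extender can be
exercised (and documented) from one place.  Defaults follow the published
parameterisation of modern transcriptome assemblers where a value is
printed, and are documented implementation choices otherwise (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class FiltrationPreset:
    """Output filter: drop short / low-coverage / isolated-edge contigs."""

    name: str
    min_len: int
    min_cov: float
    #: isolated-single-edge contigs shorter than this are additionally dropped;
    #: expressed as a multiple of read length at application time.
    drop_isolated_below_len_factor: float


@dataclass
class AssemblyParams:
    """All thresholds used by graph cleaning, gap closing and path extension.

    Tip clipping
    ------------
    A tip (dead-end or dead-start edge) of graph length ``l`` (in k-mers)
    and mean coverage ``c_T`` is removed when any of:

    1. ``l < tip_short_len_factor * k`` and ``c_T <= tip_short_cov_max``;
    2. ``l < tip_err_len_factor * k``, ``c_T < tip_err_cov_ratio * c_A``
       (``c_A`` = coverage of the best alternative edge) and the Hamming
       distance to that alternative is ``<= tip_err_hamming_max``;
    3. the tip sequence is more than ``tip_at_frac`` A/T (poly-A artefact).

    Gap closing
    -----------
    Two tips are glued if they share an exact overlap of at least ``l_ov``
    bp and at least ``n_ov`` read pairs connect them, or if at least
    ``n_min`` read pairs connect them regardless of overlap.

    Path extension
    --------------
    ``extension_c`` (C) controls the multi-extension fork: all candidates
    scoring above ``max_score / C`` and above ``theta`` are kept.  The
    coverage-based fallback uses ``delta`` (minimum fold difference),
    ``omega`` (coverage persistence band) and ``c_min`` (minimum absolute
    coverage of the chosen extension).
    """

    # -- tip clipping -------------------------------------------------
    tip_short_len_factor: float = 2.0
    tip_short_cov_max: float = 1.0
    tip_err_len_factor: float = 4.0
    tip_err_cov_ratio: float = 0.5
    tip_err_hamming_max: int = 3
    tip_at_frac: float = 0.80

    # -- bulges -------------------------------------------------------
    bulge_len_diff_max: float = 0.10

    # -- isolated edges -----------------------------------------------
    iso_edge_cov_max: float = 2.0  # strict: cov < 2 removed

    # -- chimeric loops -----------------------------------------------
    chimeric_loop_neighbor_factor: float = 2.0  # incident edge must exceed 2k

    # -- gap closing --------------------------------------------------
    l_ov: int = 8
    n_ov: int = 1
    n_min: int = 5
    l_ov_relaxed: int = 4  # negative pair-implied gaps retry with this floor

    # -- path extension -----------------------------------------------
    extension_c: float = 1.5
    theta: float = 1.0
    delta: float = 2.0
    omega: float = 10.0
    c_min: float = 2.0
    max_edge_multiplicity: int = 4

    # -- k selection --------------------------------------------------
    k_low_min: int = 29

    # -- strand handling ----------------------------------------------
    strand_split_ratio: float = 10.0
    strand_split_min_cov: float = 1.0

    # -- output filtration --------------------------------------------
    presets: dict = field(
        default_factory=lambda: {
            "soft": FiltrationPreset("soft", 0, 0.0, 0.5),
            "normal": FiltrationPreset("normal", 0, 1.0, 1.0),
            "hard": FiltrationPreset("hard", 200, 2.0, 2.0),
        }
    )

    def __post_init__(self) -> None:
        if self.extension_c <= 1:
            raise ValueError("extension_c must be > 1")
        if self.omega <= self.delta:
            raise ValueError("omega must exceed delta")
        for name in (
            "tip_short_len_factor", "tip_err_len_factor", "bulge_len_diff_max",
            "iso_edge_cov_max", "l_ov", "n_ov", "n_min", "delta", "omega",
            "c_min", "strand_split_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["presets"] = {k: asdict(v) for k, v in self.presets.items()}
        return d
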