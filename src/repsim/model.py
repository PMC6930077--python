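"""Core domain types shared by the simulator, extractor and statistics.

Coordinates are 0-based half-open everywhere; junction strings are stored
as sequence substrings (never coordinates) so no off-by-one can leak into
files.  The junction/CDR3 convention includes both the conserved V cysteine
codon and the conserved J phenylalanine/tryptophan codon of the [FW]GXG
motif, i.e. the AIRR "junction" definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class RepsimError(Exception):
    """Base class for package errors."""


class FormatError(RepsimError):
    """Malformed input file (missing column, bad value)."""


class ParameterError(RepsimError):
    """Invalid argument to an operation."""


class EmptyRepertoireError(ParameterError):
    """A statistic was requested on an empty repertoire."""


class GenerationError(RepsimError):
    """The simulator could not satisfy the requested junction geometry."""


@dataclass
class Rearrangement:
    """One sequenced TCR rearrangement.

    ``junction`` is the CDR3 nucleotide string including both anchor
    codons; ``junction_aa`` its translation when productive (empty
    otherwise).  ``duplicate_count`` is the read count supporting the
    rearrangement (>= 1).
    """

    sequence_id: str
    sequence: str
    v_call: str
    d_call: str
    j_call: str
    junction: str
    junction_aa: str
    productive: bool
    duplicate_count: int = 1
    locus: str = "TRB"
    sample_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ParameterError(
                f"duplicate_count must be >= 1, got {self.duplicate_count}"
            )


@dataclass
class Clonotype:
    """Collapsed clonal identity: V gene + CDR3 nucleotide sequence.

    ``count`` aggregates ``duplicate_count`` over member rearrangements.
    """

    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    count: int
    sample_id: str = ""
    tissue: str = ""
    locus: str = "TRB"


@dataclass(frozen=True)
class VSegment:
    """Germline V segment with the 0-based offset of its conserved Cys codon."""

    name: str
    sequence: str
    cys_anchor: int
    locus: str

    def __post_init__(self) -> None:
        codon = self.sequence[self.cys_anchor:self.cys_anchor + 3]
        if codon not in ("TGT", "TGC"):
            raise ParameterError(
                f"{self.name}: codon at cys_anchor is {codon!r}, expected TGT/TGC"
            )


@dataclass(frozen=True)
class JSegment:
    """Germline J segment with the 0-based offset of its conserved Phe/Trp codon.

    The anchor codon must begin a [FW]GXG motif: F/W followed in-frame by
    Gly, any residue, Gly.
    """

    name: str
    sequence: str
    phe_anchor: int
    locus: str

    def __post_init__(self) -> None:
        a = self.phe_anchor
        codon = self.sequence[a:a + 3]
        if codon not in ("TTT", "TTC", "TGG"):
            raise ParameterError(
                f"{self.name}: codon at phe_anchor is {codon!r}, expected TTT/TTC/TGG"
            )
        g1 = self.sequence[a + 3:a + 6]
        g2 = self.sequence[a + 9:a + 12]
        if not (g1.startswith("GG") and g2.startswith("GG")):
            raise ParameterError(
                f"{self.name}: [FW]GXG motif not satisfied after phe_anchor"
            )


@dataclass(frozen=True)
class GermlineReference:
    """V and J segments with CDR3 anchors, shared by simulator and extractor."""

    v_segments: dict[str, VSegment]
    j_segments: dict[str, JSegment]

    def v_names(self, locus: str | None = None) -> list[str]:
        return [n for n, s in self.v_segments.items()
                if locus is None or s.locus == locus]

    def j_names(self, locus: str | None = None) -> list[str]:
        return [n for n, s in self.j_segments.items()
                if locus is None or s.locus == locus]


@dataclass
class TissuePreset:
    """Generator parameters for one tissue.

    ``theta`` is the logarithmic-series parameter controlling clone sizes
    (larger theta = heavier tail = more clonal expansion);
    ``canonical_alpha_fraction`` the probability that an alpha clonotype is
    the canonical TRAV11-TRAJ18 rearrangement; ``nonproductive_rate`` the
    fraction of beta clonotypes generated out-of-frame or with a stop.
    """

    name: str
    trbv_probs: dict[str, float]
    trbj_probs: dict[str, float]
    theta: float
    canonical_alpha_fraction: float
    cdr3b_length_probs: dict[int, float]
    nonproductive_rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ParameterError(f"theta must be in (0,1), got {self.theta}")
        for label, probs in (("trbv_probs", self.trbv_probs),
                             ("trbj_probs", self.trbj_probs),
                             ("cdr3b_length_probs", self.cdr3b_length_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"{self.name}: {label} sums to {total}, expected 1"
                )
        if not 0.0 <= self.canonical_alpha_fraction <= 1.0:
            raise ParameterError("canonical_alpha_fraction must be in [0,1]")
        if not 0.0 <= self.nonproductive_rate <= 1.0:
            raise ParameterError("nonproductive_rate must be in [0,1]")


@dataclass
class GeneratorConfig:
    """Full configuration of one simulated repertoire."""

    preset: TissuePreset
    n_clonotypes: int
    seed: int
    samples_per_tissue: int = 4
    n_region_length_range: tuple[int, int] = (0, 18)
    canonical_cdr3a: str = "CVVGDRGSALGRLHF"

    def __post_init__(self) -> None:
        if self.n_clonotypes <= 0:
            raise ParameterError("n_clonotypes must be > 0")
        if not (self.canonical_cdr3a.startswith("C")
                and self.canonical_cdr3a.endswith("F")):
            raise ParameterError("canonical_cdr3a must start with C and end with F")


@dataclass
class RepertoireSummary:
    """Bundle of repertoire statistics for one scope (sample or pooled tissue)."""

    scope: str
    pooled: bool
    n_clonotypes: int
    total_count: int
    v_usage: dict[str, float] = field(default_factory=dict)
    j_usage: dict[str, float] = field(default_factory=dict)
    vj_pairing: dict[str, float] = field(default_factory=dict)
    size_classes: dict[str, float] = field(default_factory=dict)
    singleton_fraction: float = 0.0
    median_count: float = 0.0
    top_n_cumulative: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)
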