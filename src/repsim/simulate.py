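"""Synthetic iNKT repertoire generator.

Emulates the tissue-level statistical structure of mouse iNKT TCR
repertoires: a near-invariant alpha chain (canonical TRAV11-TRAJ18
junction at ~97% of alpha sequences), tissue-specific TRBV usage,
tissue-specific clonal expansion via a one-parameter logarithmic-series
clone-size model, a CDR3beta length spectrum with mode 14 aa, and a
configurable fraction of nonproductive (out-of-frame or stop-containing)
rearrangements to exercise downstream productivity filtering.

Clone sizes k = 1, 2, 3, ... follow the logarithmic series

    p_k = theta**k / (k * (-log(1 - theta))),   0 < theta < 1,

whose singleton fraction p_1 = theta / (-log(1-theta)) is a closed form
of theta.  Tissue presets are calibrated through that closed form:
theta = 0.60 gives p_1 ~ 0.655 (spleen/thymus), 0.80 gives ~ 0.497
(mesenteric LN), 0.90 gives ~ 0.391 (inguinal LN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CANONICAL_TRAV, CANONICAL_TRAJ
from .io import translate
from .model import (
    GenerationError,
    GeneratorConfig,
    GermlineReference,
    JSegment,
    ParameterError,
    Rearrangement,
    TissuePreset,
    VSegment,
)

_NT = np.array(list("ACGT"))

# TRBV vectors are configuration defaults reproducing the qualitative
# tissue ordering (TRBV13-2 depressed and "other" elevated in lymph
# nodes); they are not measured ground truth.
_TRBV_GENES = ("TRBV1", "TRBV13-1", "TRBV13-2", "TRBV13-3",
               "TRBV19", "TRBV29", "TRBVother")
_TRBV_BY_TISSUE = {
    "spleen": (0.05, 0.12, 0.35, 0.05, 0.08, 0.25, 0.10),
    "thymus": (0.04, 0.12, 0.38, 0.05, 0.07, 0.24, 0.10),
    "mLN":    (0.08, 0.10, 0.25, 0.05, 0.10, 0.27, 0.15),
    "iLN":    (0.10, 0.10, 0.20, 0.05, 0.10, 0.25, 0.20),
}
_THETA = {"thymus": 0.60, "spleen": 0.60, "mLN": 0.80, "iLN": 0.90}
_TRBJ_GENES = ("TRBJ1-1", "TRBJ2-5", "TRBJ2-7")
_LENGTH_PROBS = {11: 0.03, 12: 0.09, 13: 0.18, 14: 0.30,
                 15: 0.20, 16: 0.12, 17: 0.06, 18: 0.02}


def tissue_preset(name: str, *, nonproductive_rate: float = 0.10,
                  canonical_alpha_fraction: float = 0.97) -> TissuePreset:
    """Default preset for one of thymus / spleen / mLN / iLN."""
    if name not in _THETA:
        raise ParameterError(
            f"unknown tissue preset {name!r}; choose from {sorted(_THETA)}")
    return TissuePreset(
        name=name,
        trbv_probs=dict(zip(_TRBV_GENES, _TRBV_BY_TISSUE[name])),
        trbj_probs={g: 1.0 / len(_TRBJ_GENES) for g in _TRBJ_GENES},
        theta=_THETA[name],
        canonical_alpha_fraction=canonical_alpha_fraction,
        cdr3b_length_probs=dict(_LENGTH_PROBS),
        nonproductive_rate=nonproductive_rate,
    )


PRESET_NAMES = tuple(_THETA)


# -- clone-size model --------------------------------------------------------

def logseries_pmf(k: np.ndarray | int, theta: float) -> np.ndarray | float:
    """p_k = theta^k / (k * (-ln(1-theta))) for k >= 1."""
    k = np.asarray(k)
    return theta ** k / (k * (-math.log1p(-theta)))


def logseries_singleton_fraction(theta: float) -> float:
    """Closed-form p_1 = theta / (-ln(1-theta))."""
    return theta / (-math.log1p(-theta))


def logseries_mean(theta: float) -> float:
    """Closed-form mean theta / ((1-theta) * (-ln(1-theta)))."""
    return theta / ((1.0 - theta) * (-math.log1p(-theta)))


def sample_clone_sizes(theta: float, n_clonotypes: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. clone sizes from the log-series via inverse-CDF lookup.

    The CDF is tabulated until its tail mass falls below 1e-12; uniforms
    landing beyond the table (probability < 1e-12) are clamped to the
    last tabulated size.
    """
    if not 0.0 < theta < 1.0:
        raise ParameterError(f"theta must be in (0,1), got {theta}")
    if n_clonotypes < 0:
        raise ParameterError("n_clonotypes must be >= 0")
    # tail of the CDF shrinks geometrically (ratio theta): tabulate far enough
    k_max = max(8, int(math.ceil(math.log(1e-12) / math.log(theta))) + 8)
    pmf = logseries_pmf(np.arange(1, k_max + 1), theta)
    cdf = np.cumsum(pmf)
    u = rng.random(n_clonotypes)
    ks = np.searchsorted(cdf, u, side="right") + 1
    return np.minimum(ks, k_max).astype(np.int64)


# -- junction construction ---------------------------------------------------

@dataclass(frozen=True)
class JunctionDraw:
    """One simulated CDR3 junction plus its templated-segment bookkeeping."""

    junction: str
    junction_aa: str
    productive: bool
    v_keep: int  # nt of V kept, counted from the Cys codon inclusive
    j_keep: int  # nt of J kept, counted back from the Phe codon inclusive


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)]) if n else ""

_STOPS = ("TAA", "TAG", "TGA")


def generate_cdr3b_nt(v: VSegment, j: JSegment, target_aa_length: int,
                      rng: np.random.Generator,
                      force_nonproductive: bool = False,
                      n_region_length_range: tuple[int, int] = (0, 18),
                      ) -> JunctionDraw:
    """Build one junction: V-templated prefix from the Cys codon, an
    untemplated N region, and a J-templated suffix ending at the Phe codon.

    Productive draws have length ``3 * target_aa_length``, translate
    without stops, start with the V Cys and end with the J Phe.  With
    ``force_nonproductive`` the junction is spoiled either by a 1-2 nt
    N-region frameshift or by an in-frame interior stop codon (choice by
    ``rng``).  Exonucleolytic chewback of the templated ends is modelled
    by trimming ``v_keep``/``j_keep`` below the germline tail lengths.
    """
    v_tail = v.sequence[v.cys_anchor:]
    j_head = j.sequence[:j.phe_anchor + 3]
    tv, tj = len(v_tail), len(j_head)
    total = 3 * target_aa_length
    n_lo, n_hi = n_region_length_range
    n_min = max(n_lo, total - tv - tj)
    n_max = min(n_hi, total - 6)
    if n_min > n_max or total < 6:
        raise GenerationError(
            f"cannot build a {target_aa_length}-aa junction from "
            f"{v.name} (tail {tv} nt) and {j.name} (head {tj} nt) with "
            f"N region in {n_region_length_range}")
    for _ in range(200):
        n = int(rng.integers(n_min, n_max + 1))
        needed = total - n
        v_lo, v_hi = max(3, needed - tj), min(tv, needed - 3)
        v_keep = int(rng.integers(v_lo, v_hi + 1))
        j_keep = needed - v_keep
        junction = v_tail[:v_keep] + _random_nt(rng, n) + j_head[-j_keep:]
        aa = translate(junction)
        if "*" not in aa:
            break
    else:
        raise GenerationError(
            f"no stop-free junction found for {v.name}/{j.name} "
            f"at {target_aa_length} aa")
    if not force_nonproductive:
        return JunctionDraw(junction, aa, True, v_keep, j_keep)
    if rng.random() < 0.5:
        # frameshift: insert 1-2 nt at the V/N boundary
        ins = _random_nt(rng, int(rng.integers(1, 3)))
        junction = junction[:v_keep] + ins + junction[v_keep:]
        return JunctionDraw(junction, "", False, v_keep, j_keep)
    # in-frame stop replacing an interior codon (never the anchors)
    pos = 3 * int(rng.integers(1, target_aa_length - 1))
    stop = _STOPS[int(rng.integers(0, 3))]
    junction = junction[:pos] + stop + junction[pos + 3:]
    return JunctionDraw(junction, "", False, v_keep, j_keep)


def _read_from_junction(v: VSegment, j: JSegment, draw: JunctionDraw) -> str:
    """Full rearranged read: germline V through the junction into germline J."""
    return (v.sequence[:v.cys_anchor]
            + draw.junction
            + j.sequence[j.phe_anchor + 3:])


# -- repertoire assembly -----------------------------------------------------

def _choice(rng: np.random.Generator, items: list, probs: list[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


def generate_repertoire(config: GeneratorConfig,
                        reference: GermlineReference,
                        ) -> tuple[list[Rearrangement], pd.DataFrame]:
    """Simulate one tissue repertoire: beta clonotypes plus a parallel
    alpha record set, with ground truth.

    Each clonotype is emitted as one Rearrangement whose
    ``duplicate_count`` is its clone size (read counts).  Returns
    ``(records, truth)`` where ``truth`` has columns sequence_id,
    true_v_call, true_j_call, true_junction, true_productive.
    """
    preset = config.preset
    rng = np.random.default_rng(config.seed)
    n = config.n_clonotypes
    nrange = config.n_region_length_range

    trbv = list(preset.trbv_probs)
    trbv_p = list(preset.trbv_probs.values())
    trbj = list(preset.trbj_probs)
    trbj_p = list(preset.trbj_probs.values())
    lengths = list(preset.cdr3b_length_probs)
    length_p = list(preset.cdr3b_length_probs.values())

    trav = reference.v_names("TRA")
    traj = reference.j_names("TRA")
    vref, jref = reference.v_segments, reference.j_segments

    canon_v = vref[CANONICAL_TRAV]
    canon_j = jref[CANONICAL_TRAJ]
    canon_nt = _canonical_junction_nt(canon_v, canon_j, config.canonical_cdr3a)

    sizes_b = sample_clone_sizes(preset.theta, n, rng)
    sizes_a = sample_clone_sizes(preset.theta, n, rng)

    records: list[Rearrangement] = []
    truth_rows: list[dict] = []
    tissue = preset.name

    for i in range(n):
        sample = f"{tissue}{1 + int(rng.integers(config.samples_per_tissue))}"
        v = vref[_choice(rng, trbv, trbv_p)]
        j = jref[_choice(rng, trbj, trbj_p)]
        length = _choice(rng, lengths, length_p)
        nonprod = rng.random() < preset.nonproductive_rate
        draw = generate_cdr3b_nt(v, j, length, rng,
                                 force_nonproductive=nonprod,
                                 n_region_length_range=nrange)
        sid = f"{tissue}_TRB_{i:06d}"
        records.append(Rearrangement(
            sequence_id=sid, sequence=_read_from_junction(v, j, draw),
            v_call=v.name, d_call="", j_call=j.name,
            junction=draw.junction, junction_aa=draw.junction_aa,
            productive=draw.productive, duplicate_count=int(sizes_b[i]),
            locus="TRB", sample_id=sample, tissue=tissue))
        truth_rows.append({"sequence_id": sid, "true_v_call": v.name,
                           "true_j_call": j.name,
                           "true_junction": draw.junction,
                           "true_productive": draw.productive})

    for i in range(n):
        sample = f"{tissue}{1 + int(rng.integers(config.samples_per_tissue))}"
        if rng.random() < preset.canonical_alpha_fraction:
            v, j = canon_v, canon_j
            draw = JunctionDraw(canon_nt, config.canonical_cdr3a, True,
                                len(v.sequence) - v.cys_anchor,
                                j.phe_anchor + 3)
        else:
            v = vref[trav[int(rng.integers(len(trav)))]]
            j = jref[traj[int(rng.integers(len(traj)))]]
            length = _choice(rng, lengths, length_p)
            draw = generate_cdr3b_nt(v, j, length, rng,
                                     n_region_length_range=nrange)
        sid = f"{tissue}_TRA_{i:06d}"
        records.append(Rearrangement(
            sequence_id=sid, sequence=_read_from_junction(v, j, draw),
            v_call=v.name, d_call="", j_call=j.name,
            junction=draw.junction, junction_aa=draw.junction_aa,
            productive=draw.productive, duplicate_count=int(sizes_a[i]),
            locus="TRA", sample_id=sample, tissue=tissue))
        truth_rows.append({"sequence_id": sid, "true_v_call": v.name,
                           "true_j_call": j.name,
                           "true_junction": draw.junction,
                           "true_productive": draw.productive})

    return records, pd.DataFrame(truth_rows)


def _canonical_junction_nt(v: VSegment, j: JSegment, canonical_aa: str) -> str:
    """Fully templated nt encoding of the canonical alpha junction."""
    nt = v.sequence[v.cys_anchor:] + j.sequence[:j.phe_anchor + 3]
    aa = translate(nt)
    if aa != canonical_aa:
        raise GenerationError(
            f"germline {v.name}+{j.name} encodes {aa!r}, "
            f"not the configured canonical junction {canonical_aa!r}")
    return nt
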