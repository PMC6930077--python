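"""CDR3 physicochemical profiling: hydrophobicity, isoelectric point,
residue-class composition, length spectra and position frequency matrices.

Hydrophobicity is the mean Kyte-Doolittle value per residue (GRAVY); the
isoelectric point solves the Henderson-Hasselbalch charge balance with
the EMBOSS default pK set by bisection; residue classes follow the
polar / aliphatic / aromatic partition, with histidine counted in both
the polar and the aromatic class, so those fractions may sum above 1.

Ambiguous residues ('X') contribute zero hydrophobicity and no charge,
and are excluded from class-frequency denominators; each occurrence is
reported via a warning.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    AA_ALPHABET,
    ACIDIC_GROUPS,
    BASIC_GROUPS,
    EMBOSS_PK,
    KYTE_DOOLITTLE,
    RESIDUE_CLASSES,
)
from .model import ParameterError

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ParameterError("empty amino-acid sequence")
    bad = set(seq) - set(AA_ALPHABET) - {"X"}
    if bad:
        raise ParameterError(f"invalid amino-acid characters: {sorted(bad)}")
    if "X" in seq:
        warnings.warn("sequence contains ambiguous residue X; it carries "
                      "no hydrophobicity, charge or class membership",
                      stacklevel=3)
    return seq


def hydrophobicity(seq: str,
                   scale: Mapping[str, float] = KYTE_DOOLITTLE,
                   statistic: str = "mean") -> float:
    """Mean (default) or summed per-residue hydropathy of ``seq``.

    The mean is scale-free across lengths and is the reported per-sequence
    statistic; ``statistic='sum'`` gives the unnormalised total.
    """
    _check_sequence(seq)
    if statistic not in ("mean", "sum"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    values = [scale[aa] for aa in seq if aa != "X"]
    total = float(sum(values))
    if statistic == "sum":
        return total
    return total / len(seq) if values else 0.0


def net_charge(seq: str, ph: float,
               pk: Mapping[str, float] = EMBOSS_PK) -> float:
    """Net charge Q(pH) from the Henderson-Hasselbalch balance.

    Q is strictly decreasing in pH, so the isoelectric point (Q = 0) is
    unique.  Free termini always ionize; 'X' carries no charge.
    """
    counts = Counter(aa for aa in seq if aa != "X")
    q = 0.0
    for group in BASIC_GROUPS:
        n = 1 if group == "nterm" else counts.get(group, 0)
        if n:
            q += n / (1.0 + 10.0 ** (ph - pk[group]))
    for group in ACIDIC_GROUPS:
        n = 1 if group == "cterm" else counts.get(group, 0)
        if n:
            q -= n / (1.0 + 10.0 ** (pk[group] - ph))
    return q


def isoelectric_point(seq: str, pk: Mapping[str, float] = EMBOSS_PK,
                      tol: float = 1e-4) -> float:
    """pH in [0, 14] at which the peptide's net charge vanishes.

    Solved by bisection; Q is strictly decreasing so the root is unique.
    Iteration continues until the bracket is below 1e-6 pH, well inside
    the |Q| < ``tol`` acceptance band.  With both termini present a sign
    change on [0, 14] is guaranteed; if it were ever absent the nearer
    boundary is returned with a warning.
    """
    _check_sequence(seq)
    lo, hi = 0.0, 14.0
    q_lo, q_hi = net_charge(seq, lo, pk), net_charge(seq, hi, pk)
    if q_lo < 0 or q_hi > 0:  # pragma: no cover - impossible with termini
        warnings.warn("no sign change of Q on [0, 14]; returning boundary",
                      stacklevel=2)
        return lo if abs(q_lo) < abs(q_hi) else hi
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk) > 0:
            lo = mid
        else:
            hi = mid
    root = 0.5 * (lo + hi)
    if abs(net_charge(seq, root, pk)) > tol:  # pragma: no cover - flat tail
        warnings.warn("net charge at converged pH exceeds tolerance",
                      stacklevel=2)
    return root


def residue_class_frequencies(seq: str,
                              classes: Mapping[str, frozenset] = RESIDUE_CLASSES,
                              ) -> dict[str, float]:
    """Fraction of residues that are polar / aliphatic / aromatic.

    Denominator is the number of unambiguous residues; H counts toward
    both polar and aromatic, so the fractions may sum above 1.
    """
    _check_sequence(seq)
    counted = [aa for aa in seq if aa != "X"]
    if not counted:
        return {name: 0.0 for name in classes}
    n = len(counted)
    return {name: sum(aa in members for aa in counted) / n
            for name, members in classes.items()}


def length_distribution(sequences: Iterable[str],
                        ) -> tuple[dict[int, float], int]:
    """Amino-acid length spectrum and modal length.

    Returns (frequency map, mode); frequencies sum to 1 and ties for the
    mode resolve to the smallest length.
    """
    lengths = [len(s) for s in sequences]
    if not lengths:
        raise ParameterError("empty sequence set")
    counts = Counter(lengths)
    n = len(lengths)
    freqs = {length: counts[length] / n for length in sorted(counts)}
    peak = max(counts.values())
    mode = min(length for length, c in counts.items() if c == peak)
    return freqs, mode


def position_frequency_matrix(sequences: Iterable[str], fixed_length: int,
                              ) -> tuple[pd.DataFrame, np.ndarray, int]:
    """PFM and per-column information content over sequences of one length.

    Sequences of any other length are filtered out; the number kept is
    returned so downstream corrections stay recomputable.  Columns of the
    20 x L matrix are probability vectors; IC(column) = log2(20) - H in
    bits, with no small-sample correction applied.
    """
    if fixed_length < 1:
        raise ParameterError("fixed_length must be >= 1")
    kept = [s for s in sequences if len(s) == fixed_length and set(s) <= set(AA_ALPHABET)]
    if not kept:
        raise ParameterError(
            f"no sequence of length {fixed_length} in the input")
    counts = np.zeros((len(AA_ALPHABET), fixed_length), dtype=float)
    for s in kept:
        for pos, aa in enumerate(s):
            counts[_AA_INDEX[aa], pos] += 1
    pfm = counts / len(kept)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    entropy = -plogp.sum(axis=0)
    ic = math.log2(len(AA_ALPHABET)) - entropy
    matrix = pd.DataFrame(pfm, index=list(AA_ALPHABET),
                          columns=[f"pos{i + 1}" for i in range(fixed_length)])
    return matrix, ic, len(kept)


def consensus(pfm: pd.DataFrame) -> str:
    """Most frequent residue per column (ties by alphabetical order)."""
    return "".join(pfm.index[pfm[col].to_numpy().argmax()] for col in pfm.columns)


def property_table(sequences: Iterable[str]) -> pd.DataFrame:
    """Per-sequence property table: length, hydrophobicity, pI, class
    fractions.  The full table is reported so distribution-level group
    comparisons need no pre-chosen summary statistic."""
    rows = []
    for seq in sequences:
        classes = residue_class_frequencies(seq)
        rows.append({
            "junction_aa": seq,
            "length": len(seq),
            "hydrophobicity": hydrophobicity(seq),
            "isoelectric_point": isoelectric_point(seq),
            **{f"frac_{k}": v for k, v in classes.items()},
        })
    if not rows:
        raise ParameterError("empty sequence set")
    return pd.DataFrame(rows)
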