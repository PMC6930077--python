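"""Repertoire-level statistics: gene usage, V-J pairing, clonal structure.

All operations take assembled clonotype lists for one scope (one sample,
or one tissue pooled across samples).  Two weightings recur: *by-count*
(each sequence read counts once, i.e. clonotypes weighted by their
aggregate count) and *by-clonotype* (each distinct clonotype counts
once).  Gene-usage bar charts of sequences are by-count; clone-size
class distributions are by-clonotype.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np

from .model import Clonotype, EmptyRepertoireError, ParameterError, RepertoireSummary

SIZE_CLASS_LABELS = ("1", "2", "3", "4", ">=5")


def _require_nonempty(clonotypes: list[Clonotype]) -> None:
    if not clonotypes:
        raise EmptyRepertoireError("statistic requested on an empty repertoire")


def v_usage(clonotypes: list[Clonotype],
            weighting: str = "by-count") -> dict[str, float]:
    """Frequency of each V gene; sums to 1."""
    return _gene_usage(clonotypes, "v_call", weighting)


def j_usage(clonotypes: list[Clonotype],
            weighting: str = "by-count") -> dict[str, float]:
    """Frequency of each J gene; sums to 1."""
    return _gene_usage(clonotypes, "j_call", weighting)


def _gene_usage(clonotypes: list[Clonotype], attr: str,
                weighting: str) -> dict[str, float]:
    _require_nonempty(clonotypes)
    if weighting not in ("by-count", "by-clonotype"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    acc: Counter = Counter()
    for c in clonotypes:
        acc[getattr(c, attr)] += c.count if weighting == "by-count" else 1
    total = sum(acc.values())
    return {g: acc[g] / total for g in sorted(acc)}


def vj_pairing_matrix(clonotypes: list[Clonotype]) -> dict[tuple[str, str], float]:
    """Count-weighted percentage of sequences per (V, J) pair; sums to 100."""
    _require_nonempty(clonotypes)
    acc: Counter = Counter()
    for c in clonotypes:
        acc[(c.v_call, c.j_call)] += c.count
    total = sum(acc.values())
    return {pair: 100.0 * acc[pair] / total for pair in sorted(acc)}


def clone_size_distribution(clonotypes: list[Clonotype]) -> dict[str, float]:
    """Fractions of distinct clonotypes with count 1, 2, 3, 4, >=5."""
    _require_nonempty(clonotypes)
    n = len(clonotypes)
    bins = Counter()
    for c in clonotypes:
        bins[str(c.count) if c.count < 5 else ">=5"] += 1
    return {label: bins[label] / n for label in SIZE_CLASS_LABELS}


def singleton_fraction(clonotypes: list[Clonotype]) -> float:
    """Fraction of distinct clonotypes observed exactly once."""
    return clone_size_distribution(clonotypes)["1"]


def median_count(clonotypes: list[Clonotype]) -> float:
    """Median clone count (even n: mean of the two central order statistics)."""
    _require_nonempty(clonotypes)
    return float(np.median([c.count for c in clonotypes]))


def _prevalence_order(clonotypes: list[Clonotype]) -> list[Clonotype]:
    # deterministic: count desc, then aa asc, then nt asc
    return sorted(clonotypes, key=lambda c: (-c.count, c.cdr3_aa, c.cdr3_nt))


def top_n_cumulative(clonotypes: list[Clonotype], n: int = 25) -> float:
    """Cumulative frequency of the N most prevalent clonotypes.

    Returns 1.0 when the repertoire has fewer than N clonotypes.
    """
    _require_nonempty(clonotypes)
    if n < 1:
        raise ParameterError(f"N must be >= 1, got {n}")
    ranked = _prevalence_order(clonotypes)
    total = sum(c.count for c in ranked)
    return sum(c.count for c in ranked[:n]) / total


def top_clonotypes(clonotypes: list[Clonotype], n: int = 25) -> list[Clonotype]:
    """The N most prevalent clonotypes in deterministic prevalence order."""
    _require_nonempty(clonotypes)
    return _prevalence_order(clonotypes)[:n]


def rare_vs_abundant_usage(clonotypes: list[Clonotype],
                           threshold: int = 2,
                           ) -> tuple[dict[str, float], dict[str, float]]:
    """By-clonotype V usage among singletons vs clones with count >= threshold.

    Returns (rare_usage, abundant_usage); an empty stratum yields an empty
    map with a warning rather than an error.
    """
    _require_nonempty(clonotypes)
    if threshold < 2:
        raise ParameterError(f"abundance threshold must be >= 2, got {threshold}")
    rare = [c for c in clonotypes if c.count == 1]
    abundant = [c for c in clonotypes if c.count >= threshold]
    out = []
    for label, stratum in (("rare", rare), ("abundant", abundant)):
        if not stratum:
            warnings.warn(f"{label} stratum is empty", stacklevel=2)
            out.append({})
        else:
            out.append(v_usage(stratum, weighting="by-clonotype"))
    return out[0], out[1]


def summarize(clonotypes: list[Clonotype], scope: str = "",
              pooled: bool = False, top_n: tuple[int, ...] = (10, 25, 50),
              ) -> RepertoireSummary:
    """Full statistics bundle for one scope."""
    _require_nonempty(clonotypes)
    sizes = clone_size_distribution(clonotypes)
    n_clono = len(clonotypes)
    return RepertoireSummary(
        scope=scope, pooled=pooled,
        n_clonotypes=n_clono,
        total_count=sum(c.count for c in clonotypes),
        v_usage=v_usage(clonotypes),
        j_usage=j_usage(clonotypes),
        vj_pairing={f"{v}|{j}": p
                    for (v, j), p in vj_pairing_matrix(clonotypes).items()},
        size_classes=sizes,
        singleton_fraction=sizes["1"],
        median_count=median_count(clonotypes),
        top_n_cumulative={n: top_n_cumulative(clonotypes, n)
                          for n in top_n if n >= 1},
    )
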