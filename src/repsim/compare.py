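"""Group-comparison statistics used throughout the repertoire analyses.

The Mann-Whitney U test carries a bespoke exact mode: for pooled sample
sizes up to 14 the two-sided p value is computed by full enumeration of
all C(n_a + n_b, n_a) group assignments of the observed pooled values,
which remains correct in the presence of ties (where the classical exact
null tables do not apply).  Above the cutoff a tie-corrected normal
approximation with continuity correction is used.  t tests, one-way
ANOVA with Tukey's HSD, and Pearson correlation delegate to scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .model import ParameterError

EXACT_CUTOFF = 14


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | tuple[float, float] | None = None


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = sum over pairs of 1[a > b] + 0.5 * 1[a == b]."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(sample_a, sample_b, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: 'exact' enumerates all group assignments (requires
    n_a + n_b <= 14), 'normal' uses the tie-corrected normal
    approximation with continuity correction, 'auto' picks exact when
    the pooled size allows it.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ParameterError(f"unknown mode {mode!r}")
    n_a, n_b = a.size, b.size
    u = _u_statistic(a, b)
    if mode == "exact" and n_a + n_b > EXACT_CUTOFF:
        raise ParameterError(
            f"exact mode limited to n_a+n_b <= {EXACT_CUTOFF}")
    if mode == "auto":
        mode = "exact" if n_a + n_b <= EXACT_CUTOFF else "normal"
    if mode == "exact":
        p = _exact_two_sided_p(np.concatenate([a, b]), n_a, u)
        return TestResult(u, p, "mann-whitney exact enumeration")
    p = _normal_two_sided_p(a, b, u)
    return TestResult(u, p, "mann-whitney normal approximation")


def _exact_two_sided_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every assignment of the pooled
    values into groups of sizes (n_a, n_b).

    Extremeness is distance of U from its null mean n_a*n_b/2; the
    enumeration conditions on the observed values, so ties are handled
    exactly.
    """
    n = pooled.size
    n_b = n - n_a
    mean = n_a * n_b / 2.0
    obs_dev = abs(u_obs - mean)
    idx = np.arange(n)
    hits = 0
    total = 0
    for group_a in combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(group_a)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        # tolerate float half-counts from ties
        if abs(u - mean) >= obs_dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def _normal_two_sided_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    mean = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all values identical
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def t_test(sample_a, sample_b, paired: bool = False,
           equal_variance: bool = False) -> TestResult:
    """Two-sided Student/Welch t test (Welch is the unpaired default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ParameterError("paired test requires equal-length samples")
        if a.size < 2:
            raise ParameterError("paired test requires n >= 2")
        d = a - b
        if np.allclose(d, d[0]) and np.std(d) == 0 and d[0] == 0:
            return TestResult(0.0, 1.0, "paired t-test", df=a.size - 1)
        if np.std(d, ddof=1) == 0:
            raise ParameterError("degenerate paired test: zero-variance differences")
        res = sps.ttest_rel(a, b)
        return TestResult(float(res.statistic), float(res.pvalue),
                          "paired t-test", df=float(res.df))
    if a.size < 2 or b.size < 2:
        raise ParameterError("unpaired test requires n >= 2 per group")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        raise ParameterError("degenerate t-test: both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    method = "unpaired t-test" + ("" if equal_variance else " (Welch)")
    return TestResult(float(res.statistic), float(res.pvalue), method,
                      df=float(res.df))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    method: str
    tukey: dict[tuple[int, int], float] | None = None


def one_way_anova(groups, tukey: bool = False) -> AnovaResult:
    """One-way fixed-effects ANOVA, optionally with Tukey HSD pairwise
    p values from the studentized-range distribution."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("ANOVA requires >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    if all(np.std(a, ddof=1) == 0 for a in arrays) and np.std(pooled) == 0:
        raise ParameterError("degenerate ANOVA: zero within- and between-variance")
    if all(np.std(a, ddof=1) == 0 for a in arrays):
        raise ParameterError("degenerate ANOVA: zero within-group variance")
    f, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = pooled.size - len(arrays)
    pairwise = None
    method = "one-way ANOVA"
    if tukey:
        hsd = sps.tukey_hsd(*arrays)
        pairwise = {(i, j): float(hsd.pvalue[i, j])
                    for i in range(len(arrays))
                    for j in range(i + 1, len(arrays))}
        method += " + Tukey HSD (studentized range)"
    return AnovaResult(float(f), df1, df2, float(p), method, pairwise)


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided p from the
    t transform on n - 2 degrees of freedom."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ParameterError("pearson requires equal lengths >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ParameterError("pearson requires nonzero variance in both inputs")
    res = sps.pearsonr(xa, ya)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "pearson correlation", df=xa.size - 2)
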