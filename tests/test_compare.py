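"""Group-comparison statistics against enumeration and scipy oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from repsim.compare import (
    mann_whitney,
    one_way_anova,
    pearson,
    t_test,
)
from repsim.model import ParameterError


def _brute_force_two_sided_p(a, b):
    """Independent enumeration oracle using rank sums, not the package's
    pairwise-indicator U routine."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, len(a)
    ranks = sps.rankdata(pooled)
    mean = n_a * (n - n_a) / 2.0

    def u_from(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2.0

    obs = abs(u_from(range(n_a)) - mean)
    assignments = list(combinations(range(n), n_a))
    hits = sum(abs(u_from(idx) - mean) >= obs - 1e-9 for idx in assignments)
    return hits / len(assignments)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_give_central_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2
        assert res.p_value == pytest.approx(1.0)

    def test_u_conservation(self, rng):
        for _ in range(50):
            a = rng.integers(0, 6, size=int(rng.integers(2, 6)))
            b = rng.integers(0, 6, size=int(rng.integers(2, 6)))
            u_ab = mann_whitney(a, b).statistic
            u_ba = mann_whitney(b, a).statistic
            assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_equals_brute_force_enumeration(self, rng):
        """All random integer inputs with n_a + n_b <= 10, ties included."""
        for _ in range(60):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 11 - n_a))
            a = rng.integers(0, 5, size=n_a).astype(float)
            b = rng.integers(0, 5, size=n_b).astype(float)
            res = mann_whitney(a, b, mode="exact")
            assert res.p_value == pytest.approx(_brute_force_two_sided_p(a, b))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            pooled = rng.permutation(12)[:9].astype(float)
            a, b = pooled[:4], pooled[4:]
            res = mann_whitney(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_vs_normal_agreement_at_7_plus_7(self, rng):
        for _ in range(20):
            a = rng.normal(size=7)
            b = rng.normal(size=7)
            exact = mann_whitney(a, b, mode="exact").p_value
            approx = mann_whitney(a, b, mode="normal").p_value
            assert abs(exact - approx) < 0.02

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])
        with pytest.raises(ParameterError):
            mann_whitney(np.arange(10), np.arange(10), mode="exact")


class TestTTest:
    def test_paired_identical_vectors(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_variance_flagged(self):
        with pytest.raises(ParameterError):
            t_test([0, 0, 0, 0], [1, 1, 1, 1])

    def test_matches_scipy_welch(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(loc=0.5, size=12)
        res = t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_p_matches_t_density_integration(self, rng):
        """Two-sided p equals the numerically integrated t-density tail."""
        from scipy.integrate import quad
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        res = t_test(a, b)
        df = res.df
        tail, _ = quad(lambda x: sps.t.pdf(x, df), abs(res.statistic),
                       np.inf)
        assert res.p_value == pytest.approx(2 * tail, abs=1e-6)

    def test_length_mismatch_in_paired_mode(self):
        with pytest.raises(ParameterError):
            t_test([1, 2, 3], [1, 2], paired=True)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=9)
        f = one_way_anova([a, b]).f_statistic
        t = t_test(a, b, equal_variance=True).statistic
        assert f == pytest.approx(t ** 2)

    def test_identical_constant_groups_flagged_degenerate(self):
        with pytest.raises(ParameterError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_tukey_pairwise_present_and_bounded(self, rng):
        groups = [rng.normal(loc=m, size=6) for m in (0, 0, 2)]
        res = one_way_anova(groups, tukey=True)
        assert set(res.tukey) == {(0, 1), (0, 2), (1, 2)}
        assert all(0 <= p <= 1 for p in res.tukey.values())
        # the separated pair should be the most significant
        assert res.tukey[(0, 2)] <= res.tukey[(0, 1)]

    def test_type_one_error_calibrated(self, rng):
        """Three null groups, 10,000 replicates: rejection rate at
        alpha = 0.05 lies in [0.045, 0.055]."""
        reps, k, n = 10_000, 3, 5
        data = rng.normal(size=(reps, k, n))
        gm = data.mean(axis=2)
        grand = data.mean(axis=(1, 2))
        ss_between = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ss_within = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        f = (ss_between / (k - 1)) / (ss_within / (k * (n - 1)))
        pvals = sps.f.sf(f, k - 1, k * (n - 1))
        rate = (pvals < 0.05).mean()
        assert 0.045 <= rate <= 0.055
        # the vectorised null F above is the same statistic the package
        # computes: spot-check one replicate
        res = one_way_anova(list(data[0]))
        assert res.f_statistic == pytest.approx(float(f[0]))
        assert res.p_value == pytest.approx(float(pvals[0]))


class TestPearson:
    def test_exact_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert pearson([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ParameterError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_null_p_values_uniform(self, rng):
        """Independent bivariate-normal draws: p values follow U(0,1)
        (KS p > 0.01 over 10,000 replicates of n = 20)."""
        reps, n = 10_000, 20
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        pvals = 2 * sps.t.sf(np.abs(t), n - 2)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        # spot-check against the package implementation
        res = pearson(x[0], y[0])
        assert res.statistic == pytest.approx(float(r[0]))
        assert res.p_value == pytest.approx(float(pvals[0]))
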