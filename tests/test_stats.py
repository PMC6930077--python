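"""Repertoire statistics: usage, pairing, clonal structure."""

import math

import numpy as np
import pytest

from repsim.extract import assemble_clonotypes
from repsim.model import Clonotype, EmptyRepertoireError, ParameterError
from repsim.simulate import sample_clone_sizes, logseries_singleton_fraction
from repsim.stats import (
    clone_size_distribution,
    median_count,
    rare_vs_abundant_usage,
    summarize,
    top_n_cumulative,
    v_usage,
    vj_pairing_matrix,
)


def _clone(v="TRBV1", j="TRBJ1-1", nt="TGTAAATTT", aa="CKF", count=1):
    return Clonotype(v_call=v, j_call=j, cdr3_nt=nt, cdr3_aa=aa, count=count)


class TestUsage:
    def test_by_count_weighting(self):
        clones = [_clone(v="TRBV29", count=5), _clone(v="TRBV13-2", count=5)]
        assert v_usage(clones) == {"TRBV13-2": 0.5, "TRBV29": 0.5}

    def test_single_gene_normalises_to_one(self):
        assert v_usage([_clone(count=7)]) == {"TRBV1": 1.0}

    def test_weightings_differ_when_counts_skew(self):
        clones = [_clone(v="TRBV29", count=9), _clone(v="TRBV1", count=1)]
        assert v_usage(clones, "by-count")["TRBV29"] == 0.9
        assert v_usage(clones, "by-clonotype")["TRBV29"] == 0.5

    def test_empty_input_raises(self):
        with pytest.raises(EmptyRepertoireError):
            v_usage([])


class TestPairing:
    def test_percentages(self):
        clones = [_clone(v="TRBV29", j="TRBJ2-7", count=2),
                  _clone(v="TRBV1", j="TRBJ1-1", count=1),
                  _clone(v="TRBV1", j="TRBJ2-5", count=1)]
        matrix = vj_pairing_matrix(clones)
        assert matrix[("TRBV29", "TRBJ2-7")] == 50.0
        assert sum(matrix.values()) == pytest.approx(100.0)

    def test_single_clonotype_is_100(self):
        assert list(vj_pairing_matrix([_clone()]).values()) == [100.0]

    def test_marginal_over_j_equals_count_weighted_v_usage(self, rng):
        clones = [_clone(v=f"TRBV{rng.integers(1, 5)}",
                         j=f"TRBJ{rng.integers(1, 4)}-1",
                         nt=str(i), count=int(rng.integers(1, 9)))
                  for i in range(60)]
        matrix = vj_pairing_matrix(clones)
        usage = v_usage(clones, "by-count")
        for gene, freq in usage.items():
            marginal = sum(p for (v, _), p in matrix.items() if v == gene)
            assert marginal == pytest.approx(100.0 * freq)


class TestCloneSizes:
    def test_size_classes(self):
        clones = [_clone(nt=str(i), count=c)
                  for i, c in enumerate([1, 1, 2, 3, 5, 7])]
        dist = clone_size_distribution(clones)
        assert dist == {"1": 2 / 6, "2": 1 / 6, "3": 1 / 6, "4": 0.0,
                        ">=5": 2 / 6}
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_all_singletons(self):
        clones = [_clone(nt=str(i)) for i in range(5)]
        assert clone_size_distribution(clones)["1"] == 1.0

    @pytest.mark.parametrize("tissue_theta", [0.60, 0.80, 0.90])
    def test_singleton_fraction_recovers_theta(self, tissue_theta, rng):
        """Sampled clone sizes at n = 20,000 recover the closed-form
        singleton fraction of the preset theta within 3 binomial SE."""
        sizes = sample_clone_sizes(tissue_theta, 20_000, rng)
        clones = [_clone(nt=str(i), count=int(c))
                  for i, c in enumerate(sizes)]
        p1 = logseries_singleton_fraction(tissue_theta)
        se = math.sqrt(p1 * (1 - p1) / 20_000)
        assert abs(clone_size_distribution(clones)["1"] - p1) < 3 * se


class TestMedianAndTopN:
    def test_median_examples(self):
        assert median_count([_clone(nt=str(i), count=c)
                             for i, c in enumerate([1, 1, 2])]) == 1
        assert median_count([_clone(nt=str(i), count=c)
                             for i, c in enumerate([1, 2, 3, 10])]) == 2.5

    def test_top_n_examples(self):
        clones = [_clone(nt=str(i), count=c)
                  for i, c in enumerate([5, 3, 2])]
        assert top_n_cumulative(clones, 2) == pytest.approx(0.8)
        assert top_n_cumulative(clones, 10) == 1.0
        with pytest.raises(ParameterError):
            top_n_cumulative(clones, 0)

    def test_top_n_monotone_nondecreasing(self, rng):
        clones = [_clone(nt=str(i), count=int(c))
                  for i, c in enumerate(rng.integers(1, 40, size=80))]
        values = [top_n_cumulative(clones, n) for n in range(1, 81)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0)

    def test_expansion_ordering_iln_exceeds_spleen(self, rng):
        """Heavier-tailed clone sizes (iLN theta) concentrate more mass in
        the top 25 and raise the median relative to the spleen theta."""
        spleen = [_clone(nt=str(i), count=int(c)) for i, c in
                  enumerate(sample_clone_sizes(0.60, 20_000, rng))]
        iln = [_clone(nt=str(i), count=int(c)) for i, c in
               enumerate(sample_clone_sizes(0.90, 20_000, rng))]
        assert top_n_cumulative(iln, 25) > top_n_cumulative(spleen, 25)
        assert median_count(iln) >= median_count(spleen)


class TestRareVsAbundant:
    def test_threshold_strata(self):
        clones = [_clone(v="TRBV29", nt="a", count=1),
                  _clone(v="TRBV29", nt="b", count=3),
                  _clone(v="TRBV13-2", nt="c", count=1)]
        rare, abundant = rare_vs_abundant_usage(clones, threshold=2)
        assert rare == {"TRBV13-2": 0.5, "TRBV29": 0.5}
        assert abundant == {"TRBV29": 1.0}

    def test_all_singletons_gives_empty_abundant_with_warning(self):
        clones = [_clone(nt=str(i)) for i in range(4)]
        with pytest.warns(UserWarning, match="abundant"):
            _, abundant = rare_vs_abundant_usage(clones)
        assert abundant == {}

    def test_planted_v_biased_expansion_recovered(self, rng):
        """Expanded clones forced to TRBV29 show elevated TRBV29 usage in
        the abundant stratum relative to the rare stratum."""
        genes = ["TRBV1", "TRBV13-2", "TRBV19", "TRBV29"]
        clones = []
        for i in range(2000):
            expanded = rng.random() < 0.3
            gene = "TRBV29" if expanded else genes[int(rng.integers(4))]
            count = int(rng.integers(2, 30)) if expanded else 1
            clones.append(_clone(v=gene, nt=str(i), count=count))
        rare, abundant = rare_vs_abundant_usage(clones, threshold=2)
        assert abundant["TRBV29"] > rare["TRBV29"]
        assert abundant["TRBV29"] > 0.8


class TestSummaryInvariants:
    def test_conservation_and_permutation_invariance(self, rng,
                                                     small_repertoire):
        records, _ = small_repertoire
        trb = [r for r in records if r.locus == "TRB"]
        clones = assemble_clonotypes(trb, scope="pooled")
        s = summarize(clones, scope="spleen", pooled=True)
        assert sum(s.v_usage.values()) == pytest.approx(1.0)
        assert sum(s.j_usage.values()) == pytest.approx(1.0)
        assert sum(s.size_classes.values()) == pytest.approx(1.0)
        assert sum(s.vj_pairing.values()) == pytest.approx(100.0)
        shuffled = list(clones)
        rng.shuffle(shuffled)
        s2 = summarize(shuffled, scope="spleen", pooled=True)
        assert s2.to_dict() == s.to_dict()
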