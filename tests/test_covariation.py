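"""Covariation statistics: correlations, decomposition, variability index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meiocovar import (
    GroupPartition,
    balanced_partitions,
    grouped_correlation,
    odd_even_partition,
    partition_sweep,
    pearson,
    per_chromosome_cv,
    variability_index,
    variance_decomposition,
)
from meiocovar.covariation import _excess_fractions, n_balanced_partitions
from meiocovar.errors import (
    ConfigurationError,
    UndefinedCorrelationError,
    ValidationError,
)

from conftest import make_matrix


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_formula(self):
        # cov = 1.0, sd_x = sd_y = sqrt(1.25) -> r = 1.0 / 1.25 = 0.8
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 2], [3, 4])


class TestGroupedCorrelation:
    def test_identical_group_sums(self):
        m = make_matrix([[1, 1], [2, 2], [3, 3], [1, 1]])
        p = GroupPartition(("chr1",), ("chr2",))
        assert grouped_correlation(m, p) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        counts = rng.poisson(3.0, size=(2000, 8))
        m = make_matrix(counts)
        p = odd_even_partition(m.chromosome_ids)
        assert abs(grouped_correlation(m, p)) < 0.05

    def test_symmetric_and_reorder_invariant(self, male_small, rng):
        p = odd_even_partition(male_small.chromosome_ids)
        r1 = grouped_correlation(male_small, p)
        r2 = grouped_correlation(male_small,
                                 GroupPartition(p.group_b, p.group_a))
        shuffled = make_matrix(
            male_small.co_counts.to_numpy()[rng.permutation(male_small.n_nuclei)],
            columns=male_small.chromosome_ids)
        r3 = grouped_correlation(shuffled, p)
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_odd_even_parses_trailing_numbers(self):
        p = odd_even_partition(["chr1", "chr2", "chr3", "chr10"])
        assert set(p.group_a) == {"chr1", "chr3"}
        assert set(p.group_b) == {"chr2", "chr10"}

    def test_odd_even_unparseable_fails(self):
        with pytest.raises(ConfigurationError):
            odd_even_partition(["alpha", "beta"])


class TestPartitions:
    def test_four_chromosomes_three_partitions(self):
        parts = list(balanced_partitions(["a", "b", "c", "d"]))
        assert len(parts) == 3 == n_balanced_partitions(4)
        assert len({p.canonical() for p in parts}) == 3

    def test_two_chromosomes_single_partition_zero_se(self):
        m = make_matrix([[1, 2], [2, 3], [3, 5], [0, 1]])
        res = partition_sweep(m)
        assert res.n_partitions == 1
        assert res.se == 0.0

    def test_sampling_matches_enumeration_scale(self, male_small):
        full = partition_sweep(male_small, max_partitions=10_000, seed=0)
        sampled = partition_sweep(male_small, max_partitions=150, seed=1,
                                  full_enumeration_limit=4)
        assert not sampled.enumerated
        assert sampled.mean_r == pytest.approx(full.mean_r, abs=0.02)

    def test_unbalanced_partition_rejected(self):
        with pytest.raises(ValidationError):
            GroupPartition(("a", "b", "c"), ("d",))


class TestVarianceDecomposition:
    def test_single_chromosome_zero_covariance(self):
        m = make_matrix([[1], [2], [4], [3]])
        s = variance_decomposition(m)
        assert s.covariance == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_columns_analytic(self):
        col = np.array([1, 2, 3, 4, 2])
        v = col.var(ddof=0)
        m = make_matrix(np.column_stack([col, col]))
        s = variance_decomposition(m)
        assert s.total_variance == pytest.approx(4 * v)
        assert s.intrinsic_variance == pytest.approx(2 * v)
        assert s.covariance == pytest.approx(2 * v)
        assert s.covariance_contribution == pytest.approx(0.5)

    def test_covariance_equals_offdiagonal_sum(self, rng):
        """Brute-force oracle: covariance term = sum of off-diagonal
        pairwise chromosome covariances."""
        for _ in range(20):
            counts = rng.poisson(2.5, size=(30, 6))
            m = make_matrix(counts)
            s = variance_decomposition(m)
            cmat = np.cov(counts.T, ddof=0)
            off = cmat.sum() - np.trace(cmat)
            assert s.covariance == pytest.approx(off, rel=1e-9, abs=1e-9)

    def test_single_nucleus_rejected(self):
        with pytest.raises(ValidationError):
            variance_decomposition(make_matrix([[1, 2]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.5, 6.0), size=(rng.integers(2, 40),
                                                          rng.integers(1, 12)))
        s = variance_decomposition(make_matrix(counts))
        assert s.total_variance == pytest.approx(
            s.intrinsic_variance + s.covariance, rel=1e-9, abs=1e-9)
        if s.total_variance > 0:
            assert s.covariance_contribution * s.total_variance == \
                pytest.approx(s.covariance, rel=1e-9, abs=1e-9)


class TestPerChromosomeCV:
    def test_constant_column_zero(self):
        m = make_matrix([[2, 1], [2, 3], [2, 2]])
        assert per_chromosome_cv(m)["chr1"] == 0.0

    def test_hand_formula(self):
        m = make_matrix([[2], [4]])
        # population sd = 1, mean = 3
        assert per_chromosome_cv(m)["chr1"] == pytest.approx(1 / 3)

    def test_scale_invariance(self):
        m1 = make_matrix([[2, 1], [4, 3], [3, 2]])
        m2 = make_matrix([[6, 1], [12, 3], [9, 2]])
        assert per_chromosome_cv(m1)["chr1"] == pytest.approx(
            per_chromosome_cv(m2)["chr1"])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            per_chromosome_cv(make_matrix([[0, 1], [0, 2]]))


class TestVariabilityIndex:
    def test_identical_fits_zero(self):
        hypo, hyper = _excess_fractions((50.0, 5.0), (50.0, 5.0))
        assert hypo == hyper == 0.0

    def test_quadrature_oracle(self):
        """Tail excess of N(50, 8^2) over N(50, 5^2) matches numeric
        quadrature of max(f_data - f_null, 0) at step 1e-3."""
        hypo, hyper = _excess_fractions((50.0, 8.0), (50.0, 5.0))
        t = np.arange(0.0, 100.0, 1e-3)
        diff = stats.norm.pdf(t, 50, 8) - stats.norm.pdf(t, 50, 5)
        upper = t > 50
        hyper_quad = np.trapezoid(np.maximum(diff, 0)[upper], t[upper])
        hypo_quad = np.trapezoid(np.maximum(diff, 0)[~upper], t[~upper])
        assert hyper == pytest.approx(hyper_quad, abs=1e-4)
        assert hypo == pytest.approx(hypo_quad, abs=1e-4)

    def test_independent_matrix_near_zero(self, rng):
        counts = rng.poisson(2.3, size=(5000, 22))
        vi = variability_index(make_matrix(counts))
        assert vi.index < 0.02

    def test_covariation_raises_index(self, male_small):
        vi = variability_index(male_small)
        assert vi.index > 0.1
        assert vi.index == pytest.approx(vi.hyper_fraction + vi.hypo_fraction)

    def test_permutation_null_approaches_analytic(self, male_small):
        ana = variability_index(male_small, null_mode="analytic")
        perm = variability_index(male_small, null_mode="permutation",
                                 n_null=200, seed=0)
        assert perm.index == pytest.approx(ana.index, abs=0.03)

    def test_narrower_data_than_null_splits_at_mean(self):
        hypo, hyper = _excess_fractions((50.0, 4.0), (50.0, 6.0))
        assert hypo > 0 and hyper > 0
        assert hypo == pytest.approx(hyper, rel=1e-9)
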