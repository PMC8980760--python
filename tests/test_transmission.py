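"""Gamete prediction under no chromatid interference; variance relations."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from meiocovar import (
    add_type2_cos,
    apply_maturation,
    gamete_variance_prediction,
    partition_sweep,
    predict_gametes,
    variance_decomposition,
)
from meiocovar.errors import ConfigurationError

from conftest import make_matrix

# the four non-sister chromatid pairings of a bivalent (a,b | c,d)
PAIRINGS = [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]


def chromatid_count_distribution(k: int, chromatid: str = "a"):
    """Exhaustive enumeration oracle: distribution of the number of COs a
    single chromatid carries when each of k COs picks one of the 4
    non-sister pairings uniformly."""
    counts = {}
    for assignment in product(range(4), repeat=k):
        c = sum(1 for a in assignment if chromatid in PAIRINGS[a])
        counts[c] = counts.get(c, 0) + 1
    total = 4**k
    return {c: n / total for c, n in counts.items()}


class TestBinomialTransmission:
    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4, 5])
    def test_enumeration_matches_binomial(self, k):
        dist = chromatid_count_distribution(k)
        for c in range(k + 1):
            assert dist.get(c, 0.0) == pytest.approx(
                stats.binom.pmf(c, k, 0.5), abs=1e-12)

    def test_k2_distribution(self, rng):
        m = make_matrix(np.full((10_000, 1), 2))
        g = predict_gametes(m, seed=rng).matrix.co_counts.to_numpy().ravel()
        freqs = np.bincount(g, minlength=3) / g.size
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_mean_gamete_total_is_half(self, male_small):
        # stack replicated gamete draws to reach 10,000 gametes
        reps = 10_000 // male_small.n_nuclei + 1
        totals = np.concatenate([
            predict_gametes(male_small, seed=s).matrix.totals()
            for s in range(reps)
        ])[:10_000]
        X = male_small.totals().mean()
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - X / 2) < 3 * se

    def test_mode4_sisters_sum_to_2k(self, male_small):
        gs = predict_gametes(male_small, gametes_per_meiocyte=4, seed=0)
        arr = gs.matrix.co_counts.to_numpy()
        quads = arr.reshape(male_small.n_nuclei, 4, -1)
        assert (quads.sum(axis=1)
                == 2 * male_small.co_counts.to_numpy()).all()

    def test_mode4_marginal_binomial(self, rng):
        m = make_matrix(np.full((4000, 1), 3))
        gs = predict_gametes(m, gametes_per_meiocyte=4, seed=rng)
        first = gs.matrix.co_counts.to_numpy().reshape(4000, 4)[:, 0]
        freqs = np.bincount(first, minlength=4) / 4000
        expected = stats.binom.pmf(np.arange(4), 3, 0.5)
        assert freqs == pytest.approx(expected, abs=0.03)

    def test_invalid_mode_rejected(self, male_small):
        with pytest.raises(ConfigurationError):
            predict_gametes(male_small, gametes_per_meiocyte=2)


class TestVariancePrediction:
    def test_direct_substitution(self):
        from meiocovar.covariation import CovariationSummary

        s = CovariationSummary(32.0, 20.0, 12.0, 12.0 / 32.0, 50.0,
                               np.sqrt(32.0) / 50.0, {})
        pred = gamete_variance_prediction(s)
        assert pred.predicted_total_variance_g == pytest.approx(20.5)
        assert pred.predicted_contribution_ratio == pytest.approx(2.5625)
        # X/total = 1/(X * CV^2)
        assert pred.reduction_term == pytest.approx(
            1.0 / (s.mean_total * s.cv_total**2))

    def test_simulation_matches_closed_form(self, male_small):
        """Empirical gamete total variance and contribution ratio match the
        closed forms within 3 SE over replicates."""
        s = variance_decomposition(male_small)
        pred = gamete_variance_prediction(s)
        tv, ratio = [], []
        for seed in range(20):
            g = predict_gametes(male_small, seed=seed).matrix
            gs = variance_decomposition(g)
            tv.append(gs.total_variance)
            ratio.append(s.covariance_contribution / gs.covariance_contribution)
        tv, ratio = np.array(tv), np.array(ratio)
        se_tv = tv.std(ddof=1) / np.sqrt(tv.size)
        se_ratio = ratio.std(ddof=1) / np.sqrt(ratio.size)
        assert abs(tv.mean() - pred.predicted_total_variance_g) < 3 * se_tv
        assert abs(ratio.mean() - pred.predicted_contribution_ratio) \
            < 3 * se_ratio

    def test_higher_co_count_preserves_more_correlation(self):
        """At matched meiocyte correlation, the regime with more COs per
        nucleus retains a higher gamete correlation (the binomial sampling
        term X/4 weighs less against the covariance)."""
        from meiocovar import female_like_config, generate, male_like_config

        male = generate(male_like_config(1500, seed=1, rho=0.65))
        female = generate(female_like_config(1500, seed=2, rho=0.65))
        def gamete_r(m):
            return np.mean([
                partition_sweep(predict_gametes(m, seed=s).matrix,
                                max_partitions=40, seed=s).mean_r
                for s in range(10)
            ])
        assert gamete_r(female) > gamete_r(male)

    def test_gamete_correlation_lower_than_meiocyte(self, male_small):
        r_m = partition_sweep(male_small, max_partitions=50, seed=0).mean_r
        r_g = np.mean([
            partition_sweep(predict_gametes(male_small, seed=s).matrix,
                            max_partitions=50, seed=s).mean_r
            for s in range(10)
        ])
        assert r_g < r_m


class TestAugmentationAndMaturation:
    def test_type2_fraction_zero_identity(self, male_small):
        assert add_type2_cos(male_small, 0.0) == male_small

    def test_type2_raises_totals_by_fraction(self, male_small):
        incs = []
        for seed in range(15):
            aug = add_type2_cos(male_small, 0.10, seed=seed)
            incs.append(aug.totals().mean() / male_small.totals().mean() - 1)
        incs = np.array(incs)
        se = incs.std(ddof=1) / np.sqrt(incs.size)
        assert abs(incs.mean() - 0.10) < 3 * se + 1e-3

    def test_type2_lowers_correlation(self, male_small):
        r0 = partition_sweep(male_small, max_partitions=50, seed=0).mean_r
        r1 = np.mean([
            partition_sweep(add_type2_cos(male_small, 0.10, seed=s),
                            max_partitions=50, seed=s).mean_r
            for s in range(10)
        ])
        assert r1 <= r0

    def test_maturation_identity(self, male_small):
        assert apply_maturation(male_small, 1.0) == male_small

    def test_maturation_halves_mean(self, male_small):
        totals = np.concatenate([
            apply_maturation(male_small, 0.5, seed=s).totals()
            for s in range(13)
        ])
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - male_small.totals().mean() / 2) < 3 * se

    def test_maturation_lowers_correlation(self, male_small):
        r0 = partition_sweep(male_small, max_partitions=50, seed=0).mean_r
        r1 = np.mean([
            partition_sweep(apply_maturation(male_small, 0.6, seed=s),
                            max_partitions=50, seed=s).mean_r
            for s in range(10)
        ])
        assert r1 < r0

    def test_invalid_parameters_rejected(self, male_small):
        with pytest.raises(ConfigurationError):
            add_type2_cos(male_small, -0.1)
        with pytest.raises(ConfigurationError):
            apply_maturation(male_small, 0.0)
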