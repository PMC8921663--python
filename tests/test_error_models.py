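from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from ampdiv import (
    CountVector,
    DispersionModel,
    RecoveryProfile,
    amplify,
    binomial_compat_test,
    cluster_counts,
    condition_on_library,
    simulate_counts,
    thin,
)


def cv(*counts):
    return CountVector(tuple(f"v{i}" for i in range(len(counts))), np.array(counts))


def exact_urn_pmf(start_n=4, target_n=6, p1=Fraction(2, 3)):
    """Exhaustive enumeration: start X ~ Binomial(start_n, p1), then add
    copies one at a time with probability proportional to current counts
    until the total reaches target_n. Exact rational arithmetic."""
    pmf = {}
    for x in range(start_n + 1):
        px = comb(start_n, x) * p1**x * (1 - p1) ** (start_n - x)
        states = {(x, start_n - x): px}
        for _ in range(target_n - start_n):
            nxt = {}
            for (a, b), pr in states.items():
                t = a + b
                if a:
                    nxt[(a + 1, b)] = nxt.get((a + 1, b), 0) + pr * Fraction(a, t)
                if b:
                    nxt[(a, b + 1)] = nxt.get((a, b + 1), 0) + pr * Fraction(b, t)
            states = nxt
        for (a, _b), pr in states.items():
            pmf[a] = pmf.get(a, 0) + pr
    return np.array([float(pmf.get(k, 0)) for k in range(target_n + 1)])


class TestSimulateCounts:
    def test_poisson_mean_ratio_and_variance(self):
        model = DispersionModel("poisson", np.array([4.0, 2.0]))
        x = simulate_counts(model, 20000, seed=0)
        means = x.mean(axis=0)
        assert means[0] / means[1] == pytest.approx(2.0, rel=0.05)
        # Poisson identity: variance == mean
        np.testing.assert_allclose(x.var(axis=0), means, rtol=0.06)

    def test_negative_binomial_overdispersed(self):
        model = DispersionModel("negative_binomial", np.array([4.0, 2.0]), 1.0)
        x = simulate_counts(model, 20000, seed=1)
        assert np.all(x.var(axis=0) > x.mean(axis=0) * 1.5)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DispersionModel("poisson", np.array([0.0]))
        with pytest.raises(ValueError):
            DispersionModel("negative_binomial", np.array([1.0]))  # missing k
        with pytest.raises(ValueError):
            DispersionModel("gamma", np.array([1.0]))


class TestConditionOnLibrary:
    def test_retains_matching_totals(self):
        counts = np.array([[1, 2], [2, 2], [1, 3], [4, 1]])
        kept = condition_on_library(counts, 4)
        assert kept.shape[0] == 2
        assert np.all(kept.sum(axis=1) == 4)

    def test_empty_result_warns_not_raises(self):
        with pytest.warns(UserWarning, match="no replicates"):
            out = condition_on_library(np.array([[1, 1]]), 99)
        assert out.shape == (0, 2)

    def test_conditioned_poisson_is_binomial(self):
        """Poisson (2-to-1 means) conditioned on total N is exactly
        Binomial(N, 2/3); the compatibility test should not reject."""
        model = DispersionModel("poisson", np.array([4.0, 2.0]))
        x = simulate_counts(model, 60000, seed=2)
        kept = condition_on_library(x, 6)
        assert kept.shape[0] > 5000
        res = binomial_compat_test(kept[:, 0], n=6, p=2 / 3)
        assert res.p_value > 0.005  # non-rejection beyond type-I chance

    def test_conditioned_negative_binomial_is_not_binomial(self):
        model = DispersionModel("negative_binomial", np.array([4.0, 2.0]), 1.0)
        x = simulate_counts(model, 120000, seed=3)
        kept = condition_on_library(x, 6)
        res = binomial_compat_test(kept[:, 0], n=6, p=2 / 3)
        assert res.reject


class TestAmplify:
    def test_monomorphic_input_stays_monomorphic(self):
        out = amplify(cv(4, 0), 6, seed=0)
        np.testing.assert_array_equal(out.counts, [6, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_polya_urn_hits_target_exactly(self, seed):
        out = amplify(cv(2, 1, 1), 11, seed=seed)
        assert out.library_size == 11

    def test_polya_urn_preserves_zero_pattern(self):
        rng_out = amplify(cv(3, 0, 1, 0), 20, seed=4)
        assert rng_out.counts[1] == 0 and rng_out.counts[3] == 0

    def test_target_below_total_rejected(self):
        with pytest.raises(ValueError, match="below current total"):
            amplify(cv(3, 3), 4)

    def test_cycle_doubling_reaches_target_without_truncation(self):
        out = amplify(cv(4, 2), 20, mechanism="cycle_doubling",
                      efficiency=0.8, seed=5)
        assert out.library_size >= 20

    def test_urn_simulation_matches_enumeration_oracle(self):
        """Simulated urn amplification 4->6 from a Binomial(4, 2/3) start
        matches the exactly enumerated pmf, and that pmf differs from
        Binomial(6, 2/3)."""
        exact = exact_urn_pmf()
        rng = np.random.default_rng(6)
        reps = 4000
        finals = np.empty(reps, dtype=int)
        for r in range(reps):
            x1 = rng.binomial(4, 2 / 3)
            out = amplify(cv(x1, 4 - x1), 6, seed=rng)
            finals[r] = out.counts[0]
        obs = np.bincount(finals, minlength=7)
        chi2, p = stats.chisquare(obs, f_exp=exact * reps)
        assert p > 0.005
        # and the amplified process is NOT binomial
        res = binomial_compat_test(finals, n=6, p=2 / 3)
        assert res.reject


class TestThin:
    def test_full_recovery_is_identity(self):
        out = thin(cv(5, 3, 0), RecoveryProfile(np.ones(3)), seed=0)
        np.testing.assert_array_equal(out.counts, [5, 3, 0])

    def test_zero_recovery_empties_library(self):
        out = thin(cv(5, 3, 2), RecoveryProfile(np.zeros(3)), seed=0)
        assert out.library_size == 0

    def test_constant_recovery_preserves_composition(self):
        """Thinning Poisson counts at constant 50% recovery, conditioned on
        the post-thinning total, stays binomial with the source 2:1 ratio."""
        rng = np.random.default_rng(7)
        model = DispersionModel("poisson", np.array([8.0, 4.0]))
        x = simulate_counts(model, 60000, seed=8)
        thinned = rng.binomial(x, 0.5)
        kept = condition_on_library(thinned, 6)
        res = binomial_compat_test(kept[:, 0], n=6, p=2 / 3)
        assert res.p_value > 0.005

    def test_profile_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            thin(cv(1, 2), RecoveryProfile(np.array([0.5])), seed=0)


class TestClusterCounts:
    def test_single_copy_identity(self):
        out = cluster_counts(cv(2, 1), 1)
        np.testing.assert_array_equal(out.counts, [2, 1])

    def test_copies_multiply_counts(self):
        out = cluster_counts(cv(2, 1), 3)
        np.testing.assert_array_equal(out.counts, [6, 3])

    def test_clustered_counts_fail_compatibility(self):
        """Organism counts x3 gene copies conditioned on a total: variant
        counts only hit multiples of 3, impossible under a binomial."""
        model = DispersionModel("poisson", np.array([2.0, 1.0]))
        organisms = simulate_counts(model, 60000, seed=9)
        copies = organisms * 3
        kept = condition_on_library(copies, 9)
        assert kept.shape[0] > 500
        res = binomial_compat_test(kept[:, 0], n=9, p=2 / 3)
        assert res.reject


class TestBinomialCompatTest:
    def test_type_one_error_near_alpha(self):
        """Data really from Binomial(6, 2/3): rejection rate across many
        repetitions stays near the nominal 5%."""
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 120
        for _ in range(reps):
            data = rng.binomial(6, 2 / 3, size=800)
            rejections += binomial_compat_test(data, 6, 2 / 3).reject
        assert 0.0 <= rejections / reps <= 0.125

    def test_pooled_cells_have_adequate_expectation(self):
        rng = np.random.default_rng(11)
        data = rng.binomial(6, 2 / 3, size=500)
        res = binomial_compat_test(data, 6, 2 / 3)
        assert np.all(res.expected >= 5.0)
        assert res.df == len(res.cell_edges) - 1

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError, match="fewer than 2 cells"):
            binomial_compat_test(np.array([1, 1, 1]), 6, 2 / 3)

    def test_counts_outside_support_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 6\]"):
            binomial_compat_test(np.array([7]), 6, 2 / 3)
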