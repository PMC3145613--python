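"""Permutation machinery, parametric fallback, genome-wide thresholds."""

import numpy as np
import pytest
from scipy.stats import binomtest

from genewise.model import fit_subset
from genewise.significance import (
    BestFStatistic,
    GwisScoreStatistic,
    PermutationConfig,
    gene_empirical_pvalue,
    genomewide_threshold,
    parametric_pvalue_gwis,
    permute_phenotype,
    threshold_from_best_p,
)


class TestPermutePhenotype:
    def test_multiset_preserved(self, rng):
        y = rng.normal(size=50)
        yp = permute_phenotype(y, rng)
        np.testing.assert_array_equal(np.sort(y), np.sort(yp))

    def test_seeded_determinism(self):
        a = permute_phenotype(np.arange(20.0), np.random.default_rng(5))
        b = permute_phenotype(np.arange(20.0), np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_all_orders_equally_likely(self):
        """Each of the 6 orders of (1,2,3) appears ~1/6 of the time."""
        rng = np.random.default_rng(0)
        counts: dict[tuple, int] = {}
        n = 12_000
        for _ in range(n):
            key = tuple(permute_phenotype(np.array([1.0, 2.0, 3.0]), rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            # exact binomial 99.9% band around 1/6
            assert binomtest(c, n, 1 / 6).pvalue > 0.001


class _CannedStatistic:
    """Deterministic statistic for exercising the counting logic."""

    def __init__(self, observed_value, permuted_values):
        self._obs = observed_value
        self._vals = np.asarray(permuted_values, dtype=float)
        self._cursor = 0

    def observed(self, suff):
        return self._obs

    def permuted_batch(self, suff, C):
        b = C.shape[1]
        out = self._vals[self._cursor : self._cursor + b]
        self._cursor += b
        return out


class TestAdaptiveCounting:
    def _run(self, stat, config):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        x = rng.normal(size=(8, 2))
        return gene_empirical_pvalue(stat, y, x, config)

    def test_p_is_s_over_q(self):
        """10 successes out of 2000 trials gives p = 0.005 exactly."""
        vals = np.zeros(4000)
        hit_at = np.linspace(199, 1999, 10, dtype=int)
        vals[hit_at] = 2.0  # successes at chosen trial indices
        res = self._run(
            _CannedStatistic(1.0, vals),
            PermutationConfig(max_trials=4000, stop_successes=10),
        )
        assert res.successes == 10 and res.trials == 2000
        assert res.p_empirical == pytest.approx(0.005)

    def test_tie_counts_as_success(self):
        vals = np.full(100, 1.0)
        res = self._run(
            _CannedStatistic(1.0, vals),
            PermutationConfig(max_trials=100, stop_successes=10),
        )
        assert res.successes == 10 and res.trials == 10

    def test_exhausted_floor_and_fallback(self):
        vals = np.zeros(500)
        res = self._run(
            _CannedStatistic(1.0, vals),
            PermutationConfig(max_trials=500, stop_successes=10),
        )
        assert res.exhausted and res.successes == 0
        assert res.p_empirical == pytest.approx(1 / 500)

    def test_early_stop_nearly_unbiased(self, rng):
        """Stopping at the 10th success tracks the true p to order 1/S.

        A canned statistic with i.i.d. success probability 0.04 is run to
        10 successes many times.  The sequential estimator S/Q is
        slightly conservative — its expectation is inflated by at most
        the factor S/(S-1) — so the mean must land between the true p
        and that envelope (never below, never beyond).
        """
        estimates = []
        for rep in range(300):
            vals = (rng.uniform(size=4000) < 0.04).astype(float) * 2.0
            res = self._run(
                _CannedStatistic(1.0, vals),
                PermutationConfig(max_trials=4000, stop_successes=10),
            )
            estimates.append(
                res.p_empirical if res.successes else 0.0
            )
        mean = np.mean(estimates)
        assert 0.04 * 0.97 <= mean <= 0.04 * (10 / 9) * 1.03


class TestParametricFallback:
    def _fit(self, rng, n, k, f_target=None):
        x = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        return fit_subset(y - y.mean(), x - x.mean(0), list(range(k)))

    def test_combinatorial_factor(self):
        """p_F = 1e-10, t = 10, k = 1 scales to 1e-9 (C(10,1) = 10)."""
        from scipy.stats import f as f_dist

        n = 1000
        # build a fit whose overall F has sf = 1e-10 at (1, n-2)
        f_target = f_dist.isf(1e-10, 1, n - 2)
        # choose sse so that (ssm/1)/(sse/(n-2)) = f_target with sst = 1
        sse = 1.0 / (1.0 + f_target / (n - 2))
        from genewise.model import RegressionFit

        fit = RegressionFit([0], np.array([1.0]), sse, 1.0, n)
        p = parametric_pvalue_gwis(fit, 1, 10.0)
        assert p == pytest.approx(1e-9, rel=1e-6)

    def test_probability_cap(self):
        from scipy.stats import f as f_dist
        from genewise.model import RegressionFit

        n = 100
        f_target = f_dist.isf(0.5, 2, n - 3)
        sse = 1.0 / (1.0 + 2 * f_target / (n - 3))
        fit = RegressionFit([0, 1], np.ones(2), sse, 1.0, n)
        assert parametric_pvalue_gwis(fit, 2, 4.0) == 1.0  # 0.5 * C(4,2) capped

    def test_k_equals_t_boundary(self):
        from scipy.stats import f as f_dist
        from genewise.model import RegressionFit

        n = 200
        f_target = f_dist.isf(0.01, 3, n - 4)
        sse = 1.0 / (1.0 + 3 * f_target / (n - 4))
        fit = RegressionFit([0, 1, 2], np.ones(3), sse, 1.0, n)
        assert parametric_pvalue_gwis(fit, 3, 3.0) == pytest.approx(0.01, rel=1e-6)

    def test_k_zero_is_one(self):
        from genewise.model import RegressionFit

        fit = RegressionFit([], np.empty(0), 1.0, 1.0, 50)
        assert parametric_pvalue_gwis(fit, 0, 5.0) == 1.0


class TestGenomeWideThreshold:
    def test_order_statistic_rules(self):
        rng = np.random.default_rng(1)
        best = rng.uniform(size=300)
        th = threshold_from_best_p(best, alpha=0.05)
        assert th.threshold == np.sort(best)[14]  # 15th of 300
        th100 = threshold_from_best_p(best[:100], alpha=0.05)
        assert th100.threshold == np.sort(best[:100])[4]  # 5th of 100

    def test_degenerate_distribution(self):
        th = threshold_from_best_p(np.full(40, 0.123), alpha=0.05)
        assert th.threshold == pytest.approx(0.123)

    def test_unresolvable_alpha_warns(self):
        with pytest.warns(UserWarning):
            th = threshold_from_best_p(np.array([0.4, 0.2, 0.9]), alpha=0.01)
        assert th.threshold == pytest.approx(0.2)

    def test_whole_genome_permutation(self, rng):
        """Small end-to-end run: best-p per genome permutation, order stat."""
        genes = []
        for _ in range(5):
            x = rng.binomial(2, 0.3, size=(150, 4)).astype(float)
            genes.append((x, BestFStatistic()))
        y = rng.normal(size=150)
        with pytest.warns(UserWarning):  # n_perm below recommended
            th = genomewide_threshold(
                y,
                genes,
                n_perm=10,
                alpha=0.1,
                config=PermutationConfig(max_trials=400, seed=7),
            )
        assert th.n_genome_permutations == 10
        assert len(th.best_p_per_permutation) == 10
        assert 0 < th.threshold <= 1
        # best-of-5-genes p-values must be biased small vs uniform
        assert th.best_p_per_permutation.mean() < 0.5


class TestStatisticInternals:
    def test_gwis_batch_matches_scalar(self, rng):
        """Vectorized permuted statistics equal the scalar greedy path."""
        x = rng.binomial(2, 0.35, size=(120, 7)).astype(float)
        x = x - x.mean(0)
        y = rng.normal(size=120)
        y = y - y.mean()
        from genewise.model import GeneSuffStats

        suff = GeneSuffStats.build(y, x)
        stat = GwisScoreStatistic(4.5)
        B = 64
        perms = np.column_stack([rng.permutation(y) for _ in range(B)])
        C = x.T @ perms
        batch = stat.permuted_batch(suff, C)
        for b in range(B):
            scalar = stat.observed(suff.with_cross(C[:, b]))
            assert batch[b] == pytest.approx(scalar, abs=1e-8)

    def test_best_f_batch_matches_scalar(self, rng):
        x = rng.binomial(2, 0.2, size=(90, 5)).astype(float)
        x = x - x.mean(0)
        y = rng.normal(size=90)
        y = y - y.mean()
        from genewise.model import GeneSuffStats
        from genewise.comparators import snp_association

        suff = GeneSuffStats.build(y, x)
        stat = BestFStatistic()
        obs = stat.observed(suff)
        expected = max(
            snp_association(y, x[:, j]).f_stat for j in range(5)
        )
        assert obs == pytest.approx(expected, rel=1e-9)
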