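"""Regression sufficient statistics, model score, and the search."""

from itertools import combinations

import numpy as np
import pytest
from scipy.special import betaln
from scipy.stats import norm

from genewise.ld import effective_tests, pairwise_correlation
from genewise.model import (
    DegenerateFitError,
    GwisModel,
    f_statistic_add_one,
    fit_subset,
    greedy_search,
    log_model_prior,
    log_model_score,
    subset_search,
)


class TestFitSubset:
    def test_null_model(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=(20, 3))
        fit = fit_subset(y - y.mean(), x - x.mean(0), [])
        assert fit.sse == pytest.approx(fit.sst)
        assert fit.b_hat.size == 0

    def test_perfect_fit(self):
        x = np.array([[-1.0], [0.0], [1.0]])
        fit = fit_subset(x[:, 0], x, [0])
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.b_hat[0] == pytest.approx(1.0)

    def test_univariate_closed_form(self):
        """b = x'y/x'x = 0.5 and SSE = 2 - 0.5*2 = 1 on the worked example."""
        y = np.array([-1.0, 0.0, 1.0, 0.0, 0.0])
        x = np.array([[-1.0], [0.0], [1.0], [-1.0], [1.0]])
        fit = fit_subset(y, x, [0])
        assert fit.b_hat[0] == pytest.approx(0.5)
        assert fit.sse == pytest.approx(1.0)
        assert fit.sigma2_hat == pytest.approx(1.0 / 5)

    def test_rank_deficient_raises(self, rng):
        x1 = rng.normal(size=20)
        x = np.column_stack([x1, 2.0 * x1])
        with pytest.raises(DegenerateFitError):
            fit_subset(rng.normal(size=20), x, [0, 1])


class TestAddOneF:
    def test_no_improvement_gives_zero(self, rng):
        y = rng.normal(size=30)
        x = rng.normal(size=(30, 2))
        x[:, 1] = rng.normal(size=30)
        y = y - y.mean()
        x = x - x.mean(0)
        # orthogonalize column 1 against y so it adds nothing
        x[:, 1] -= (x[:, 1] @ y) / (y @ y) * y
        f0 = fit_subset(y, x, [])
        f1 = fit_subset(y, x, [1])
        assert f_statistic_add_one(f0, f1) == pytest.approx(0.0, abs=1e-9)

    def test_halved_sse_arithmetic(self, rng):
        """If SSE halves at n=102, k=0: F = (s/2) / ((s/2)/100) = 100."""
        n = 102
        y = rng.normal(size=n)
        y = y - y.mean()
        # construct a column capturing exactly half the variance
        e = rng.normal(size=n)
        e -= (e @ y) / (y @ y) * y
        e /= np.linalg.norm(e)
        u = y / np.linalg.norm(y)
        x = (u + e)[:, None]  # corr(x, y)^2 = 1/2
        f0 = fit_subset(y, x, [])
        f1 = fit_subset(y, x, [0])
        assert f1.sse == pytest.approx(f0.sse / 2, rel=1e-9)
        assert f_statistic_add_one(f0, f1) == pytest.approx(100.0, rel=1e-9)


class TestModelPrior:
    @pytest.mark.parametrize(
        "k,t,expected",
        [(0, 4.0, 1 / 5), (2, 4.0, 1 / 30), (1, 10.0, 1 / 110)],
    )
    def test_integer_t_equals_binomial_form(self, k, t, expected):
        assert np.exp(log_model_prior(k, t)) == pytest.approx(expected)

    def test_beta_integral_oracle(self):
        """ln B(k+1, t-k+1) equals the integral of f^k (1-f)^(t-k) df."""
        from scipy.integrate import quad

        for k, t in [(0, 4.0), (1, 3.5), (2, 6.7)]:
            val, _ = quad(lambda f: f**k * (1 - f) ** (t - k), 0, 1)
            assert log_model_prior(k, t) == pytest.approx(np.log(val), rel=1e-8)

    @pytest.mark.parametrize("t", [1, 3, 7])
    def test_normalization_for_integer_t(self, t):
        """Per-model weights times model multiplicity C(t, k) sum to one."""
        from math import comb

        total = sum(
            comb(t, k) * np.exp(log_model_prior(k, float(t)))
            for k in range(t + 1)
        )
        assert total == pytest.approx(1.0)


class TestModelScore:
    def test_null_model_value(self):
        sst, n, t = 25.0, 100, 4.0
        got = log_model_score(sst, 0, t, n)
        assert got == pytest.approx(np.log(1 / 5) - 50 * np.log(25.0))

    def test_decreasing_in_sse_and_deterministic(self):
        s1 = log_model_score(10.0, 2, 5.0, 100)
        s2 = log_model_score(9.0, 2, 5.0, 100)
        assert s2 > s1
        assert log_model_score(10.0, 2, 5.0, 100) == s1

    def test_perfect_fit_dominates(self):
        assert log_model_score(0.0, 1, 5.0, 100) == np.inf

    def test_ranking_matches_exact_marginal_likelihood(self, rng):
        """Score ordering agrees with brute-force marginal likelihood.

        The exact Bayesian evidence for a k-SNP model integrates the
        Gaussian likelihood over coefficients (wide uniform prior) and the
        residual scale numerically; the dropped constants are shared, so
        the exact evidences (times the same model-size prior) must rank
        the candidate models the way the asymptotic score does.
        """
        from scipy.integrate import quad

        n, p = 60, 5
        x = rng.normal(size=(n, p))
        x = x - x.mean(0)
        beta_true = np.array([0.5, 0.0, 0.3, 0.0, 0.0])
        y = x @ beta_true + rng.normal(size=n)
        y = y - y.mean()
        t = effective_tests(pairwise_correlation(x).r).t

        def exact_log_evidence(subset):
            k = len(subset)
            # profile out b analytically (Gaussian integral), then integrate
            # sigma numerically under p(sigma) ~ uniform
            fit = fit_subset(y, x, list(subset))
            G = x[:, subset].T @ x[:, subset] if k else np.empty((0, 0))
            logdet = np.linalg.slogdet(G)[1] if k else 0.0

            def integrand(log_s):
                s = np.exp(log_s)
                ll = (
                    -0.5 * n * np.log(2 * np.pi * s**2)
                    - fit.sse / (2 * s**2)
                    + 0.5 * k * np.log(2 * np.pi * s**2)
                    - 0.5 * logdet
                )
                return np.exp(ll - peak)

            peak = (
                -0.5 * n * np.log(2 * np.pi * fit.sigma2_hat)
                - n / 2
                + 0.5 * k * np.log(2 * np.pi * fit.sigma2_hat)
                - 0.5 * logdet
            )
            val, _ = quad(integrand, np.log(fit.sigma2_hat) / 2 - 3,
                          np.log(fit.sigma2_hat) / 2 + 3, limit=200)
            return peak + np.log(val) + log_model_prior(k, t)

        models = [[0], [2], [4], [0, 2], [0, 4], [1, 3]]
        exact = [exact_log_evidence(m) for m in models]
        score = [
            log_model_score(fit_subset(y, x, m), len(m), t) for m in models
        ]
        assert list(np.argsort(exact)) == list(np.argsort(score))


class TestGreedySearch:
    def test_null_phenotype_selects_null(self, rng):
        """Permuted/null traits overwhelmingly select the empty model."""
        hits = 0
        for _ in range(50):
            x = rng.normal(size=(300, 8))
            x = x - x.mean(0)
            y = rng.normal(size=300)
            y = y - y.mean()
            t = effective_tests(pairwise_correlation(x).r).t
            if greedy_search(y, x, t).k == 0:
                hits += 1
        assert hits >= 45

    def test_strong_single_snp_recovered(self, rng):
        n = 4000
        x = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
        x = x - x.mean(0)
        j = 3
        b = np.sqrt(0.007 / x[:, j].var())
        y = b * x[:, j] + rng.normal(size=n)
        y = y - y.mean()
        t = effective_tests(pairwise_correlation(x).r).t
        best = greedy_search(y, x, t)
        assert best.k == 1 and best.selected == [j]

    def test_search_vs_exhaustive_small_p(self, rng):
        """At P <= 3 greedy never beats enumeration; subset search matches it.

        Greedy is myopic: a suppression pair can hide the optimum from the
        one-at-a-time path, which is exactly what the small-subset
        initialization exists to fix — from the best pair, growth reaches
        any larger optimum at these sizes.
        """
        for trial in range(30):
            p = int(rng.integers(1, 4))
            x = rng.normal(size=(80, p))
            x = x - x.mean(0)
            y = x @ rng.normal(scale=0.3, size=p) + rng.normal(size=80)
            y = y - y.mean()
            t = effective_tests(pairwise_correlation(x).r).t
            greedy = greedy_search(y, x, t)
            sub2 = subset_search(y, x, t, init_size=2)
            best_enum = -np.inf
            k_max = min(p, int(np.floor(t)) + 1)
            for k in range(0, k_max + 1):
                for sub in combinations(range(p), k):
                    fit = fit_subset(y, x, list(sub))
                    best_enum = max(best_enum, log_model_score(fit, k, t))
            assert greedy.log_score <= best_enum + 1e-9
            assert sub2.log_score == pytest.approx(best_enum, abs=1e-9)

    def test_duplicate_snp_changes_nothing(self, rng):
        n = 1000
        x = rng.binomial(2, 0.4, size=(n, 4)).astype(float)
        y = 0.1 * x[:, 1] + rng.normal(size=n)
        x = x - x.mean(0)
        y = y - y.mean()
        xd = np.column_stack([x, x[:, 1]])
        t1 = effective_tests(pairwise_correlation(x).r).t
        t2 = effective_tests(pairwise_correlation(xd).r).t
        b1 = greedy_search(y, x, t1)
        b2 = greedy_search(y, xd, t2)
        assert b1.k == b2.k
        assert b1.fit.sse == pytest.approx(b2.fit.sse)

    def test_selection_scale_invariant(self, rng):
        n = 500
        x = rng.normal(size=(n, 6))
        x = x - x.mean(0)
        y = 0.15 * x[:, 2] + rng.normal(size=n)
        y = y - y.mean()
        t = effective_tests(pairwise_correlation(x).r).t
        a = greedy_search(y, x, t)
        b = greedy_search(7.3 * y, x, t)
        assert a.selected == b.selected


class TestSubsetSearch:
    def test_suppression_pair_found(self, rng):
        """Two near-collinear SNPs jointly explain y though neither alone does."""
        n = 3000
        z = rng.normal(size=n)
        x1 = z + 0.15 * rng.normal(size=n)
        x2 = z + 0.15 * rng.normal(size=n)
        signal = x1 - x2  # orthogonal-ish to each of x1, x2 marginally
        y = 0.45 * signal / signal.std() + rng.normal(size=n)
        x = np.column_stack([x1, x2, rng.normal(size=(n, 2))])
        x = x - x.mean(0)
        y = y - y.mean()
        t = effective_tests(pairwise_correlation(x).r).t
        sub = subset_search(y, x, t, init_size=2)
        assert set(sub.selected) >= {0, 1}
        assert sub.log_score >= greedy_search(y, x, t).log_score

    def test_subset_never_below_greedy(self, rng):
        for _ in range(10):
            x = rng.normal(size=(200, 5))
            x = x - x.mean(0)
            y = x @ rng.normal(scale=0.2, size=5) + rng.normal(size=200)
            y = y - y.mean()
            t = effective_tests(pairwise_correlation(x).r).t
            assert (
                subset_search(y, x, t, init_size=2).log_score
                >= greedy_search(y, x, t).log_score - 1e-9
            )

    def test_single_snp_gene_falls_back(self, rng):
        x = rng.normal(size=(50, 1))
        y = rng.normal(size=50)
        res = subset_search(y - y.mean(), x - x.mean(0), 1.0, init_size=2)
        assert res.k in (0, 1)

    def test_triples_cap(self, rng):
        x = rng.normal(size=(20, 501))
        with pytest.raises(ValueError):
            subset_search(rng.normal(size=20), x, 10.0, init_size=3)


class TestGwisModelAPI:
    def test_fit_and_summary(self, rng):
        n = 800
        x = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        b = np.sqrt(0.02 / x[:, 2].var())
        y = b * x[:, 2] + rng.normal(size=n)
        res = GwisModel(y, x).fit()
        assert res.k == 1 and res.selected == [2]
        assert 0 < res.rsquared < 0.1
        assert res.params.shape == (1,) and res.bse.shape == (1,)
        text = res.summary()
        assert "Effective tests" in text and "snp2" in text

    def test_from_dataframe(self, rng):
        import pandas as pd

        n = 300
        df = pd.DataFrame(
            {
                "trait": rng.normal(size=n),
                "rs1": rng.binomial(2, 0.4, n),
                "rs2": rng.binomial(2, 0.2, n),
            }
        )
        res = GwisModel.from_dataframe(df, "trait").fit()
        assert res.k == 0
        assert res.pvalue_parametric == 1.0
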