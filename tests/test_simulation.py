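"""Generators and experiment drivers: reproducibility and calibration."""

import numpy as np
import pytest
from scipy.stats import binomtest

from genewise.ld import effective_tests, pairwise_correlation
from genewise.simulate import (
    GeneSkipped,
    LdBlockSpec,
    TrueModel,
    effects_equal_variance,
    effects_from_power,
    model_size_experiment,
    select_causal_snps,
    simulate_ld_genotypes,
    simulate_no_ld_genotypes,
    simulate_phenotype,
)


class TestLdGenotypes:
    def test_block_correlation_realized(self, rng):
        spec = LdBlockSpec(n_snps=10, block_sizes=[5, 5], rho=0.9,
                           maf_range=(0.3, 0.3))
        gm = simulate_ld_genotypes(spec, 4000, rng)
        r = pairwise_correlation(gm.dosages).r
        within = [r[i, j] for i in range(5) for j in range(5) if i < j]
        between = [r[i, j] for i in range(5) for j in range(5, 10)]
        assert 0.8 <= np.mean(within) <= 0.95
        assert abs(np.mean(between)) < 0.05

    def test_no_correlation_gives_full_effective_tests(self, rng):
        spec = LdBlockSpec(n_snps=8, block_sizes=[1] * 8, rho=0.0)
        gm = simulate_ld_genotypes(spec, 3000, rng)
        t = effective_tests(pairwise_correlation(gm.dosages).r).t
        assert t == pytest.approx(8.0, abs=0.3)

    def test_maf_realized(self, rng):
        spec = LdBlockSpec(n_snps=4, rho=0.5, maf_range=(0.3, 0.3))
        gm = simulate_ld_genotypes(spec, 5000, rng)
        for j in range(4):
            freq = gm.dosages[:, j].mean() / 2
            assert binomtest(int(freq * 10_000), 10_000, 0.3).pvalue > 1e-4

    def test_decay_structure_profile(self, rng):
        spec = LdBlockSpec(n_snps=12, rho=0.9, structure="decay",
                           maf_range=(0.3, 0.5))
        gm = simulate_ld_genotypes(spec, 4000, rng)
        r = pairwise_correlation(gm.dosages).r
        lag1 = np.mean([r[i, i + 1] for i in range(11)])
        lag5 = np.mean([r[i, i + 5] for i in range(7)])
        assert lag1 > lag5 > 0

    def test_seeded_reproducibility(self):
        spec = LdBlockSpec(n_snps=6)
        a = simulate_ld_genotypes(spec, 100, np.random.default_rng(7))
        b = simulate_ld_genotypes(spec, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestNoLdGenotypes:
    def test_independence_and_range(self, rng):
        gm = simulate_no_ld_genotypes(p=20, n=8000, rng=rng)
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}
        r = pairwise_correlation(gm.dosages).r
        off = np.abs(r[~np.eye(20, dtype=bool)])
        assert off.max() < 0.05
        assert ((gm.variants["maf"] >= 0.03) & (gm.variants["maf"] <= 0.5)).all()


class TestCausalSelection:
    def test_k1_unconstrained(self, rng):
        x = rng.binomial(2, 0.3, size=(100, 4)).astype(float)
        idx = select_causal_snps(x, 1, rng=rng)
        assert idx.shape == (1,)

    def test_identical_snps_unsatisfiable(self, rng):
        col = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        x = np.tile(col, (1, 4))
        with pytest.raises(GeneSkipped):
            select_causal_snps(x, 2, r2_cap=0.2, rng=rng, max_retries=20)

    def test_independent_snps_any_triple(self, rng):
        x = rng.binomial(2, 0.3, size=(500, 8)).astype(float)
        idx = select_causal_snps(x, 3, r2_cap=0.2, rng=rng)
        assert idx.shape == (3,) and len(set(idx.tolist())) == 3

    def test_needs_twice_k_snps(self, rng):
        x = rng.binomial(2, 0.3, size=(100, 5)).astype(float)
        with pytest.raises(GeneSkipped):
            select_causal_snps(x, 3, rng=rng)


class TestEffects:
    def test_equal_variance_closed_forms(self):
        sigma = np.diag([0.5, 0.5])
        b = effects_equal_variance(sigma, 2, 0.01)
        # independent SNPs with equal variance contribute v/2 each
        assert b[0] ** 2 * 0.5 == pytest.approx(0.005)
        assert float(b @ sigma @ b) == pytest.approx(0.01, abs=1e-9)

    def test_exact_rescale_under_ld(self, rng):
        a = rng.normal(size=(4, 4))
        sigma = a @ a.T + 0.5 * np.eye(4)
        b = effects_equal_variance(sigma, 4, 0.007)
        assert float(b @ sigma @ b) == pytest.approx(0.007, abs=1e-9)

    def test_k1_closed_form(self):
        b = effects_equal_variance(np.array([[0.42]]), 1, 0.007)
        assert b[0] == pytest.approx(np.sqrt(0.007 / 0.42))

    def test_power_inversion_values(self):
        v, b = effects_from_power(0.5, power=0.5, alpha=0.01, n=1000)
        from scipy.stats import norm

        assert v == pytest.approx(norm.isf(0.005) ** 2 / 1000)  # z_power = 0
        v01, _ = effects_from_power(0.5, 0.1, 5e-8, 1000)
        v08, _ = effects_from_power(0.5, 0.8, 5e-8, 1000)
        assert v08 > v01

    def test_power_closed_loop(self, rng):
        """Simulating at the inverted effect recovers the nominal power.

        Univariate F test at alpha on data generated with v from the
        power inversion must reject in ~power of replicates.
        """
        from scipy.stats import f as f_dist

        n, alpha, power = 2000, 1e-3, 0.8
        reps = 800
        hits = 0
        x = rng.binomial(2, 0.3, size=(n, reps)).astype(float)
        xc = x - x.mean(0)
        for i in range(reps):
            v, b = effects_from_power(xc[:, i].var(), power, alpha, n)
            y = b * xc[:, i] + rng.standard_normal(n)
            y = y - y.mean()
            xx = float(xc[:, i] @ xc[:, i])
            red = float(xc[:, i] @ y) ** 2 / xx
            f = red / ((float(y @ y) - red) / (n - 2))
            hits += int(f_dist.sf(f, 1, n - 2) <= alpha)
        assert binomtest(hits, reps, power).pvalue > 0.001


class TestPhenotype:
    def test_null_variance(self, rng):
        gm = simulate_no_ld_genotypes(p=3, n=5000, rng=rng)
        model = TrueModel([0], [0.0], 0.0, [0.0])
        y = simulate_phenotype(gm, model, rng)
        assert y.values.var() == pytest.approx(1.0, rel=0.1)

    def test_variance_adds_signal(self, rng):
        v = 0.05
        variances = []
        for _ in range(30):
            gm = simulate_no_ld_genotypes(p=2, n=2000, rng=rng)
            sii = gm.dosages[:, 0].var()
            model = TrueModel([0], [np.sqrt(v / sii)], v, [v])
            variances.append(simulate_phenotype(gm, model, rng).values.var())
        assert np.mean(variances) == pytest.approx(1.0 + v, rel=0.05)

    def test_seeded_determinism(self):
        gm = simulate_no_ld_genotypes(p=2, n=50, rng=np.random.default_rng(3))
        model = TrueModel([0], [0.1], 0.001, [0.001])
        y1 = simulate_phenotype(gm, model, np.random.default_rng(11))
        y2 = simulate_phenotype(gm, model, np.random.default_rng(11))
        np.testing.assert_array_equal(y1.values, y2.values)


class TestPowerDriver:
    def test_power_counts_and_ci(self):
        """Strong single effects are detected; the CI brackets the rate."""
        from genewise.comparators import snp_association
        from genewise.simulate import power_experiment

        def cheap_gene_p(y, x, rng):
            # Bonferroni-corrected best parametric SNP p (no permutations)
            ps = [
                snp_association(y, x[:, j]).p_parametric
                for j in range(x.shape[1])
            ]
            return min(1.0, min(ps) * x.shape[1])

        power, (lo, hi) = power_experiment(
            cheap_gene_p,
            k_true=1,
            v=0.05,
            n_genes=20,
            threshold=1e-4,
            n=1000,
            spec=LdBlockSpec(n_snps=10),
            rng=np.random.default_rng(6),
        )
        assert power >= 0.9
        assert lo <= power <= hi


class TestModelSizeDriver:
    def test_null_genes_select_nothing(self):
        df = model_size_experiment(
            0.8,
            k_true_values=[0],
            n_genes=15,
            n=1000,
            spec=LdBlockSpec(n_snps=15),
            rng=np.random.default_rng(2),
        )
        assert (df.k_estimated == 0).mean() >= 0.9

    def test_recovers_signal_scale(self):
        df = model_size_experiment(
            0.8,
            k_true_values=[2],
            n_genes=10,
            n=1500,
            alpha=1e-4,
            spec=LdBlockSpec(n_snps=20),
            rng=np.random.default_rng(4),
        )
        assert 0.4 <= df.k_estimated.mean() / 2 <= 1.2
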