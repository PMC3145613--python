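"""Benchmark gene-based statistics: minSNP, minSNP-P, BIMBAM, VEGAS.

These are the standard alternatives the model-selection test is compared
against:

* **minSNP** — the gene inherits the p-value of its best single SNP (not
  uniform under the null; it needs its own genome-wide threshold).
* **minSNP-P** — gene-level permutation of the best single-SNP F
  statistic, which restores uniformity under the null.
* **BIMBAM** — the mean of conjugate-normal single-SNP Bayes factors over
  the gene, converted to a p-value by the same gene-level permutation.
* **VEGAS** — the sum over SNPs of 1-df chi-square quantiles of the
  single-SNP p-values, with the null distribution simulated from a
  multivariate normal with the gene's LD matrix as covariance (sample LD
  here, rather than a reference panel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, f as f_dist

from .data import Phenotype
from .ld import CorrelationMatrix
from .model import COLLINEAR_TOL
from .significance import (
    BestFStatistic,
    MeanBayesFactorStatistic,
    PermutationConfig,
    PermutationResult,
    gene_empirical_pvalue,
)

__all__ = [
    "SnpAssociation",
    "SingleSnpBayesFactor",
    "snp_association",
    "min_snp",
    "min_snp_p",
    "bimbam_bf",
    "bimbam_gene_stat",
    "vegas_stat",
]


@dataclass
class SnpAssociation:
    """Univariate association result for one SNP."""

    snp_index: int
    f_stat: float
    p_parametric: float
    p_empirical: float | None = None


@dataclass
class SingleSnpBayesFactor:
    """Single-SNP Bayes factor against the intercept-only null."""

    snp_index: int
    log10_bf: float
    sigma_a: float
    sigma_mu: float

    @property
    def bf(self) -> float:
        return 10.0**self.log10_bf


def _as_array(v) -> np.ndarray:
    if isinstance(v, Phenotype):
        return np.asarray(v.values, dtype=float)
    return np.asarray(v, dtype=float)


def snp_association(
    y, x_col, config: PermutationConfig | None = None, snp_index: int = 0
) -> SnpAssociation:
    """Univariate F test of one dosage column against the trait.

    The parametric p-value is the F(1, n-2) upper tail; when ``config`` is
    given, an empirical p-value is added by permutation, which keeps
    p-values honest for low-MAF SNPs where the F approximation is poor.
    A constant column carries no information: F = 0, p = 1.
    """
    yv = _as_array(y)
    xv = _as_array(x_col).reshape(-1)
    yv = yv - yv.mean()
    xv = xv - xv.mean()
    n = yv.shape[0]
    xx = float(xv @ xv)
    yy = float(yv @ yv)
    if xx <= COLLINEAR_TOL or yy <= 0.0:
        return SnpAssociation(snp_index, 0.0, 1.0)
    red = float(xv @ yv) ** 2 / xx
    red = min(red, yy)
    sse = yy - red
    f_stat = np.inf if sse == 0 else red / (sse / (n - 2))
    p_par = float(f_dist.sf(f_stat, 1, n - 2))
    p_emp = None
    if config is not None:
        res = gene_empirical_pvalue(BestFStatistic(), yv, xv[:, None], config)
        p_emp = res.p_empirical
    return SnpAssociation(snp_index, float(f_stat), p_par, p_emp)


def min_snp(gene_snp_ps) -> float:
    """The gene's p-value is its best SNP's p-value.

    Deliberately not uniform under the null — the minimum over many SNPs
    is biased small — so it must be compared to its own, more stringent,
    genome-wide threshold.
    """
    ps = np.asarray(list(gene_snp_ps), dtype=float)
    if ps.size == 0:
        raise ValueError("min_snp needs at least one SNP p-value")
    return float(ps.min())


def min_snp_p(
    y, x_gene, config: PermutationConfig | None = None
) -> PermutationResult:
    """Gene-level permutation p-value of the best single-SNP F statistic.

    When permutations exhaust without a success, the Bonferroni-corrected
    best parametric SNP p-value (scaled by the SNP count) is attached for
    ranking.
    """
    config = config or PermutationConfig()
    yv = _as_array(y)
    xv = _as_array(x_gene)
    if xv.ndim == 1:
        xv = xv[:, None]

    def bonferroni() -> float:
        ps = [
            snp_association(yv, xv[:, j], snp_index=j).p_parametric
            for j in range(xv.shape[1])
        ]
        return min(1.0, min(ps) * xv.shape[1])

    return gene_empirical_pvalue(
        BestFStatistic(), yv, xv, config, parametric=bonferroni
    )


# ---------------------------------------------------------------------------
# BIMBAM
# ---------------------------------------------------------------------------

def bimbam_bf(
    y,
    x_col,
    sigma_a: float = 0.2,
    sigma_mu: float = 1.0,
    snp_index: int = 0,
) -> SingleSnpBayesFactor:
    """Conjugate-normal Bayes factor of a single-SNP model vs the null.

    The alternative regresses the trait on an intercept and the SNP's
    dosages with independent normal priors — intercept centered at the
    phenotypic mean with SD ``sigma_mu``, effect centered at 0 with SD
    ``sigma_a``, both in units of the phenotypic standard deviation; the
    null keeps only the intercept.  The residual scale is the phenotypic
    variance, so the Bayes factor is the ratio of two bivariate Gaussian
    integrals and has a closed form; ``sigma_a = 0`` collapses the
    alternative onto the null and gives BF = 1 exactly.
    """
    if sigma_a < 0 or sigma_mu < 0:
        raise ValueError("prior standard deviations must be >= 0")
    yv = _as_array(y)
    xv = _as_array(x_col).reshape(-1)
    n = yv.shape[0]
    lam = yv.mean()
    r = yv - lam
    sigma2 = float(r @ r) / n
    if sigma_a == 0.0 or sigma2 == 0.0:
        return SingleSnpBayesFactor(snp_index, 0.0, sigma_a, sigma_mu)
    sx = float(xv.sum())
    xx = float(xv @ xv)
    xr = float(xv @ r)
    # A = D^{-1} + U'U for U = [1, x], D = diag(sigma_mu^2, sigma_a^2)
    a11 = (1.0 / sigma_mu**2 if sigma_mu > 0 else np.inf) + n
    a22 = 1.0 / sigma_a**2 + xx
    if np.isinf(a11):
        # zero-variance intercept prior: intercept pinned at the mean
        log_bf = -0.5 * np.log(sigma_a**2 * a22) + xr**2 / (2 * sigma2 * a22)
    else:
        det_a = a11 * a22 - sx**2
        log_det_alt = np.log(sigma_mu**2 * sigma_a**2 * det_a)
        log_det_null = np.log(1.0 + sigma_mu**2 * n)
        quad = xr**2 * a11 / (2.0 * sigma2 * det_a)
        log_bf = -0.5 * (log_det_alt - log_det_null) + quad
    return SingleSnpBayesFactor(
        snp_index, float(log_bf / np.log(10)), sigma_a, sigma_mu
    )


def bimbam_gene_stat(
    y,
    x_gene,
    config: PermutationConfig | None = None,
    sigma_a: float = 0.2,
    sigma_mu: float = 1.0,
) -> PermutationResult:
    """Gene p-value from the mean of single-SNP Bayes factors.

    The statistic is the average Bayes factor over the gene's SNPs (in
    practice dominated by the single best term); the permutation machinery
    converts it into a p-value that is uniform under the null.  Exhausted
    permutations fall back to the Bonferroni-corrected best SNP p for
    ranking, mirroring minSNP-P.
    """
    config = config or PermutationConfig()
    yv = _as_array(y)
    xv = _as_array(x_gene)
    if xv.ndim == 1:
        xv = xv[:, None]

    def bonferroni() -> float:
        ps = [
            snp_association(yv, xv[:, j], snp_index=j).p_parametric
            for j in range(xv.shape[1])
        ]
        return min(1.0, min(ps) * xv.shape[1])

    return gene_empirical_pvalue(
        MeanBayesFactorStatistic(sigma_a, sigma_mu),
        yv,
        xv,
        config,
        parametric=bonferroni,
    )


# ---------------------------------------------------------------------------
# VEGAS
# ---------------------------------------------------------------------------

def vegas_stat(
    y,
    x_gene,
    corr: CorrelationMatrix | np.ndarray | None = None,
    n_sim: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """LD-corrected chi-square-sum gene p-value.

    Each SNP's parametric p-value is converted to a 1-df chi-square
    quantile and summed over the gene.  The null distribution of the sum
    is simulated by drawing multivariate normal vectors with the gene's
    SNP correlation matrix as covariance (repaired to positive
    semidefinite by eigenvalue clipping when needed) and summing their
    squares; the returned value is the fraction of simulated sums at or
    above the observed one.
    """
    from .ld import pairwise_correlation

    yv = _as_array(y)
    xv = _as_array(x_gene)
    if xv.ndim == 1:
        xv = xv[:, None]
    if rng is None:
        rng = np.random.default_rng()
    p = xv.shape[1]
    ps = np.array(
        [snp_association(yv, xv[:, j], snp_index=j).p_parametric for j in range(p)]
    )
    ps = np.clip(ps, 1e-300, 1.0)
    observed = float(chi2.isf(ps, df=1).sum())
    r = corr.r if isinstance(corr, CorrelationMatrix) else corr
    if r is None:
        r = pairwise_correlation(xv).r
    r = np.asarray(r, dtype=float)
    eigval, eigvec = np.linalg.eigh((r + r.T) / 2.0)
    eigval = np.clip(eigval, 0.0, None)
    factor = eigvec * np.sqrt(eigval)
    z = rng.standard_normal((n_sim, p)) @ factor.T
    sums = (z * z).sum(axis=1)
    exceed = int((sums >= observed).sum())
    return float(max(exceed, 1) / n_sim)
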