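"""Empirical p-values by adaptive phenotype permutation.

Gene-level significance is assessed by permuting the trait (Fisher-Yates,
via numpy's Generator) while holding genotypes fixed, re-running the full
statistic — including model-size selection — on every permutation, and
counting permutations whose statistic is greater than or equal to the
observed one.  Permutations stop early once ``stop_successes`` successes
accumulate (the negative-binomial stopping rule keeps S/Q unbiased) or at
``max_trials``; a statistic-specific parametric fallback ranks the genes
whose permutations exhaust without a success.

The model-selection test statistic is the best score over models with at
least one SNP, measured relative to the null-model score.  The null score
is permutation-invariant (the trait's sum of squares survives shuffling),
so this difference is a continuous statistic and the empirical p-values
are exactly uniform under the null; the reported model is the null
whenever the statistic is non-positive.

Genome-wide significance is calibrated by a second permutation stage:
permute the trait genome-wide, record the best gene p-value per
permutation, and take the ``ceil(alpha * m)``-th smallest of the pooled
best p-values as the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import f as f_dist

from .data import Phenotype
from .model import (
    BETA_ARG_FLOOR,
    COLLINEAR_TOL,
    GeneSuffStats,
    RegressionFit,
    _greedy_from,
    log_model_score,
)

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "GenomeWideThreshold",
    "permute_phenotype",
    "GwisScoreStatistic",
    "BestFStatistic",
    "MeanBayesFactorStatistic",
    "gene_empirical_pvalue",
    "parametric_pvalue_gwis",
    "genomewide_threshold",
    "threshold_from_best_p",
]


@dataclass
class PermutationConfig:
    """Adaptive permutation settings.

    ``max_trials`` caps the permutation count (one-in-a-million is the
    finest resolvable p-value); ``stop_successes`` ends a gene early once
    that many permuted statistics have reached the observed one.
    """

    max_trials: int = 1_000_000
    stop_successes: int = 10
    seed: int = 0
    rng_algorithm: str = "PCG64"

    def __post_init__(self) -> None:
        if self.max_trials < 1 or self.stop_successes < 1:
            raise ValueError("max_trials and stop_successes must be >= 1")

    def make_rng(self, *spawn_key: int) -> np.random.Generator:
        seq = np.random.SeedSequence(self.seed, spawn_key=spawn_key)
        bitgen = getattr(np.random, self.rng_algorithm)(seq)
        return np.random.Generator(bitgen)


@dataclass
class PermutationResult:
    """Empirical p-value with its success/trial counts."""

    p_empirical: float
    successes: int
    trials: int
    p_parametric: float | None = None
    exhausted: bool = False

    @property
    def ranking_value(self) -> float:
        """P-value to rank by: parametric fallback when exhausted."""
        if self.exhausted and self.p_parametric is not None:
            return self.p_parametric
        return self.p_empirical


@dataclass
class GenomeWideThreshold:
    method: str
    threshold: float
    n_genome_permutations: int
    best_p_per_permutation: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )


def permute_phenotype(y: Phenotype | np.ndarray, rng: np.random.Generator):
    """Uniform random permutation of the trait values (genotypes fixed)."""
    if isinstance(y, Phenotype):
        return y.with_values(rng.permutation(y.values))
    return rng.permutation(np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# gene statistics (observed + vectorized permuted batches)
# ---------------------------------------------------------------------------

class GwisScoreStatistic:
    """Best model score relative to the null, by greedy search.

    The greedy search is forced through its best single-SNP start and then
    grows only while the score improves; the statistic is the resulting
    best score minus the null score.  Model size is re-optimized for every
    permutation.
    """

    name = "gwis"

    def __init__(self, t: float):
        self.t = float(t)

    def observed(self, suff: GeneSuffStats) -> float:
        best = _greedy_from(suff, self.t, [], force_first=True)
        if best.k == 0:
            return 0.0
        return best.log_score - log_model_score(suff.yy, 0, self.t, suff.n)

    def observed_model(self, suff: GeneSuffStats):
        """Selected model: the greedy best, or the null if it scores higher."""
        return _greedy_from(suff, self.t, [])

    def permuted_batch(self, suff: GeneSuffStats, C: np.ndarray) -> np.ndarray:
        n, t = suff.n, self.t
        diag = np.diag(suff.G)
        valid = np.flatnonzero(diag > COLLINEAR_TOL)
        B = C.shape[1]
        if valid.size == 0:
            return np.zeros(B)
        score0 = log_model_score(suff.yy, 0, t, n)
        red = C[valid] ** 2 / diag[valid, None]  # (V, B)
        pick = red.argmax(axis=0)
        sse1 = np.maximum(suff.yy - red[pick, np.arange(B)], 0.0)
        stats = _stat_of(sse1, 1, t, n, score0)
        k_max = int(np.floor(t)) + 1
        if suff.p < 2 or k_max < 2:
            return stats
        # second greedy step, grouped by the first selected SNP
        j1 = valid[pick]
        stat2 = np.full(B, -np.inf)
        for j in np.unique(j1):
            cols = np.flatnonzero(j1 == j)
            others = valid[valid != j]
            if others.size == 0:
                continue
            beta = suff.G[others, j] / diag[j]
            d2 = diag[others] - beta * suff.G[others, j]
            ok = d2 > COLLINEAR_TOL * np.maximum(diag[others], 1.0)
            if not ok.any():
                continue
            o, bta, dd = others[ok], beta[ok], d2[ok]
            num2 = C[np.ix_(o, cols)] - bta[:, None] * C[j, cols]
            red2 = (num2 * num2 / dd[:, None]).max(axis=0)
            sse2 = np.maximum(sse1[cols] - red2, 0.0)
            stat2[cols] = _stat_of(sse2, 2, t, n, score0)
        improved = stat2 > stats
        if improved.any() and k_max >= 2:
            if k_max == 2:
                stats = np.where(improved, stat2, stats)
            else:
                for b in np.flatnonzero(improved):
                    best = _greedy_from(
                        suff.with_cross(C[:, b]), t, [], force_first=True
                    )
                    stats[b] = best.log_score - score0
        return stats


def _stat_of(sse: np.ndarray, k: int, t: float, n: int, score0: float) -> np.ndarray:
    from .model import _score_vector

    return _score_vector(np.asarray(sse, dtype=float), k, t, n) - score0


class BestFStatistic:
    """Maximum single-SNP F statistic within the gene (minSNP-P)."""

    name = "minsnp-p"

    def observed(self, suff: GeneSuffStats) -> float:
        return float(self.permuted_batch(suff, suff.c[:, None])[0])

    def permuted_batch(self, suff: GeneSuffStats, C: np.ndarray) -> np.ndarray:
        diag = np.diag(suff.G)
        valid = diag > COLLINEAR_TOL
        if not valid.any():
            return np.zeros(C.shape[1])
        red = (C[valid] ** 2 / diag[valid, None]).max(axis=0)
        red = np.minimum(red, suff.yy)
        df = suff.n - 2
        with np.errstate(divide="ignore"):
            return np.where(
                red < suff.yy, red / ((suff.yy - red) / df), np.inf
            )


class MeanBayesFactorStatistic:
    """Log of the mean single-SNP Bayes factor within the gene.

    The Bayes factors use the conjugate-normal single-SNP model (see
    :func:`genewise.comparators.bimbam_bf`); on centered data the per-SNP
    log BF is ``q_j (x_j'y)^2 - half-log-constant``, so permuted batches
    reduce to array arithmetic.  The log transform of the mean is monotone
    and overflow-safe; p-values and rankings are unchanged by it.
    """

    name = "bimbam"

    def __init__(self, sigma_a: float = 0.2, sigma_mu: float = 1.0):
        self.sigma_a = float(sigma_a)
        self.sigma_mu = float(sigma_mu)

    def _per_snp_terms(self, suff: GeneSuffStats):
        xx = np.diag(suff.G)
        sigma2 = suff.yy / suff.n  # phenotypic variance (centered y)
        if self.sigma_a == 0.0 or sigma2 == 0.0:
            return None
        a22 = 1.0 / self.sigma_a**2 + xx
        log_const = -0.5 * np.log(self.sigma_a**2 * a22)
        quad_coef = 1.0 / (2.0 * sigma2 * a22)
        return log_const, quad_coef

    def observed(self, suff: GeneSuffStats) -> float:
        return float(self.permuted_batch(suff, suff.c[:, None])[0])

    def permuted_batch(self, suff: GeneSuffStats, C: np.ndarray) -> np.ndarray:
        terms = self._per_snp_terms(suff)
        if terms is None:
            return np.zeros(C.shape[1])
        log_const, quad_coef = terms
        log_bf = log_const[:, None] + quad_coef[:, None] * C**2  # (P, B)
        return logsumexp(log_bf, axis=0) - np.log(suff.p)


# ---------------------------------------------------------------------------
# adaptive permutation p-value
# ---------------------------------------------------------------------------

def _batch_sizes(n: int, max_trials: int):
    """Growing batch sizes, capped to keep the permuted-trait matrix small."""
    cap = max(256, min(8192, int(4e6 / max(n, 1))))
    b = min(256, cap)
    done = 0
    while done < max_trials:
        size = min(b, max_trials - done)
        yield size
        done += size
        b = min(b * 2, cap)


def gene_empirical_pvalue(
    statistic,
    y,
    x_gene,
    config: PermutationConfig | None = None,
    positions: np.ndarray | None = None,
    parametric=None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Adaptive permutation p-value for one gene under any statistic.

    ``statistic`` must expose ``observed(suff)`` and
    ``permuted_batch(suff, C)`` where ``C = X' Y_perm`` holds one column of
    cross-products per permutation.  Successes are permutations whose
    statistic is greater than or equal to the observed one; the returned
    p-value is S/Q.  If no success occurs within ``max_trials``, the
    result is flagged exhausted, the minimum reportable p (1/max_trials)
    is recorded, and ``parametric`` (a callable of no arguments), when
    given, supplies the fallback p-value used for ranking.
    """
    config = config or PermutationConfig()
    yv = np.asarray(y.values if isinstance(y, Phenotype) else y, dtype=float)
    xv = np.asarray(
        x_gene.dosages if hasattr(x_gene, "dosages") else x_gene, dtype=float
    )
    if xv.ndim == 1:
        xv = xv[:, None]
    yv = yv - yv.mean()
    xv = xv - xv.mean(axis=0, keepdims=True)
    suff = GeneSuffStats.build(yv, xv, positions)
    observed = statistic.observed(suff)
    if rng is None:
        rng = config.make_rng()

    successes = 0
    trials = 0
    for b in _batch_sizes(suff.n, config.max_trials):
        tiled = np.tile(yv, (b, 1))
        perms = rng.permuted(tiled, axis=1)
        C = xv.T @ perms.T  # (P, b)
        stats = statistic.permuted_batch(suff, C)
        hits = stats >= observed
        new = int(hits.sum())
        if successes + new >= config.stop_successes:
            needed = config.stop_successes - successes
            idx = np.flatnonzero(hits)[needed - 1]
            trials += int(idx) + 1
            successes = config.stop_successes
            break
        successes += new
        trials += b
    if successes >= 1:
        return PermutationResult(successes / trials, successes, trials)
    p_par = parametric() if parametric is not None else None
    return PermutationResult(
        1.0 / config.max_trials, 0, trials, p_parametric=p_par, exhausted=True
    )


def parametric_pvalue_gwis(fit: RegressionFit, k: int, t: float) -> float:
    """Parametric fallback p-value for a selected model of size ``k``.

    The upper tail of F(k, n-k-1) at the overall MLE F statistic, times
    the generalized binomial coefficient C(t, k) counting models of the
    same size among t effective tests; capped at 1.  Defined for ranking
    genes whose permutations exhaust without a success.
    """
    if k == 0:
        return 1.0
    df2 = fit.n - k - 1
    f_stat = (fit.ssm / k) / (fit.sse / df2) if fit.sse > 0 else np.inf
    p_f = float(f_dist.sf(f_stat, k, df2))
    log_comb = (
        gammaln(t + 1) - gammaln(k + 1) - gammaln(max(t - k + 1, BETA_ARG_FLOOR))
    )
    return float(min(1.0, p_f * np.exp(log_comb)))


# ---------------------------------------------------------------------------
# genome-wide significance thresholds
# ---------------------------------------------------------------------------

def threshold_from_best_p(
    best_p, alpha: float = 0.05, method: str = "", n_perm: int | None = None
) -> GenomeWideThreshold:
    """Order-statistic threshold from pooled per-permutation best p-values.

    The family-wise ``alpha`` threshold is the ``ceil(alpha * m)``-th
    smallest of the ``m`` pooled best p-values (e.g. the 15th of 300 at
    alpha = 0.05).
    """
    best_p = np.sort(np.asarray(best_p, dtype=float))
    m = best_p.size
    k = int(np.ceil(alpha * m))
    if alpha * m < 1:
        warnings.warn(
            f"{m} permutations cannot resolve alpha={alpha}; using the minimum",
            stacklevel=2,
        )
        k = 1
    return GenomeWideThreshold(
        method=method,
        threshold=float(best_p[k - 1]),
        n_genome_permutations=n_perm if n_perm is not None else m,
        best_p_per_permutation=best_p,
    )


def genomewide_threshold(
    y,
    genes: list[tuple[np.ndarray, object]],
    n_perm: int = 100,
    alpha: float = 0.05,
    config: PermutationConfig | None = None,
    method: str = "",
) -> GenomeWideThreshold:
    """Genome-wide significance threshold by whole-genome permutation.

    For each of ``n_perm`` genome permutations the trait is shuffled once,
    every gene's empirical p-value is recomputed on the shuffled trait,
    and the best p-value is recorded; the threshold is the order statistic
    of those best values at ``alpha``.  ``genes`` is a list of
    ``(x_gene, statistic)`` pairs.  Per-gene random streams are derived
    from the master seed and the (permutation, gene) indices, so results
    do not depend on evaluation order.
    """
    config = config or PermutationConfig()
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} is small for threshold estimation", stacklevel=2
        )
    yv = np.asarray(y.values if isinstance(y, Phenotype) else y, dtype=float)
    master = config.make_rng(0)
    best = np.empty(n_perm)
    for i in range(n_perm):
        y_p = master.permutation(yv)
        best_p = 1.0
        for g, (x_gene, stat) in enumerate(genes):
            res = gene_empirical_pvalue(
                stat, y_p, x_gene, config, rng=config.make_rng(1 + i, g)
            )
            best_p = min(best_p, res.ranking_value)
        best[i] = best_p
    return threshold_from_best_p(best, alpha, method=method, n_perm=n_perm)
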