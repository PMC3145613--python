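"""Gene-wide Bayesian model selection over SNPs (the GWiS statistic).

A gene with P assigned SNPs defines a family of linear models: each model
is the subset of SNPs allowed non-zero additive effects on the (centered)
trait.  The selection objective combines

* a model-size prior calibrated by the effective number of independent
  tests T within the gene — ``ln B(K+1, T-K+1)`` with B the Beta function,
  the continuous extension of a uniform-f "each SNP associated with
  probability f, f integrated out" prior that is insensitive to marker
  density;
* a Schwarz/BIC complexity penalty ``-(K/2) ln N``; and
* the Gaussian profile likelihood ``-(N/2) ln SSE``.

Model-independent constants are dropped throughout: scores are only ever
compared between models of the same gene and phenotype (or permutation),
where N and SST are fixed.

The search is greedy forward selection (optionally seeded by exhaustive
enumeration of small subsets), adding at each step the SNP with the
maximal score increase and stopping when no addition improves the score.
The number of independent effects K in the selected model is the quantity
of interest; significance comes from phenotype permutation (see
:mod:`genewise.significance`).

:class:`GwisModel` / :class:`GwisResults` wrap this machinery in the
model/results idiom: build the model from data, ``fit()`` it, and read
estimates, diagnostics and p-values off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import betaln

from .data import GenotypeMatrix, GeneRegion, Phenotype

__all__ = [
    "DegenerateFitError",
    "RegressionFit",
    "ModelScore",
    "GeneSuffStats",
    "fit_subset",
    "f_statistic_add_one",
    "log_model_prior",
    "log_model_score",
    "greedy_search",
    "subset_search",
    "GwisModel",
    "GwisResults",
]

#: candidate SNPs whose residual variance against the current model falls
#: below this fraction of their total variance are treated as collinear
COLLINEAR_TOL = 1e-10

#: floor for Beta-function arguments when K exceeds T
BETA_ARG_FLOOR = 1e-3


class DegenerateFitError(ValueError):
    """Raised when a requested SNP subset is rank-deficient."""


@dataclass
class RegressionFit:
    """OLS sufficient results for one SNP subset (centered, no intercept)."""

    selected: list[int]
    b_hat: np.ndarray
    sse: float
    sst: float
    n: int

    @property
    def k(self) -> int:
        return len(self.selected)

    @property
    def sigma2_hat(self) -> float:
        return self.sse / self.n

    @property
    def ssm(self) -> float:
        return self.sst - self.sse


@dataclass
class ModelScore:
    """A selected model and its log score."""

    k: int
    selected: list[int]
    log_score: float
    fit: RegressionFit


@dataclass
class GeneSuffStats:
    """Gram-matrix sufficient statistics for all regressions within a gene.

    Everything the model search needs is ``G = X'X``, ``c = X'y`` and
    ``yy = y'y`` — permutations of the phenotype only change ``c``.
    """

    G: np.ndarray
    c: np.ndarray
    yy: float
    n: int
    positions: np.ndarray

    @classmethod
    def build(
        cls, y: np.ndarray, x: np.ndarray, positions: np.ndarray | None = None
    ) -> "GeneSuffStats":
        y = np.asarray(y, dtype=np.float64)
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        pos = (
            np.arange(x.shape[1], dtype=np.int64)
            if positions is None
            else np.asarray(positions, dtype=np.int64)
        )
        return cls(G=x.T @ x, c=x.T @ y, yy=float(y @ y), n=y.shape[0], positions=pos)

    @property
    def p(self) -> int:
        return self.G.shape[0]

    def with_cross(self, c: np.ndarray) -> "GeneSuffStats":
        """Same gene, different phenotype cross-products (permutations)."""
        return GeneSuffStats(self.G, c, self.yy, self.n, self.positions)


# ---------------------------------------------------------------------------
# score components
# ---------------------------------------------------------------------------

def log_model_prior(k: int, t: float) -> float:
    """Log prior of model size ``k`` given ``t`` effective tests.

    ``ln B(k+1, t-k+1)``; for integer ``t`` this equals
    ``ln[1 / ((t+1) C(t,k))]`` and the prior sums to one over k = 0..t.
    When ``k`` exceeds ``t`` the second Beta argument is clamped at a small
    positive floor (the search itself never proposes k > t+1).
    """
    if k < 0 or t < 0:
        raise ValueError("k and t must be non-negative")
    return float(betaln(k + 1, max(t - k + 1, BETA_ARG_FLOOR)))


def log_model_score(fit: RegressionFit | float, k: int, t: float, n: int | None = None) -> float:
    """Selection objective: prior + BIC penalty + profile log-likelihood.

    Accepts either a :class:`RegressionFit` or a raw SSE (with ``n``).
    A perfect fit (SSE = 0) returns ``+inf``: it dominates every
    competitor, which is the correct limit of the objective.
    """
    if isinstance(fit, RegressionFit):
        sse, n = fit.sse, fit.n
    else:
        sse = float(fit)
        if n is None:
            raise ValueError("n is required when passing a raw SSE")
    if sse < 0:
        raise ValueError("negative SSE")
    if sse == 0.0:
        return np.inf
    return log_model_prior(k, t) - 0.5 * k * np.log(n) - 0.5 * n * np.log(sse)


def _score_vector(sse: np.ndarray, k: int, t: float, n: int) -> np.ndarray:
    """Vectorized ``log_model_score`` over an array of SSE values."""
    prior = log_model_prior(k, t) - 0.5 * k * np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = prior - 0.5 * n * np.log(np.maximum(sse, 0.0))
    out = np.where(sse <= 0.0, np.inf, out)
    return out


# ---------------------------------------------------------------------------
# regression on subsets
# ---------------------------------------------------------------------------

def _fit_from_suff(suff: GeneSuffStats, subset: list[int]) -> RegressionFit:
    subset = list(subset)
    if not subset:
        return RegressionFit([], np.empty(0), suff.yy, suff.yy, suff.n)
    Gss = suff.G[np.ix_(subset, subset)]
    cs = suff.c[subset]
    try:
        L = np.linalg.cholesky(Gss)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"rank-deficient subset {subset}") from exc
    # guard near-singularity that Cholesky tolerates numerically
    if np.min(np.diag(L)) ** 2 <= COLLINEAR_TOL * np.max(np.diag(Gss)):
        raise DegenerateFitError(f"near-collinear subset {subset}")
    u = solve_triangular(L, cs, lower=True)
    b = solve_triangular(L.T, u, lower=False)
    sse = max(suff.yy - float(u @ u), 0.0)
    return RegressionFit(subset, b, sse, suff.yy, suff.n)


def fit_subset(y, x, subset) -> RegressionFit:
    """OLS of the centered trait on the given SNP columns, no intercept.

    ``y`` and ``x`` may be :class:`Phenotype` / :class:`GenotypeMatrix`
    or plain arrays.  Raises :class:`DegenerateFitError` for a
    rank-deficient subset.
    """
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    xv = x.dosages if isinstance(x, GenotypeMatrix) else np.asarray(x, dtype=float)
    if xv.ndim == 1:
        xv = xv[:, None]
    suff = GeneSuffStats.build(yv, xv)
    return _fit_from_suff(suff, list(subset))


def f_statistic_add_one(fit_k: RegressionFit, fit_k_plus_1: RegressionFit) -> float:
    """F statistic for adding one SNP to a nested model.

    ``F = (SSE_k - SSE_{k+1}) / (SSE_{k+1} / (n - k - 2))`` with one
    numerator degree of freedom; used by the univariate comparators and
    the parametric fallback, not by the model search itself.
    """
    if fit_k_plus_1.k != fit_k.k + 1 or fit_k.n != fit_k_plus_1.n:
        raise ValueError("fits must be nested with exactly one extra SNP")
    df = fit_k.n - fit_k.k - 2
    if fit_k_plus_1.sse <= 0.0:
        return np.inf
    return max(fit_k.sse - fit_k_plus_1.sse, 0.0) / (fit_k_plus_1.sse / df)


# ---------------------------------------------------------------------------
# greedy / subset search on sufficient statistics
# ---------------------------------------------------------------------------

def _greedy_step(
    suff: GeneSuffStats,
    selected: list[int],
    L: np.ndarray,
    u: np.ndarray,
    sse: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate SSEs after adding each remaining SNP to ``selected``.

    Returns (candidate indices, their new SSE, their residual variance d);
    candidates with d ~ 0 (collinear with the current span) are excluded.
    """
    mask = np.ones(suff.p, dtype=bool)
    mask[selected] = False
    cand = np.flatnonzero(mask)
    diag = np.diag(suff.G)
    if len(selected):
        Z = solve_triangular(L, suff.G[np.ix_(selected, cand)], lower=True)
        d = diag[cand] - (Z * Z).sum(axis=0)
        num = suff.c[cand] - Z.T @ u
    else:
        d = diag[cand].astype(float)
        num = suff.c[cand].astype(float)
    ok = d > COLLINEAR_TOL * np.maximum(diag[cand], 1.0)
    cand, d, num = cand[ok], d[ok], num[ok]
    sse_new = np.maximum(sse - num * num / d, 0.0)
    return cand, sse_new, d


def _append_to_cholesky(
    suff: GeneSuffStats, selected: list[int], L: np.ndarray, u: np.ndarray, j: int
) -> tuple[np.ndarray, np.ndarray]:
    if len(selected):
        z = solve_triangular(L, suff.G[selected, j], lower=True)
        dj = suff.G[j, j] - float(z @ z)
        root = np.sqrt(max(dj, 0.0))
        L_new = np.zeros((len(selected) + 1,) * 2)
        L_new[:-1, :-1] = L
        L_new[-1, :-1] = z
        L_new[-1, -1] = root
        u_new = np.append(u, (suff.c[j] - float(z @ u)) / root)
    else:
        root = np.sqrt(suff.G[j, j])
        L_new = np.array([[root]])
        u_new = np.array([suff.c[j] / root])
    return L_new, u_new


def _argbest(cand: np.ndarray, scores: np.ndarray, positions: np.ndarray) -> int:
    """Index into ``cand`` of the best score; ties to lowest coordinate."""
    best = scores.max()
    tied = np.flatnonzero(scores >= best)
    order = np.argmin(positions[cand[tied]])
    return int(tied[order])


def _greedy_from(
    suff: GeneSuffStats,
    t: float,
    initial: list[int],
    force_first: bool = False,
) -> ModelScore:
    """Greedy forward search continuing from ``initial`` (possibly empty).

    With ``force_first`` and an empty start, the best single SNP is added
    unconditionally before the improve-only loop; the returned model is
    then the best along the k >= 1 path even if the null scores higher
    (callers that need the null comparison make it themselves).
    """
    n = suff.n
    k_max = int(np.floor(t)) + 1
    selected = list(initial)
    if selected:
        fit0 = _fit_from_suff(suff, selected)
        Gss = suff.G[np.ix_(selected, selected)]
        L = np.linalg.cholesky(Gss)
        u = solve_triangular(L, suff.c[selected], lower=True)
        sse = fit0.sse
    else:
        L = np.zeros((0, 0))
        u = np.zeros(0)
        sse = suff.yy
    current = log_model_score(sse, len(selected), t, n)

    first = force_first and not selected
    while len(selected) < min(k_max, suff.p):
        cand, sse_new, _ = _greedy_step(suff, selected, L, u, sse)
        if cand.size == 0:
            break
        scores = _score_vector(sse_new, len(selected) + 1, t, n)
        pick = _argbest(cand, scores, suff.positions)
        if not first and not scores[pick] > current:
            break
        j = int(cand[pick])
        L, u = _append_to_cholesky(suff, selected, L, u, j)
        selected.append(j)
        sse = float(sse_new[pick])
        current = scores[pick]
        first = False
    fit = RegressionFit(
        selected,
        _fit_from_suff(suff, selected).b_hat if selected else np.empty(0),
        sse,
        suff.yy,
        n,
    )
    return ModelScore(len(selected), selected, current, fit)


def greedy_search(
    y, x_gene, t: float, positions: np.ndarray | None = None
) -> ModelScore:
    """Greedy forward model selection for one gene.

    Starts from the null model and adds, at each step, the SNP whose
    inclusion maximizes the score, as long as the score strictly
    increases; SNPs collinear with the current model are skipped and ties
    go to the lowest genomic coordinate.  May return the null model
    (k = 0), the typical outcome for unassociated genes and permuted
    phenotypes.
    """
    suff = _as_suff(y, x_gene, positions)
    return _greedy_from(suff, t, [])


def subset_search(
    y,
    x_gene,
    t: float,
    init_size: int = 2,
    positions: np.ndarray | None = None,
    max_p_for_triples: int = 500,
) -> ModelScore:
    """Exhaustive small-subset initialization followed by greedy growth.

    Evaluates every subset of ``init_size`` SNPs (2 or 3), continues
    greedily from the best, and returns the better of that and the plain
    greedy result.  Exists for suppression-style genes where every
    single-SNP model scores below the null yet a joint model wins.  Falls
    back to plain greedy when the gene has fewer than ``init_size`` SNPs.
    """
    from itertools import combinations

    if init_size not in (2, 3):
        raise ValueError("init_size must be 2 or 3")
    suff = _as_suff(y, x_gene, positions)
    greedy = _greedy_from(suff, t, [])
    if suff.p < init_size:
        return greedy
    if init_size == 3 and suff.p > max_p_for_triples:
        raise ValueError(
            f"refusing all-triples search over {suff.p} SNPs "
            f"(cap {max_p_for_triples})"
        )
    best_init: list[int] | None = None
    best_init_score = -np.inf
    for combo in combinations(range(suff.p), init_size):
        try:
            fit = _fit_from_suff(suff, list(combo))
        except DegenerateFitError:
            continue
        s = log_model_score(fit, init_size, t)
        if s > best_init_score:
            best_init_score = s
            best_init = list(combo)
    if best_init is None:
        return greedy
    grown = _greedy_from(suff, t, best_init)
    null_score = log_model_score(suff.yy, 0, t, suff.n)
    candidates = [greedy, grown]
    if null_score >= grown.log_score and null_score >= greedy.log_score:
        return greedy if greedy.k == 0 else ModelScore(
            0, [], null_score, RegressionFit([], np.empty(0), suff.yy, suff.yy, suff.n)
        )
    return max(candidates, key=lambda m: m.log_score)


def _as_suff(y, x, positions) -> GeneSuffStats:
    if isinstance(y, GeneSuffStats):
        return y
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    xv = x.dosages if isinstance(x, GenotypeMatrix) else np.asarray(x, dtype=float)
    return GeneSuffStats.build(yv, xv, positions)


# ---------------------------------------------------------------------------
# model / results API
# ---------------------------------------------------------------------------

class GwisModel:
    """Gene-wide association model for a quantitative trait.

    Parameters
    ----------
    phenotype
        :class:`Phenotype` or 1-D array of trait values (centered
        internally if needed).
    genotypes
        :class:`GenotypeMatrix` or 2-D dosage array for the SNPs under
        consideration (one gene's worth).
    gene
        Optional :class:`GeneRegion`; restricts the matrix to the gene's
        assigned SNPs and records coordinates for tie-breaking.
    effective_tests
        The effective test count T; computed from the dosage correlations
        when not supplied.

    Examples
    --------
    >>> model = GwisModel(y, x_gene)
    >>> res = model.fit()
    >>> res.k, res.selected_ids, res.log_score  # doctest: +SKIP
    """

    def __init__(
        self,
        phenotype,
        genotypes,
        gene: GeneRegion | None = None,
        effective_tests: float | None = None,
    ):
        from .ld import effective_tests as _eff, pairwise_correlation

        if isinstance(genotypes, GenotypeMatrix):
            gm = genotypes.take_variants(gene.snp_indices) if gene is not None else genotypes
            x = gm.dosages
            positions = gm.variants["pos"].to_numpy(dtype=np.int64)
            self.snp_ids = gm.variants["id"].to_numpy()
        else:
            x = np.asarray(genotypes, dtype=float)
            if x.ndim == 1:
                x = x[:, None]
            positions = np.arange(x.shape[1], dtype=np.int64)
            self.snp_ids = np.array([f"snp{i}" for i in range(x.shape[1])])
        yv = phenotype.values if isinstance(phenotype, Phenotype) else np.asarray(
            phenotype, dtype=float
        )
        if yv.shape[0] != x.shape[0]:
            raise ValueError("phenotype and genotypes differ in length")
        yv = yv - yv.mean()
        x = x - x.mean(axis=0, keepdims=True)
        self.endog = yv
        self.exog = x
        self.positions = positions
        self.gene = gene
        if effective_tests is None:
            corr = pairwise_correlation(x)
            effective_tests = _eff(corr, positions).t
        self.t = float(effective_tests)
        self.suff = GeneSuffStats.build(yv, x, positions)

    @classmethod
    def from_dataframe(cls, data, pheno_col: str, snp_cols: list[str] | None = None):
        """Build from a tidy DataFrame of one row per individual."""
        import pandas as pd

        df = pd.DataFrame(data)
        if snp_cols is None:
            snp_cols = [c for c in df.columns if c != pheno_col]
        model = cls(df[pheno_col].to_numpy(float), df[snp_cols].to_numpy(float))
        model.snp_ids = np.asarray(snp_cols)
        return model

    @property
    def nobs(self) -> int:
        return self.suff.n

    def fit(self, method: str = "greedy", init_size: int = 2) -> "GwisResults":
        """Run the model search and return a results object."""
        if method == "greedy":
            best = _greedy_from(self.suff, self.t, [])
        elif method == "subset":
            best = subset_search(
                self.suff, None, self.t, init_size=init_size
            )
        else:
            raise ValueError("method must be 'greedy' or 'subset'")
        return GwisResults(self, best)


class GwisResults:
    """Results of gene-wide model selection.

    Carries the selected model (size ``k``, SNP indices/ids, coefficient
    estimates), the log score, fit diagnostics, the parametric p-value
    and — via :meth:`permutation_pvalue` — the empirical permutation
    p-value that is the method's actual significance measure.
    """

    def __init__(self, model: GwisModel, best: ModelScore):
        self.model = model
        self._best = best
        self.k = best.k
        self.selected = list(best.selected)
        self.log_score = best.log_score
        self.fit_result = best.fit

    @property
    def params(self) -> np.ndarray:
        return self.fit_result.b_hat

    @property
    def bse(self) -> np.ndarray:
        """Naive OLS standard errors of the selected coefficients.

        Post-selection inference caveat applies: these ignore the search
        over SNPs and are descriptive only; use permutation p-values for
        significance.
        """
        if not self.selected:
            return np.empty(0)
        sub = self.selected
        Ginv = np.linalg.inv(self.model.suff.G[np.ix_(sub, sub)])
        df = self.nobs - self.k - 1
        s2 = self.fit_result.sse / max(df, 1)
        return np.sqrt(s2 * np.diag(Ginv))

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def selected_ids(self) -> list[str]:
        return [str(self.model.snp_ids[j]) for j in self.selected]

    @property
    def sse(self) -> float:
        return self.fit_result.sse

    @property
    def sst(self) -> float:
        return self.fit_result.sst

    @property
    def rsquared(self) -> float:
        return 1.0 - self.sse / self.sst

    @property
    def f_overall(self) -> float:
        """Overall F statistic of the selected model vs the null."""
        if self.k == 0:
            return 0.0
        df2 = self.nobs - self.k - 1
        return (self.fit_result.ssm / self.k) / (self.sse / df2)

    @property
    def pvalue_parametric(self) -> float:
        from .significance import parametric_pvalue_gwis

        return parametric_pvalue_gwis(self.fit_result, self.k, self.model.t)

    def permutation_pvalue(self, config=None):
        """Empirical p-value by adaptive phenotype permutation."""
        from .significance import (
            GwisScoreStatistic,
            PermutationConfig,
            gene_empirical_pvalue,
        )

        config = config or PermutationConfig()
        stat = GwisScoreStatistic(self.model.t)
        return gene_empirical_pvalue(
            stat,
            self.model.endog,
            self.model.exog,
            config,
            positions=self.model.positions,
        )

    def summary(self) -> str:
        """Plain-text summary table of the selected model."""
        lines = [
            "Gene-wide model selection results",
            "=" * 46,
            f"No. observations : {self.nobs}",
            f"SNPs in gene     : {self.model.suff.p}",
            f"Effective tests T: {self.model.t:.3f}",
            f"Selected size K  : {self.k}",
            f"Log score        : {self.log_score:.4f}",
            f"R-squared        : {self.rsquared:.5f}",
            f"Parametric p     : {self.pvalue_parametric:.3g}",
            "-" * 46,
        ]
        if self.selected:
            lines.append(f"{'SNP':<16}{'coef':>12}{'std err':>12}")
            for sid, b, se in zip(self.selected_ids, self.params, self.bse):
                lines.append(f"{sid:<16}{b:>12.5f}{se:>12.5f}")
        else:
            lines.append("Null model selected (no SNP improves the score).")
        lines.append("=" * 46)
        return "\n".join(lines)
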