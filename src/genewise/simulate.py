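"""Synthetic genotypes, phenotypes, and the power / model-size studies.

Real cohort genotypes are access-controlled, so the experiments run on
synthetic stand-ins that reproduce the features the methods are sensitive
to: block LD (equicorrelated latent haplotypes thresholded at MAF-matched
quantiles and summed to dosages in {0, 1, 2}), minor-allele frequencies
down to rare variants, and additive quantitative-trait effects with
standard-normal residuals.  Defaults mirror the study conditions: a few
thousand individuals, genes of tens of SNPs, and per-gene variance
explained around 0.007.

Two effect-size constructions are provided: splitting a fixed total
variance equally across causal SNPs (with an exact rescale so the causal
set explains the target variance), and inverting the univariate
normal-approximation power formula so each causal SNP individually has a
chosen detection power at a chosen significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

from .data import GenotypeMatrix, Phenotype, _folded_maf

__all__ = [
    "LdBlockSpec",
    "TrueModel",
    "GeneSkipped",
    "simulate_ld_genotypes",
    "simulate_no_ld_genotypes",
    "select_causal_snps",
    "effects_equal_variance",
    "effects_from_power",
    "simulate_phenotype",
    "power_experiment",
    "model_size_experiment",
]


class GeneSkipped(RuntimeError):
    """No valid causal-SNP set exists for this gene; redraw it."""


@dataclass
class LdBlockSpec:
    """LD layout for one synthetic gene.

    Two latent-correlation structures are available.  ``"block"``:
    ``block_sizes`` must sum to ``n_snps`` and within a block the latent
    haplotype values share a common factor with correlation ``rho``
    (between blocks everything is independent).  ``"decay"``: the latents
    follow an AR(1) chain with neighbor correlation ``rho``, so
    correlation falls off as ``rho**distance`` — the smoother profile of
    real haplotype data, where one marker can partially tag two others
    that are nearly independent of each other.  MAFs are drawn uniformly
    from ``maf_range``.  SNPs are laid out ``spacing`` bp apart on the
    given chromosome starting at ``start_pos``.
    """

    n_snps: int = 20
    block_sizes: list[int] = field(default_factory=list)
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    structure: str = "block"
    mafs: np.ndarray | None = None  # per-SNP MAFs overriding maf_range
    chromosome: str = "1"
    start_pos: int = 1_000_000
    spacing: int = 1_000

    def __post_init__(self) -> None:
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (self.n_snps,):
                raise ValueError("mafs must have length n_snps")
        if self.structure not in ("block", "decay"):
            raise ValueError("structure must be 'block' or 'decay'")
        if not self.block_sizes:
            size = 5
            sizes = [size] * (self.n_snps // size)
            if self.n_snps % size:
                sizes.append(self.n_snps % size)
            self.block_sizes = sizes
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError("block sizes must sum to n_snps")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class TrueModel:
    """The planted causal model of one simulated gene."""

    causal_indices: np.ndarray
    effects: np.ndarray
    total_variance: float
    per_snp_variance: np.ndarray

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        self.per_snp_variance = np.asarray(self.per_snp_variance, dtype=float)


from functools import lru_cache


@lru_cache(maxsize=4096)
def _latent_rho(target_r: float, maf: float) -> float:
    """Latent-normal correlation giving dosage correlation ``target_r``.

    Alleles are thresholded latent normals, so their correlation is the
    tetrachoric-attenuated version of the latent one; this inverts the
    attenuation (at a representative MAF) by bisection on the bivariate
    normal orthant probability.  Cached: callers quantize the MAF.
    """
    if target_r <= 0.0:
        return 0.0
    from scipy.stats import multivariate_normal

    h = norm.ppf(maf)
    denom = maf * (1.0 - maf)
    mean = np.zeros(2)

    def dosage_corr(rho: float) -> float:
        p11 = multivariate_normal.cdf(
            [h, h], mean=mean, cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf * maf) / denom

    lo, hi = 0.0, 0.9999
    if dosage_corr(hi) <= target_r:
        return hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if dosage_corr(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _variant_table(spec_mafs, chromosome, start_pos, spacing, dosages) -> pd.DataFrame:
    p = len(spec_mafs)
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(p)],
            "chrom": chromosome,
            "pos": start_pos + spacing * np.arange(p),
            "ref": "A",
            "alt": "G",
            "maf": [_folded_maf(dosages[:, j]) for j in range(p)],
            "imputed": False,
        }
    )


def simulate_ld_genotypes(
    spec: LdBlockSpec, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw block-correlated dosages for ``n`` individuals.

    Per haplotype, each block shares a latent factor with loading
    sqrt(rho); thresholding the latent normal at the MAF quantile yields
    alleles, and two independent haplotypes sum to the dosage.  Realized
    dosage correlations within a block approach ``rho`` for matched MAFs
    and attenuate when MAFs differ — the same attenuation real data show
    for rare variants, which cannot be strongly correlated with common
    ones.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    mafs = (
        spec.mafs.copy()
        if spec.mafs is not None
        else rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
    )
    thresholds = norm.ppf(mafs)
    dosage = np.zeros((n, spec.n_snps))
    # spec.rho is a dosage-scale LD target; thresholding attenuates the
    # latent correlation, so calibrate the latent scale at the typical MAF
    rho_latent = _latent_rho(round(spec.rho, 4), round(float(np.median(mafs)), 2))
    for _ in range(2):  # two haplotypes
        latent = np.empty((n, spec.n_snps))
        if spec.structure == "block":
            offset = 0
            for size in spec.block_sizes:
                shared = rng.standard_normal((n, 1))
                own = rng.standard_normal((n, size))
                latent[:, offset : offset + size] = (
                    np.sqrt(rho_latent) * shared + np.sqrt(1 - rho_latent) * own
                )
                offset += size
        else:  # AR(1) decay: corr(i, j) = rho_latent^|i-j| on the latent scale
            innov = rng.standard_normal((n, spec.n_snps))
            latent[:, 0] = innov[:, 0]
            scale = np.sqrt(1.0 - rho_latent**2)
            for j in range(1, spec.n_snps):
                latent[:, j] = rho_latent * latent[:, j - 1] + scale * innov[:, j]
        dosage += (latent < thresholds).astype(float)
    variants = _variant_table(
        mafs, spec.chromosome, spec.start_pos, spec.spacing, dosage
    )
    ids = np.array([f"ind{i + 1}" for i in range(n)])
    return GenotypeMatrix(dosage, variants, ids)


def simulate_no_ld_genotypes(
    p: int = 20,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n: int = 2000,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Independent binomial(2, maf) dosages: 20 SNPs/gene, no LD, by default."""
    if rng is None:
        rng = np.random.default_rng()
    if n < 2:
        raise ValueError("need at least 2 individuals")
    mafs = rng.uniform(maf_range[0], maf_range[1], size=p)
    dosage = rng.binomial(2, mafs, size=(n, p)).astype(float)
    variants = _variant_table(mafs, "1", 1_000_000, 1_000, dosage)
    ids = np.array([f"ind{i + 1}" for i in range(n)])
    return GenotypeMatrix(dosage, variants, ids)


def select_causal_snps(
    x_gene: np.ndarray | GenotypeMatrix,
    k: int,
    r2_cap: float = 0.2,
    rng: np.random.Generator | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    """Sample ``k`` causal SNPs that are mutually near-independent.

    Each selected SNP's squared multiple correlation with the other
    selected SNPs must stay below ``r2_cap`` (so the planted effects are
    genuinely independent signals).  Rejection sampling; raises
    :class:`GeneSkipped` when no valid set is found, and requires the gene
    to have at least 2k SNPs so a model of the true size remains possible
    after causal-SNP removal.
    """
    x = x_gene.dosages if isinstance(x_gene, GenotypeMatrix) else np.asarray(x_gene)
    if rng is None:
        rng = np.random.default_rng()
    p = x.shape[1]
    if p < 2 * k:
        raise GeneSkipped(f"gene has {p} SNPs; needs >= {2 * k} for k={k}")
    if k == 1:
        return np.sort(rng.choice(p, size=1, replace=False))
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    if usable.size < k:
        raise GeneSkipped("not enough polymorphic SNPs")
    corr = np.corrcoef(xc[:, usable], rowvar=False)
    for _ in range(max_retries):
        pick = np.sort(rng.choice(usable.size, size=k, replace=False))
        sub = corr[np.ix_(pick, pick)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            continue
        r2_multiple = 1.0 - 1.0 / np.diag(prec)
        if (r2_multiple < r2_cap).all():
            return usable[pick]
    raise GeneSkipped(f"no causal set with mutual r2 < {r2_cap} after {max_retries} draws")


def effects_equal_variance(sigma: np.ndarray, k: int, v: float) -> np.ndarray:
    """Effect sizes splitting total variance ``v`` equally over ``k`` SNPs.

    Initial effects are proportional to ``1/sqrt(k * sigma_ii)`` (equal
    marginal contributions), then rescaled so that ``b' Sigma b = v``
    exactly, accounting for LD among the causal SNPs.
    """
    sigma = np.asarray(sigma, dtype=float)
    if v <= 0:
        raise ValueError("v must be > 0")
    diag = np.diag(sigma)
    if (diag <= 0).any():
        raise ValueError("singular genotype covariance for causal set")
    b = 1.0 / np.sqrt(k * diag)
    scale2 = v / float(b @ sigma @ b)
    return b * np.sqrt(scale2)


def effects_from_power(
    sigma_ii: float, power: float, alpha: float = 5e-8, n: int = 8000
) -> tuple[float, float]:
    """Per-SNP variance and effect giving a chosen univariate power.

    Inverts the two-sided normal-approximation power formula:
    ``v = (z_{1-alpha/2} + z_power)^2 / n`` with ``z`` standard-normal
    quantiles, then ``b = sqrt(v / sigma_ii)``.  The variance is
    controlled per SNP, not per gene, so no LD rescaling is applied.
    """
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    z_alpha = norm.isf(alpha / 2)
    z_power = norm.ppf(power)
    v = (z_alpha + z_power) ** 2 / n
    return float(v), float(np.sqrt(v / sigma_ii))


def simulate_phenotype(
    x: GenotypeMatrix | np.ndarray,
    model: TrueModel,
    rng: np.random.Generator,
) -> Phenotype:
    """Additive trait: centered causal dosages times effects plus N(0,1)."""
    d = x.dosages if isinstance(x, GenotypeMatrix) else np.asarray(x, dtype=float)
    n = d.shape[0]
    xc = d[:, model.causal_indices]
    xc = xc - xc.mean(axis=0, keepdims=True)
    values = xc @ model.effects + rng.standard_normal(n)
    ids = (
        x.individual_ids
        if isinstance(x, GenotypeMatrix)
        else np.array([f"ind{i + 1}" for i in range(n)])
    )
    return Phenotype(ids, values)


def plant_effects(
    genotypes: GenotypeMatrix,
    k_true: int,
    rng: np.random.Generator,
    v_total: float | None = None,
    power: float | None = None,
    alpha: float = 5e-8,
    r2_cap: float = 0.2,
) -> TrueModel:
    """Choose causal SNPs and effects under either simulation design."""
    x = genotypes.dosages
    causal = select_causal_snps(x, k_true, r2_cap=r2_cap, rng=rng)
    xc = x[:, causal] - x[:, causal].mean(axis=0, keepdims=True)
    sigma = xc.T @ xc / x.shape[0]
    if v_total is not None:
        b = effects_equal_variance(sigma, k_true, v_total)
        per_snp = b**2 * np.diag(sigma)
        total = v_total
    elif power is not None:
        vs, bs = zip(
            *(effects_from_power(sii, power, alpha, x.shape[0]) for sii in np.diag(sigma))
        )
        b = np.asarray(bs)
        per_snp = np.asarray(vs)
        total = float(b @ sigma @ b)
    else:
        raise ValueError("provide v_total or power")
    return TrueModel(causal, b, total, per_snp)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _binomial_ci(successes: int, n: int) -> tuple[float, float]:
    ci = binomtest(successes, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def power_experiment(
    gene_pvalue,
    k_true: int,
    v: float = 0.007,
    n_genes: int = 1000,
    threshold: float = 5e-8,
    n: int = 8000,
    spec: LdBlockSpec | None = None,
    rng: np.random.Generator | None = None,
    r2_cap: float = 0.2,
) -> tuple[float, tuple[float, float]]:
    """Fraction of simulated genes reaching significance, with exact CI.

    Per replicate: draw a gene's genotypes, plant ``k_true`` causal
    effects sharing total variance ``v``, simulate the trait, call
    ``gene_pvalue(y, x, rng)``, and count p <= threshold.  Returns the
    power and its 95% exact binomial confidence interval.
    """
    if rng is None:
        rng = np.random.default_rng()
    spec = spec or LdBlockSpec()
    hits = 0
    done = 0
    while done < n_genes:
        gm = simulate_ld_genotypes(spec, n, rng)
        try:
            model = plant_effects(gm, k_true, rng, v_total=v, r2_cap=r2_cap)
        except GeneSkipped:
            continue
        y = simulate_phenotype(gm, model, rng)
        p = gene_pvalue(y.values, gm.dosages, rng)
        hits += int(p <= threshold)
        done += 1
    return hits / n_genes, _binomial_ci(hits, n_genes)


def model_size_experiment(
    power_level: float,
    k_true_values=range(0, 11),
    n_genes: int = 100,
    remove_causal: bool = False,
    n: int = 8000,
    alpha: float = 5e-8,
    spec: LdBlockSpec | None = None,
    rng: np.random.Generator | None = None,
    r2_cap: float = 0.2,
) -> pd.DataFrame:
    """Recovery of the planted model size by greedy selection.

    For each true size, simulate ``n_genes`` genes whose causal SNPs each
    carry the same univariate detection power, run the model search, and
    record the selected size; optionally delete the causal columns first,
    leaving only LD proxies.  Returns a tidy frame of
    ``(k_true, replicate, k_estimated, removed)``.
    """
    from .ld import effective_tests as _efft, pairwise_correlation
    from .model import greedy_search

    if rng is None:
        rng = np.random.default_rng()
    spec = spec or LdBlockSpec(n_snps=30, rho=0.8)
    rows = []
    for k_true in k_true_values:
        done = 0
        while done < n_genes:
            gm = simulate_ld_genotypes(spec, n, rng)
            if k_true == 0:
                y = Phenotype(gm.individual_ids, rng.standard_normal(n))
                x = gm.dosages
                positions = gm.variants["pos"].to_numpy()
            else:
                try:
                    model = plant_effects(
                        gm, k_true, rng, power=power_level, alpha=alpha, r2_cap=r2_cap
                    )
                except GeneSkipped:
                    continue
                y = simulate_phenotype(gm, model, rng)
                keep = (
                    np.setdiff1d(np.arange(gm.n_variants), model.causal_indices)
                    if remove_causal
                    else np.arange(gm.n_variants)
                )
                x = gm.dosages[:, keep]
                positions = gm.variants["pos"].to_numpy()[keep]
            xc = x - x.mean(axis=0, keepdims=True)
            t = _efft(pairwise_correlation(xc), positions).t
            best = greedy_search(y.values - y.values.mean(), xc, t, positions)
            rows.append(
                {
                    "k_true": int(k_true),
                    "replicate": done,
                    "k_estimated": best.k,
                    "removed": remove_causal,
                }
            )
            done += 1
    return pd.DataFrame(rows)
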