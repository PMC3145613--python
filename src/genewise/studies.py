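"""Down-scaled evaluation studies for the gene-based tests.

Each function runs one self-contained simulation study at desk scale and
returns plain numbers.  The conditions — sample sizes, LD layouts, effect
calibrations, permutation budgets — are the package's reference study
conditions and are documented in the methods note; they are deliberately
fixed here rather than exposed as knobs, so that reported results always
refer to the same experiment.

Two significance scales appear throughout:

* ``ALPHA_UNIVARIATE = 5e-8`` — the conventional univariate genome-wide
  threshold, used to calibrate the *total* variance of a strong gene
  (single-SNP detection power 0.8);
* ``ALPHA_DESK = 1e-3`` — the down-scaled stand-in for a genome-wide
  threshold that the desk-scale permutation budgets can actually resolve,
  used to calibrate *per-SNP* effects in the model-size and
  MAF-robustness studies.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, pearsonr, spearmanr, wilcoxon

from .comparators import vegas_stat
from .ld import effective_tests, pairwise_correlation
from .model import greedy_search
from .significance import (
    BestFStatistic,
    GwisScoreStatistic,
    MeanBayesFactorStatistic,
    PermutationConfig,
    gene_empirical_pvalue,
    parametric_pvalue_gwis,
)
from .simulate import (
    GeneSkipped,
    LdBlockSpec,
    TrueModel,
    _binomial_ci,
    effects_from_power,
    model_size_experiment,
    plant_effects,
    simulate_ld_genotypes,
    simulate_phenotype,
)

ALPHA_UNIVARIATE = 5e-8
ALPHA_DESK = 1e-3

__all__ = [
    "null_calibration_study",
    "power_ordering_study",
    "maf_robustness_study",
    "model_size_study",
    "concordance_study",
    "parametric_empirical_study",
]


def _gene_t(x_centered: np.ndarray, positions: np.ndarray) -> float:
    return effective_tests(pairwise_correlation(x_centered), positions).t


def null_calibration_study(
    seed: int, n_genes: int = 500, n: int = 1000, max_trials: int = 2000
) -> dict:
    """Uniformity of empirical p-values under the null.

    Simulates unassociated genes (block LD, 15 SNPs), computes empirical
    p-values for the model-score, best-F and mean-Bayes-factor statistics,
    and returns the Kolmogorov-Smirnov p-value against Uniform(0, 1) for
    each (plus the mean p as a cruder location check).

    Uses the fixed-trial-count design (every gene runs the full
    permutation budget): the sequential stop-at-S-successes estimator is
    slightly conservative (upward-biased by ~1/S), which a uniformity
    test at this sample size would register even though it is harmless —
    indeed favorable — for significance calling.
    """
    rng = np.random.default_rng(seed)
    ps: dict[str, list] = {"gwis": [], "minsnp_p": [], "bimbam": []}
    for g in range(n_genes):
        gm = simulate_ld_genotypes(LdBlockSpec(n_snps=15, rho=0.8), n, rng)
        x = gm.dosages - gm.dosages.mean(0)
        y = rng.standard_normal(n)
        t = _gene_t(x, gm.variants["pos"].to_numpy())
        cfg = PermutationConfig(
            max_trials=max_trials, stop_successes=max_trials + 1, seed=seed
        )
        stats = {
            "gwis": GwisScoreStatistic(t),
            "minsnp_p": BestFStatistic(),
            "bimbam": MeanBayesFactorStatistic(),
        }
        for name, stat in stats.items():
            res = gene_empirical_pvalue(
                stat, y, x, cfg, rng=cfg.make_rng(g)
            )
            ps[name].append(
                res.p_empirical if res.successes else 1.0 / max_trials
            )
    out = {}
    for name, vals in ps.items():
        out[f"ks_p_{name}"] = float(kstest(vals, "uniform").pvalue)
        out[f"mean_p_{name}"] = float(np.mean(vals))
    return out


def power_ordering_study(
    seed: int,
    n_genes: int = 200,
    n: int = 2000,
    threshold: float = 5e-4,
    max_trials: int = 10_000,
    k_true_values: tuple[int, ...] = (1, 4),
) -> dict:
    """Power of the model-score test vs the best-SNP permutation test.

    Genes carry a fixed total variance — the amount that gives a lone
    causal SNP 80% detection power at the univariate genome-wide
    threshold — diluted over ``k_true`` causal SNPs.  Power is the
    fraction of genes whose empirical p reaches the study threshold;
    exact binomial 95% CIs are attached.
    """
    v_total = effects_from_power(1.0, 0.8, ALPHA_UNIVARIATE, n)[0]
    out: dict = {"v_total": v_total, "threshold": threshold}
    for k_true in k_true_values:
        rng = np.random.default_rng(seed + k_true)
        hits = {"gwis": 0, "minsnp_p": 0}
        done = 0
        while done < n_genes:
            gm = simulate_ld_genotypes(LdBlockSpec(n_snps=20, rho=0.8), n, rng)
            try:
                model = plant_effects(gm, k_true, rng, v_total=v_total)
            except GeneSkipped:
                continue
            y = simulate_phenotype(gm, model, rng).values
            x = gm.dosages - gm.dosages.mean(0)
            pos = gm.variants["pos"].to_numpy()
            t = _gene_t(x, pos)
            cfg = PermutationConfig(
                max_trials=max_trials, stop_successes=10, seed=seed
            )
            for name, stat in (
                ("gwis", GwisScoreStatistic(t)),
                ("minsnp_p", BestFStatistic()),
            ):
                res = gene_empirical_pvalue(
                    stat, y, x, cfg, positions=pos, rng=cfg.make_rng(k_true, done)
                )
                p = res.p_empirical if res.successes else 1.0 / max_trials
                hits[name] += int(p <= threshold)
            done += 1
        for name in hits:
            power = hits[name] / n_genes
            lo, hi = _binomial_ci(hits[name], n_genes)
            out[f"power_{name}_k{k_true}"] = power
            out[f"ci_{name}_k{k_true}"] = (lo, hi)
    return out


def maf_robustness_study(
    seed: int,
    genes_per_bin: int = 40,
    n: int = 2000,
    threshold: float = 0.01,
    max_trials: int = 2000,
    maf_bins: tuple[float, ...] = (0.05, 0.1, 0.2, 0.35, 0.5),
) -> dict:
    """Power as a function of the causal SNP's minor-allele frequency.

    One causal SNP with fixed variance explained (80% power at the
    desk-scale threshold) sits in a 20-SNP block-LD gene whose other
    SNPs are common; only the causal MAF varies across bins.  Permutation
    tests that key on the causal SNP itself should be flat in MAF, while
    the chi-square-sum test dilutes rare-variant signal (a rare SNP
    cannot be strongly correlated with its common neighbors) and loses
    power toward low MAF.  Returns per-bin powers and, per method, the
    p-value of the (point-biserial) MAF-power trend.
    """
    v = effects_from_power(1.0, 0.8, ALPHA_DESK, n)[0]
    rng = np.random.default_rng(seed)
    methods = ("gwis", "minsnp_p", "vegas")
    hits = {m: {mb: 0 for mb in maf_bins} for m in methods}
    mafs_used: list[float] = []
    outcomes: dict[str, list[int]] = {m: [] for m in methods}
    for mb in maf_bins:
        for g in range(genes_per_bin):
            other = rng.uniform(0.2, 0.5, 19)
            spec = LdBlockSpec(
                n_snps=20, rho=0.8, mafs=np.concatenate([[mb], other])
            )
            gm = simulate_ld_genotypes(spec, n, rng)
            sigma_ii = gm.dosages[:, 0].var()
            model = TrueModel([0], [np.sqrt(v / sigma_ii)], v, [v])
            y = simulate_phenotype(gm, model, rng).values
            x = gm.dosages - gm.dosages.mean(0)
            pos = gm.variants["pos"].to_numpy()
            t = _gene_t(x, pos)
            cfg = PermutationConfig(
                max_trials=max_trials, stop_successes=10, seed=seed
            )
            for name, stat in (
                ("gwis", GwisScoreStatistic(t)),
                ("minsnp_p", BestFStatistic()),
            ):
                res = gene_empirical_pvalue(
                    stat, y, x, cfg, positions=pos, rng=cfg.make_rng(int(mb * 1000), g)
                )
                p = res.p_empirical if res.successes else 1.0 / max_trials
                hit = int(p <= threshold)
                hits[name][mb] += hit
                outcomes[name].append(hit)
            p_vegas = vegas_stat(
                y, x, n_sim=2000, rng=np.random.default_rng(seed + 7919 * g + int(mb * 1e4))
            )
            hit = int(p_vegas <= threshold)
            hits["vegas"][mb] += hit
            outcomes["vegas"].append(hit)
            mafs_used.append(mb)
    out: dict = {}
    for m in methods:
        for mb in maf_bins:
            out[f"power_{m}_maf{mb}"] = hits[m][mb] / genes_per_bin
        r, p_trend = pearsonr(mafs_used, outcomes[m])
        out[f"trend_r_{m}"] = float(r)
        out[f"trend_p_{m}"] = float(p_trend)
    return out


def model_size_study(seed: int, n_genes_per_k: int = 13) -> dict:
    """Recovery of the planted number of independent effects.

    AR(1)-decay LD genes (60 SNPs, dosage rho 0.75, n = 2000); every
    causal SNP gets 80% univariate power at the desk-scale threshold;
    true sizes 1..8.  Run once with causal SNPs kept and once with them
    removed (identical gene draws via a shared seed).  Reports the mean
    estimated/true size ratio for both arms and the paired Wilcoxon
    p-value for the kept-vs-removed reduction.
    """
    spec = LdBlockSpec(n_snps=60, rho=0.75, structure="decay")
    kw = dict(
        k_true_values=range(1, 9),
        n_genes=n_genes_per_k,
        n=2000,
        spec=spec,
        alpha=ALPHA_DESK,
        r2_cap=0.5,
    )
    kept = model_size_experiment(
        0.8, remove_causal=False, rng=np.random.default_rng(seed), **kw
    )
    removed = model_size_experiment(
        0.8, remove_causal=True, rng=np.random.default_rng(seed), **kw
    )
    w = wilcoxon(kept.k_estimated, removed.k_estimated)
    return {
        "ratio_kept": float((kept.k_estimated / kept.k_true).mean()),
        "ratio_removed": float((removed.k_estimated / removed.k_true).mean()),
        "pooled_ratio_kept": float(kept.k_estimated.sum() / kept.k_true.sum()),
        "pooled_ratio_removed": float(
            removed.k_estimated.sum() / removed.k_true.sum()
        ),
        "wilcoxon_p": float(w.pvalue),
        "n_genes": int(len(kept)),
    }


def concordance_study(
    seed: int, n_genes: int = 200, n: int = 1000, max_trials: int = 4000
) -> dict:
    """Rank agreement between the Bayes-factor and best-SNP gene tests.

    Genes with signal strengths graded from null to strong; both methods
    get the same permutation streams.  Returns the Spearman correlation
    of the two p-value rankings.
    """
    rng = np.random.default_rng(seed)
    pm, pb = [], []
    for g in range(n_genes):
        gm = simulate_ld_genotypes(LdBlockSpec(n_snps=12, rho=0.7), n, rng)
        v = rng.uniform(0.0, 0.012)
        if v > 1e-4:
            j = int(rng.integers(0, 12))
            sii = gm.dosages[:, j].var()
            model = TrueModel([j], [np.sqrt(v / sii)], v, [v])
            y = simulate_phenotype(gm, model, rng).values
        else:
            y = rng.standard_normal(n)
        x = gm.dosages - gm.dosages.mean(0)
        cfg = PermutationConfig(max_trials=max_trials, stop_successes=10, seed=seed)
        r1 = gene_empirical_pvalue(BestFStatistic(), y, x, cfg, rng=cfg.make_rng(g, 0))
        r2 = gene_empirical_pvalue(
            MeanBayesFactorStatistic(), y, x, cfg, rng=cfg.make_rng(g, 1)
        )
        floor = 1.0 / max_trials
        pm.append(r1.p_empirical if r1.successes else floor)
        pb.append(r2.p_empirical if r2.successes else floor)
    return {"spearman_rho": float(spearmanr(pm, pb).statistic)}


def parametric_empirical_study(
    seed: int,
    n_genes: int = 100,
    n: int = 500,
    max_trials: int = 50_000,
    p_window: tuple[float, float] = (1e-3, 0.5),
) -> dict:
    """Agreement of the parametric fallback with the permutation p-value.

    Single-effect genes (8 SNPs, mild LD) with effect sizes spread so that
    many land with moderate significance; genes whose selected model is
    non-null and whose empirical p falls inside ``p_window`` contribute
    the ratio parametric/empirical.  Returns the worst-case ratio spread
    and the count of eligible genes.
    """
    rng = np.random.default_rng(seed)
    ratios = []
    for g in range(n_genes):
        gm = simulate_ld_genotypes(LdBlockSpec(n_snps=8, rho=0.5), n, rng)
        j = int(rng.integers(0, 8))
        v = rng.uniform(0.012, 0.045)
        sii = gm.dosages[:, j].var()
        model = TrueModel([j], [np.sqrt(v / sii)], v, [v])
        y = simulate_phenotype(gm, model, rng).values
        x = gm.dosages - gm.dosages.mean(0)
        pos = gm.variants["pos"].to_numpy()
        t = _gene_t(x, pos)
        best = greedy_search(y - y.mean(), x, t, pos)
        if best.k == 0:
            continue
        p_par = parametric_pvalue_gwis(best.fit, best.k, t)
        cfg = PermutationConfig(max_trials=max_trials, stop_successes=100, seed=seed)
        res = gene_empirical_pvalue(
            GwisScoreStatistic(t), y, x, cfg, positions=pos, rng=cfg.make_rng(g)
        )
        p_emp = res.p_empirical if res.successes else 1.0 / max_trials
        if p_window[0] <= p_emp <= p_window[1]:
            ratios.append(p_par / p_emp)
    ratios = np.asarray(ratios)
    return {
        "n_eligible": int(ratios.size),
        "ratio_min": float(ratios.min()) if ratios.size else np.nan,
        "ratio_max": float(ratios.max()) if ratios.size else np.nan,
        "ratio_median": float(np.median(ratios)) if ratios.size else np.nan,
    }
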