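# Methods

## The model

A gene region with P assigned SNPs and N individuals defines a family of
additive linear models for a quantitative trait. The trait vector **y**
and every dosage column of **X** are centered, so models have no
intercept. A model M is a subset of K SNPs permitted non-zero
coefficients:

    y = X_M b + e,   e ~ N(0, σ² I)

OLS on the centered data gives the maximum-likelihood fit; SST = y'y,
SSE the residual sum of squares. The selection objective for a model of
size K is

    score(M) = ln B(K+1, T−K+1) − (K/2)·ln N − (N/2)·ln SSE

with B the Beta function and T the effective number of independent tests
in the gene (below). The three terms are:

* **Model-size prior.** Assume each of the gene's "independent" SNPs is
  associated with unknown probability f, integrate f out under a uniform
  prior. Counting SNPs naively would make the prior depend on marker
  density, so the count is replaced by T; for integer T the per-model
  weight is 1/((T+1)·C(T,K)), and the Beta form extends it to real T.
  The weights of all models of one size sum to 1/(T+1), so the family is
  normalized over sizes 0..T.
* **Schwarz/BIC penalty** (K/2)·ln N for the integrated-out coefficient
  and scale parameters, keeping only terms of order ln N.
* **Profile likelihood** −(N/2)·ln SSE from the steepest-descents
  integral over σ.

Model-independent constants are dropped: scores are only ever compared
between models of the same gene and the same (possibly permuted)
phenotype, where N and SST are fixed. An empirical consequence worth
stating: selection is exactly invariant to rescaling the trait, because
the −(N/2)·ln SSE term shifts all models (including the null) by a
common constant.

The number K of the selected model is the estimate of the number of
independent association signals in the gene.

### Search

Exact optimization over subsets is combinatorial; the implementation is
greedy forward selection on Gram-matrix sufficient statistics (X'X, X'y,
y'y) with Cholesky updates: at each step the SNP with the maximal score
increase is added if the increase is strictly positive. Ties break to
the lowest genomic coordinate; candidates collinear with the current
model (residual variance below 1e−10 of their total) are skipped; the
model size is capped at floor(T)+1, inside the prior's support. An
optional variant enumerates all 2- or 3-SNP subsets as starting points
(and falls back to plain greedy when it cannot do better), which covers
suppression configurations where every 1-SNP model scores below the null
but a joint model wins; on realistic data the plain greedy search finds
the same associations and is the default.

### Effective number of tests

T is computed from the gene's Pearson dosage-correlation matrix by
weight stripping: all weights start at 1 and T at 0; repeatedly the SNP
with the largest weight is selected (ties to the lowest coordinate), its
weight is added to T and zeroed, and every other weight is reduced by
the squared correlation with the selected SNP, floored at 0 (weights
below 1e−12 count as 0, guaranteeing termination in floating point).
Correlations are not updated between rounds — a simplification that can
only overestimate T and therefore biases model selection conservative;
p-values are unaffected because they come from permutation. Duplicating
a SNP adds a weight that the first round strips to zero, so T — and with
it the prior — is insensitive to marker density. A zero-variance column
correlates 0 with everything and contributes a full unit.

## Significance

### Gene-level permutation p-values

The trait is shuffled (Fisher–Yates, numpy Generator) with genotypes
fixed, and the full statistic — including model-size selection — is
recomputed per permutation. The p-value is S/Q: successes S
(permutation statistic ≥ observed, ties counting as successes) over
trials Q. Permutations stop at 10 successes (the negative-binomial
stopping rule keeps S/Q unbiased) or at 1 million trials (configurable);
a gene with no success in the full budget is "exhausted", reported at
the 1/max-trials floor, and ranked by a parametric fallback.

One numerical subtlety is load-bearing. The greedy best score has an
atom at the null model: y'y is permutation-invariant, so every permuted
null model scores identically, and a "score ≥ observed" rule would
return p = 1 for every gene whose observed selection is null —
sub-uniform, not uniform. The test statistic is therefore the best score
over models with K ≥ 1 (greedy from the forced best single-SNP start)
minus the null score. This statistic is continuous under the null, so
empirical p-values are exactly uniform; the reported model is the null
whenever the statistic is non-positive, and rankings of significant
genes are unchanged.

Permutation batches are vectorized: a batch of shuffled traits enters as
cross-products C = X'Y_perm; the first greedy step for all permutations
is array arithmetic, the second step is grouped by the first selected
SNP, and only permutations whose search is still improving after two
steps (rare under the null) fall back to the scalar path.

### Parametric fallback

For an exhausted gene whose selected model has size K ≥ 1:

    p = Pr[F(K, N−K−1) ≥ F_MLE] × C(T, K)

the F-tail of the overall MLE fit times the generalized binomial
coefficient Γ(T+1)/(Γ(K+1)Γ(T−K+1)) counting models of the same size,
capped at 1. For K = 0 the fallback is 1. On single-effect genes this
tracks the empirical p-value within a factor of ~2 across the moderate
range (the acceptance suite measures this).

### Genome-wide thresholds

A second permutation stage shuffles the trait genome-wide, recomputes
every gene's p-value, and records the best per permutation; the
family-wise α threshold is the ceil(α·m)-th smallest of the m pooled
best values (e.g. the 15th of 300 at α = 0.05, pooling three traits of
100 permutations). Per-gene random streams derive from the master seed
and the (permutation, gene) indices, so results are independent of
evaluation order.

## Locus analysis

Strong LD can smear one signal over neighboring genes or split a causal
region between genes. Significant genes on one chromosome are
transitively merged when transcript-boundary gaps are ≤ 200 kb; the
merged SNP set is refitted (T recomputed); terminal genes containing no
selected SNP are trimmed, refitting until stable. A locus reduced to a
single gene keeps its original p-value; a multi-gene locus takes the
minimum of its members' p-values and its own merged-set permutation p —
a SNP assigned to two overlapping genes should not be penalized for the
overlap. Predictions are scored against a user-supplied known-positive
list: any partial overlap is a true positive, only the first hit per
known counts, and repeat hits are dropped from the ranking (neither TP
nor FP) — the least-distortionary reading of first-hit counting.

## Comparators

* **minSNP** — the gene inherits its best SNP's p-value; biased small
  under the null, so it needs its own (more stringent) genome-wide
  threshold.
* **minSNP-P** — gene-level permutation of the best univariate F;
  uniform under the null. Bonferroni fallback (best parametric p × SNP
  count) when exhausted.
* **BIMBAM-style** — mean over SNPs of the conjugate-normal single-SNP
  Bayes factor, permuted to a p-value. The BF compares
  y ~ N(μ1 + a x, σ²I) with priors μ ~ N(ȳ, σ²σ_μ²), a ~ N(0, σ²σ_a²)
  against a = 0, with the residual scale σ² plugged in as the phenotypic
  variance — so σ_a and σ_μ are in units of the phenotypic SD and the
  Bayes factor is a ratio of two closed-form Gaussian integrals
  (validated against 2-D quadrature). Defaults σ_a = 0.2, σ_μ = 1.0.
  σ_a = 0 collapses the alternative onto the null (BF = 1). The
  statistic enters the permutation machinery as ln(mean BF) — a monotone,
  overflow-safe transform that changes no rank and no p-value. In
  practice the mean is dominated by the best SNP, and rankings agree
  with minSNP-P at Spearman ρ > 0.95.
* **VEGAS-style** — sum over SNPs of 1-df chi-square quantiles of the
  univariate parametric p-values; the null distribution is simulated
  from N(0, R) draws (R the gene's sample dosage correlation matrix,
  eigenvalue-clipped to PSD), summing squares. Sample LD stands in for
  the reference-panel LD of the original formulation.

## Synthetic data

Real cohort genotypes are access-controlled; the generator emulates the
features the methods are sensitive to.

* **Genotypes.** Two latent-Gaussian haplotypes per individual,
  thresholded at the MAF quantile and summed to dosages {0,1,2}. Latent
  structure is either equicorrelated blocks (default: blocks of 5) or an
  AR(1) chain ("decay", correlation ρ^distance) — the smoother profile
  of real haplotypes, where one marker partially tags two others that
  are nearly independent of each other. The `rho` parameter is the
  dosage-scale LD target: thresholding attenuates latent correlation
  (tetrachoric relationship), so the latent correlation is calibrated by
  bisection at the block's median MAF. Correlations between SNPs of very
  different MAFs remain attenuated — as in real data, where a rare
  variant cannot be strongly correlated with a common one. A no-LD
  generator draws independent binomial(2, MAF) dosages (20 SNPs, MAF
  uniform on [0.05, 0.5] by default).
* **Phenotypes.** y = (x − mean)·b + ε with ε standard normal; the
  sample mean stands in for the population mean (the difference is
  negligible at the sample sizes used). Causal SNPs are sampled subject
  to a cap on each one's squared multiple correlation with the others
  (default 0.2), by rejection.
* **Effect sizes.** Either a fixed total gene variance v split equally —
  b_i ∝ 1/√(K σ_ii), exactly rescaled so b'Σb = v — or per-SNP variance
  from the two-sided normal power inversion
  v_i = (z_{1−α/2} + z_power)²/N, b_i = √(v_i/σ_ii), with no LD rescale
  (variance is controlled per SNP, not per gene).

What the generator does not emulate: genuine haplotype mosaics and
recombination hotspots, genotyping/imputation error, population
structure, non-Gaussian trait residuals, and the long-tailed gene-size
distribution of a real genome. Passing tests therefore demonstrate the
statistical machinery under controlled LD, not cohort-level numbers;
results that depend on a specific cohort's LD (absolute power values,
absolute recovery counts) are reproduced qualitatively (orderings,
conservativeness), not numerically.

## Reference study conditions (desk scale)

Fixed once in `genewise.studies`; chosen to finish in minutes on one
CPU while probing the same regimes as the full-scale experiments. Two
significance scales appear: α = 5e−8 (the univariate genome-wide
convention) calibrates the *total* variance of a "strong gene"
(single-SNP power 0.8 → v ≈ 0.0198 at N = 2000, total noncentrality
≈ 40); α = 1e−3 is the desk-scale genome-wide stand-in that the
permutation budgets can resolve, and calibrates *per-SNP* effects where
the interesting behavior lives near the selection threshold.

* Null calibration: 500 unassociated 15-SNP genes, N = 1000, 2000
  permutations; KS uniformity per statistic.
* Power ordering: 200 genes/condition, N = 2000, 20-SNP block-LD genes
  (ρ = 0.8), total v as above diluted over K_true ∈ {1, 4}; significance
  at 5e−4 with 10⁴ permutations.
* MAF robustness: one causal SNP (fixed v, 80% power at α = 1e−3) in a
  20-SNP block gene of common SNPs; causal MAF ∈ {0.05, 0.1, 0.2, 0.35,
  0.5}, 40 genes per bin, hits at p ≤ 0.01; point-biserial trend test.
* Model size: 60-SNP decay-LD genes (ρ = 0.75), N = 2000, per-SNP
  effects at 80% power (α = 1e−3), causal mutual-r² cap 0.5 (the looser
  cap admits the correlated causal sets dense real LD contains), K_true
  1..8 × 13 genes, kept vs removed causal columns with shared draws for
  pairing. With effects calibrated instead at α = 5e−8 the per-SNP
  noncentrality (~40) sits far above the greedy acceptance threshold
  (≈ ln N + 2 ln T) and recovery is essentially perfect — conservative
  recovery is a property of the near-threshold regime.
* Concordance: 200 graded-signal genes, N = 1000; Spearman ρ between
  minSNP-P and Bayes-factor p-value rankings.
* Parametric agreement: 100 single-effect genes (8 SNPs, ρ = 0.5,
  N = 500), permutation to 100 successes or 5×10⁴ trials; ratio
  parametric/empirical over genes with non-null selection and empirical
  p in [1e−3, 0.5].

## Numerical choices and degenerate inputs

* Weights/ties: effective-test ties and greedy score ties break to the
  lowest genomic coordinate, then lowest column index.
* Beta-prior arguments are clamped at 1e−3 when K > T (reachable only at
  K = floor(T)+1).
* SSE = 0 scores +∞ (a perfect fit dominates); F statistics on zero
  residuals report +∞; constant dosage columns give r = 0, F = 0, p = 1
  and are skipped by the search.
* Missing hard-call dosages are mean-imputed per SNP before centering;
  MAF is the folded mean dosage / 2.
* HWE exact test (Levene–Haldane conditional distribution) applies to
  hard-called SNPs only; fractional (imputed) dosages bypass HWE and
  call-rate filters. QC defaults: HWE p ≥ 1e−6, MAF ≥ 0.001, call rate
  ≥ 0.95, all configurable.
* Coordinates are 1-based inclusive internally; BED converts on read;
  `chr` prefixes are stripped. Default flank 20 kb (CLI-configurable).
* VCF FORMAT floats are float32 in htslib-backed readers; `read_vcf`
  re-parses DS strings at float64 so dosage round trips are bit-exact.

## Known limitations

* Covariates are not modelled; the trait is assumed pre-adjusted.
* Sex chromosomes receive no special handling; no imputation, liftover
  or multi-allelic splitting (multi-allelic records are rejected or
  skipped).
* The greedy search is myopic: suppression configurations can hide the
  optimum (the subset-initialized search exists for exactly this, at
  combinatorial cost for 3-SNP starts on large genes).
* The parametric fallback is a ranking device for genes beyond the
  permutation budget, not a calibrated p-value.
* Genome-wide threshold estimation re-runs every gene per genome
  permutation, including each gene's own permutation loop; it is the
  one genuinely expensive operation and is sized accordingly in the
  bundled studies.
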