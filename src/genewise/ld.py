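"""Within-gene LD and the effective number of independent tests.

The effective number of tests T calibrates the model-size prior used by
the gene-wide model search: correlated SNPs should not each count as an
independent opportunity for association.  T is computed by a greedy
weight-stripping procedure over the squared Pearson correlation matrix of
the dosage columns.  It is designed to be insensitive to marker density —
duplicating an existing SNP leaves T unchanged — and deterministic, with
ties broken by genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GeneRegion, GenotypeMatrix

__all__ = ["CorrelationMatrix", "EffectiveTests", "pairwise_correlation", "effective_tests"]

#: weights below this are treated as exactly zero (guarantees termination)
WEIGHT_FLOOR = 1e-12


@dataclass
class CorrelationMatrix:
    """P x P Pearson correlations between dosage columns."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("correlation matrix must be square")

    @property
    def p(self) -> int:
        return self.r.shape[0]


@dataclass
class EffectiveTests:
    """The real-valued effective test count T with an audit trace.

    ``trace`` lists, in selection order, the SNP index chosen at each round
    and the weight it contributed to T.
    """

    t: float
    trace: list[tuple[int, float]] = field(default_factory=list)


def pairwise_correlation(
    genotypes: GenotypeMatrix | np.ndarray, gene: GeneRegion | None = None
) -> CorrelationMatrix:
    """Pearson correlation of the gene's dosage columns.

    A zero-variance column correlates 0 with every other column and 1 with
    itself, so monomorphic markers contribute a full unit to the effective
    test count rather than poisoning the matrix with NaN.
    """
    if isinstance(genotypes, GenotypeMatrix):
        x = genotypes.dosages
        if gene is not None:
            x = x[:, gene.snp_indices]
    else:
        x = np.asarray(genotypes, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need an n x p matrix with p >= 1")
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.sqrt((xc * xc).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    r = (xc / safe).T @ (xc / safe)
    degenerate = norms == 0
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMatrix(r)


def effective_tests(
    corr: CorrelationMatrix | np.ndarray, positions: np.ndarray | None = None
) -> EffectiveTests:
    """Effective number of independent tests from pairwise correlations.

    Every SNP starts with weight 1 and T at 0.  Repeatedly, the SNP with
    the largest remaining weight is selected (ties go to the lowest genomic
    coordinate, then the lowest column index, for reproducibility); its
    weight is added to T and set to zero, and every other SNP's weight is
    reduced by the squared correlation with the selected SNP, floored at
    zero.  Correlations are never updated between rounds — a deliberate
    simplification that can only overestimate T, making downstream model
    selection conservative.  The process ends when all weights are zero.

    Duplicating an existing SNP adds a weight that the first selection
    round strips to zero, so T is unchanged — the density-insensitivity
    this construction exists for.
    """
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    p = r.shape[0]
    if p < 1:
        raise ValueError("need at least one SNP")
    pos = (
        np.arange(p)
        if positions is None
        else np.asarray(positions, dtype=np.int64)
    )
    r2 = r * r
    w = np.ones(p)
    t = 0.0
    trace: list[tuple[int, float]] = []
    while True:
        w_max = w.max()
        if w_max <= WEIGHT_FLOOR:
            break
        tied = np.flatnonzero(w >= w_max - WEIGHT_FLOOR)
        i = int(tied[np.argmin(pos[tied])])
        t += w[i]
        trace.append((i, float(w[i])))
        w[i] = 0.0
        active = w > 0
        w[active] = np.maximum(0.0, w[active] - r2[i, active])
        w[w <= WEIGHT_FLOOR] = 0.0
    return EffectiveTests(t=float(t), trace=trace)
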