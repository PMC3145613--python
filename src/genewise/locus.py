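"""Hierarchical locus analysis: merge, trim, and score against knowns.

Strong LD can smear one association across several neighboring genes, or
split a causal region between genes.  The hierarchical procedure handles
both: (1) transitively merge significant genes whose transcript
boundaries lie within 200 kb; (2) re-run model selection on the merged
SNP set (with the effective test count recomputed for the locus) and
iteratively trim terminal genes that contain no selected SNP; (3) assign
the locus the minimum of its member genes' p-values and its own
permutation p-value — a single SNP assigned to two overlapping genes
should not be penalized for the overlap.

Predictions are scored against a user-supplied list of known-positive
loci: any (even partial) coordinate overlap is a true positive, only the
first hit to each known locus counts, and later hits to an already-found
known are dropped from the ranking rather than penalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneRegion, normalize_chrom
from .ld import effective_tests, pairwise_correlation
from .model import ModelScore, _greedy_from, GeneSuffStats
from .significance import (
    GwisScoreStatistic,
    PermutationConfig,
    gene_empirical_pvalue,
)

__all__ = [
    "GeneResult",
    "Locus",
    "KnownPositive",
    "PrecisionRecallPoint",
    "merge_significant_genes",
    "trim_locus",
    "locus_pvalue",
    "score_predictions",
    "read_known_positives",
]

MERGE_DISTANCE = 200_000


@dataclass
class GeneResult:
    """Per-gene association result feeding the locus stage."""

    gene: GeneRegion
    p_value: float

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


@dataclass
class Locus:
    """A merged (and possibly trimmed) run of significant genes."""

    genes: list[GeneResult]
    chromosome: str
    start: int
    end: int
    model: ModelScore | None = None
    t_merged: float | None = None
    p_value: float = 1.0
    p_source: str = "single-gene"

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class KnownPositive:
    """A locus established by prior meta-analyses, used as ground truth."""

    name: str
    chromosome: str
    start: int
    end: int
    source_trait: str = ""

    def __post_init__(self) -> None:
        self.chromosome = normalize_chrom(self.chromosome)


@dataclass
class PrecisionRecallPoint:
    rank: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two closed intervals (0 when they touch/overlap)."""
    if b_start > a_end:
        return b_start - a_end
    if a_start > b_end:
        return a_start - b_end
    return 0


def merge_significant_genes(
    results: list[GeneResult],
    p_threshold: float,
    distance: int = MERGE_DISTANCE,
) -> list[Locus]:
    """Transitively cluster significant genes within ``distance`` bp.

    Genes with p <= threshold on the same chromosome join one locus
    whenever a chain of pairwise boundary gaps <= ``distance`` connects
    them (so A-B at 150 kb and B-C at 150 kb merge A, B and C even though
    A and C are 300 kb apart).  Each locus starts with the minimum member
    p-value; run :func:`trim_locus` / :func:`locus_pvalue` to finish the
    hierarchical procedure.
    """
    sig = [r for r in results if r.p_value <= p_threshold]
    sig.sort(key=lambda r: (r.gene.chromosome, r.gene.tx_start, r.gene.tx_end))
    loci: list[Locus] = []
    current: list[GeneResult] = []

    def flush() -> None:
        if not current:
            return
        loci.append(
            Locus(
                genes=list(current),
                chromosome=current[0].gene.chromosome,
                start=min(g.gene.tx_start for g in current),
                end=max(g.gene.tx_end for g in current),
                p_value=min(g.p_value for g in current),
                p_source="min-of-genes" if len(current) > 1 else "single-gene",
            )
        )

    reach = 0
    for r in sig:
        g = r.gene
        if current and g.chromosome == current[0].gene.chromosome and (
            _interval_gap(
                min(x.gene.tx_start for x in current), reach, g.tx_start, g.tx_end
            )
            <= distance
        ):
            current.append(r)
            reach = max(reach, g.tx_end)
        else:
            flush()
            current = [r]
            reach = g.tx_end
    flush()
    return loci


def _pooled_snps(locus: Locus) -> np.ndarray:
    idx = np.unique(np.concatenate([g.gene.snp_indices for g in locus.genes]))
    return idx.astype(int)


def trim_locus(locus: Locus, y, genotypes) -> Locus:
    """Re-fit the merged locus and trim terminal genes with no selected SNP.

    The pooled SNP set gets a fresh effective-test count and a fresh
    greedy model fit.  Genes at either end of the locus whose assigned
    SNPs include none of the selected SNPs are dropped; the fit-and-trim
    cycle repeats until stable.  A locus reduced to a single gene keeps
    that gene's original p-value as the only association in the region.
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, dtype=float)
    yv = yv - yv.mean()
    genes = sorted(locus.genes, key=lambda r: (r.gene.tx_start, r.gene.tx_end))
    while True:
        idx = np.unique(np.concatenate([g.gene.snp_indices for g in genes]))
        x = genotypes.dosages[:, idx]
        x = x - x.mean(axis=0, keepdims=True)
        positions = genotypes.variants["pos"].to_numpy()[idx]
        t = effective_tests(pairwise_correlation(x), positions).t
        suff = GeneSuffStats.build(yv, x, positions)
        model = _greedy_from(suff, t, [])
        selected_cols = set(idx[model.selected])
        if len(genes) <= 1:
            break
        trimmed = False
        while len(genes) > 1 and not (
            selected_cols & set(genes[0].gene.snp_indices.tolist())
        ):
            genes = genes[1:]
            trimmed = True
        while len(genes) > 1 and not (
            selected_cols & set(genes[-1].gene.snp_indices.tolist())
        ):
            genes = genes[:-1]
            trimmed = True
        if not trimmed:
            break
    single = len(genes) == 1
    return Locus(
        genes=genes,
        chromosome=locus.chromosome,
        start=min(g.gene.tx_start for g in genes),
        end=max(g.gene.tx_end for g in genes),
        model=model,
        t_merged=t,
        p_value=genes[0].p_value if single else min(g.p_value for g in genes),
        p_source="single-gene" if single else "min-of-genes",
    )


def locus_pvalue(
    locus: Locus,
    y,
    genotypes,
    config: PermutationConfig | None = None,
) -> Locus:
    """Final locus p-value: min of member p-values and the merged-set p.

    A locus that trimmed down to one gene keeps that gene's p unchanged.
    For multi-gene loci, the merged SNP set gets its own permutation
    p-value; the locus takes whichever of {member p-values, merged p} is
    smallest, recording the source, and the whole trimmed region is
    reported as one association.
    """
    if len(locus.genes) <= 1:
        return locus
    config = config or PermutationConfig()
    idx = _pooled_snps(locus)
    x = genotypes.dosages[:, idx]
    positions = genotypes.variants["pos"].to_numpy()[idx]
    t = (
        locus.t_merged
        if locus.t_merged is not None
        else effective_tests(pairwise_correlation(x - x.mean(0)), positions).t
    )
    res = gene_empirical_pvalue(
        GwisScoreStatistic(t), y, x, config, positions=positions
    )
    member_min = min(g.p_value for g in locus.genes)
    merged_p = res.ranking_value
    if merged_p < member_min:
        locus.p_value, locus.p_source = merged_p, "merged-permutation"
    else:
        locus.p_value, locus.p_source = member_min, "min-of-genes"
    return locus


def score_predictions(
    predicted: list[Locus] | list[tuple[str, int, int]],
    known: list[KnownPositive],
) -> list[PrecisionRecallPoint]:
    """Precision/recall trajectory of ranked predictions against knowns.

    Predictions must arrive ranked best-first.  Any partial coordinate
    overlap with a known locus is a true positive; a prediction
    overlapping only already-hit knowns is dropped (neither TP nor FP);
    a prediction overlapping nothing is a false positive.  One point per
    scored prediction.
    """
    n_known = len(known)
    hit = [False] * n_known
    tp = fp = 0
    points: list[PrecisionRecallPoint] = []
    for pred in predicted:
        if isinstance(pred, Locus):
            chrom, start, end = pred.chromosome, pred.start, pred.end
        else:
            chrom, start, end = normalize_chrom(pred[0]), pred[1], pred[2]
        overlapping = [
            i
            for i, kp in enumerate(known)
            if kp.chromosome == chrom and start <= kp.end and kp.start <= end
        ]
        if overlapping:
            fresh = [i for i in overlapping if not hit[i]]
            if not fresh:
                continue  # repeat hit: dropped from the ranking
            hit[fresh[0]] = True
            tp += 1
        else:
            fp += 1
        points.append(
            PrecisionRecallPoint(rank=len(points) + 1, tp=tp, fp=fp, fn=n_known - tp)
        )
    return points


def read_known_positives(path) -> list[KnownPositive]:
    """Read a BED-like TSV of known loci: name, chrom, start, end[, trait]."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["name", "chrom", "start", "end", "trait"],
        dtype={"name": str, "chrom": str, "trait": str},
    )
    return [
        KnownPositive(
            name=r["name"],
            chromosome=r["chrom"],
            start=int(r["start"]),
            end=int(r["end"]),
            source_trait="" if pd.isna(r["trait"]) else r["trait"],
        )
        for _, r in df.iterrows()
    ]
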