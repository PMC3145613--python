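"""In-memory containers for genotypes, phenotypes and gene regions.

The central object is :class:`GenotypeMatrix`, an N x P dosage matrix
(individuals by variants) with per-variant metadata held in a pandas
DataFrame.  Dosages are expected minor-allele counts in [0, 2]; fractional
values arise from imputation.  All regression code in the package operates
on zero-mean (centered) columns, mirroring the usual GWAS convention of
dropping the intercept after centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "Phenotype",
    "GeneRegion",
    "normalize_chrom",
]

#: columns required in GenotypeMatrix.variants
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "maf", "imputed")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-source labels compare equal."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass(frozen=True)
class Variant:
    """A single biallelic variant and its dosage column."""

    id: str
    chromosome: str
    position: int  # 1-based bp
    allele_ref: str
    allele_alt: str
    dosages: np.ndarray  # length N, values in [0, 2] (NaN = missing)
    maf: float

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError(f"dosages for {self.id} outside [0, 2]")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")


def _folded_maf(dosages: np.ndarray) -> float:
    """Allele frequency from mean dosage / 2, folded to the minor allele."""
    with np.errstate(invalid="ignore"):
        f = float(np.nanmean(dosages)) / 2.0
    if not np.isfinite(f):
        return 0.0
    return min(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """N x P dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages
        Array of shape (n_individuals, n_variants); NaN marks missing
        hard calls (imputed data have none).
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt, maf, imputed``,
        one row per dosage column, in column order.
    individual_ids
        Sample identifiers, in row order.
    centered
        True once every column has been mean-centered (see
        :func:`genewise.io.align_and_center`).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length does not match columns")
        self.individual_ids = np.asarray(self.individual_ids)
        if self.individual_ids.shape[0] != self.dosages.shape[0]:
            raise ValueError("individual_ids length does not match rows")
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant(self, i: int) -> Variant:
        """Materialize column ``i`` as a :class:`Variant`."""
        row = self.variants.iloc[i]
        return Variant(
            id=row["id"],
            chromosome=row["chrom"],
            position=int(row["pos"]),
            allele_ref=row["ref"],
            allele_alt=row["alt"],
            dosages=self.dosages[:, i],
            maf=float(row["maf"]),
        )

    def take_variants(self, indices) -> "GenotypeMatrix":
        """Subset to the given variant columns (order preserved as given)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            individual_ids=self.individual_ids,
            centered=self.centered,
        )

    def take_individuals(self, row_indices) -> "GenotypeMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            individual_ids=self.individual_ids[idx],
            centered=False,
        )

    def recompute_maf(self) -> None:
        """Refresh the ``maf`` column from the (uncentered) dosages."""
        if self.centered:
            raise ValueError("cannot recompute MAF from centered dosages")
        self.variants = self.variants.copy()
        self.variants["maf"] = [
            _folded_maf(self.dosages[:, j]) for j in range(self.n_variants)
        ]


@dataclass
class Phenotype:
    """A quantitative trait vector aligned to individual identifiers."""

    individual_ids: np.ndarray
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.individual_ids.shape[0] != self.values.shape[0]:
            raise ValueError("ids and values differ in length")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, centered: bool | None = None) -> "Phenotype":
        return Phenotype(
            individual_ids=self.individual_ids,
            values=np.asarray(values, dtype=np.float64),
            centered=self.centered if centered is None else centered,
        )


@dataclass
class GeneRegion:
    """A gene's transcript-union interval plus the SNPs assigned to it.

    ``tx_start``/``tx_end`` are 1-based inclusive and span the most extreme
    transcription start/end over all transcripts annotated to the gene.
    ``snp_indices`` index columns of an associated :class:`GenotypeMatrix`
    and include SNPs within ``flank`` bp of the transcript boundaries; a SNP
    may appear in several genes.
    """

    gene_id: str
    chromosome: str
    tx_start: int
    tx_end: int
    flank: int = 0
    snp_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: tx_start {self.tx_start} > tx_end {self.tx_end}"
            )
        self.chromosome = normalize_chrom(self.chromosome)
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)

    @property
    def n_snps(self) -> int:
        return int(self.snp_indices.size)

    def with_snps(self, indices, flank: int | None = None) -> "GeneRegion":
        return replace(
            self,
            snp_indices=np.asarray(indices, dtype=int),
            flank=self.flank if flank is None else flank,
        )
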