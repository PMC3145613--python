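"""Reading and writing genotypes, phenotypes and gene annotations.

Formats
-------
* PLINK bed/bim/fam (variant-major bed v1; hard calls only).
* VCF 4.x via cyvcf2, preferring a per-sample ``DS`` dosage field and
  falling back to hard ``GT`` calls.
* Phenotype TSV with header columns ``FID  IID  VALUE``.
* Gene annotation as BED (0-based half-open, converted on read) or GTF
  (1-based inclusive, ``gene_id`` attribute); multiple transcripts per gene
  are collapsed to the union interval.

Coordinates are 1-based inclusive internally and chromosome labels are
normalized by stripping any ``chr`` prefix.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GeneRegion, GenotypeMatrix, Phenotype, _folded_maf, normalize_chrom

__all__ = [
    "FormatError",
    "AlignmentError",
    "read_genotypes",
    "read_plink",
    "read_vcf",
    "write_plink",
    "write_vcf",
    "read_phenotype",
    "write_phenotype",
    "read_gene_annotation",
    "assign_snps_to_genes",
    "qc_filter",
    "hwe_exact_test",
    "align_and_center",
]


class FormatError(ValueError):
    """Raised for unparseable or unsupported input records."""


class AlignmentError(ValueError):
    """Raised when genotype and phenotype samples cannot be aligned."""


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])

# 2-bit PLINK codes -> dosage of the A1 allele: 00 hom-A1, 01 missing,
# 10 het, 11 hom-A2.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _byte_decode_table() -> np.ndarray:
    table = np.empty((256, 4), dtype=np.float64)
    for byte in range(256):
        for i in range(4):
            table[byte, i] = _CODE_TO_DOSAGE[(byte >> (2 * i)) & 0b11]
    return table


_BYTE_TABLE = _byte_decode_table()


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam fileset into dosages of the A1 allele."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise FormatError(f"{prefix}.bed: only variant-major bed v1 is supported")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * p:
        raise FormatError(f"{prefix}.bed: size inconsistent with bim/fam")
    # (p, bytes_per_variant) -> (p, 4*bytes_per_variant) -> trim to n
    decoded = _BYTE_TABLE[body.reshape(p, bytes_per_variant)].reshape(p, -1)[:, :n]
    dosages = np.ascontiguousarray(decoded.T)

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"].map(normalize_chrom),
            "pos": bim["pos"].astype(int),
            "ref": bim["a2"],
            "alt": bim["a1"],
            "maf": [_folded_maf(dosages[:, j]) for j in range(p)],
            "imputed": False,
        }
    )
    return GenotypeMatrix(dosages, variants, fam["iid"].to_numpy())


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-call dosages to bed/bim/fam (dosages must be 0/1/2/NaN)."""
    if genotypes.centered:
        raise ValueError("cannot write centered dosages as genotypes")
    prefix = Path(prefix)
    d = genotypes.dosages
    hard = np.where(np.isnan(d), -1, np.round(d)).astype(int)
    if not np.isin(hard, [-1, 0, 1, 2]).all() or (
        np.nanmax(np.abs(d - np.round(d)), initial=0) > 1e-9
    ):
        raise ValueError("write_plink requires hard calls; use write_vcf for dosages")
    # dosage -> 2-bit code
    code_of = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
    n, p = hard.shape
    bytes_per_variant = (n + 3) // 4
    body = np.zeros((p, bytes_per_variant), dtype=np.uint8)
    for j in range(p):
        for i in range(n):
            body[j, i // 4] |= code_of[hard[i, j]] << (2 * (i % 4))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(body.tobytes())
    v = genotypes.variants
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
         "a1": v["alt"], "a2": v["ref"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": genotypes.individual_ids, "iid": genotypes.individual_ids,
         "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _ds_columns_float64(path: str | Path) -> dict[int, np.ndarray] | None:
    """Per-record DS values parsed from the text at full float64 precision.

    htslib-backed readers store FORMAT floats as float32, which silently
    perturbs imputed dosages; this supplementary pass re-parses the DS
    strings so a write/read round trip is bit-exact.  Returns None when
    the file declares no DS field.  Keys are record indices in file order.
    """
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    out: dict[int, np.ndarray] = {}
    with opener(path, "rt") as fh:
        has_ds = False
        rec_index = 0
        for line in fh:
            if line.startswith("##"):
                has_ds = has_ds or 'ID=DS' in line
                continue
            if line.startswith("#"):
                if not has_ds:
                    return None
                continue
            fields = line.rstrip("\n").split("\t")
            fmt = fields[8].split(":")
            if "DS" in fmt:
                k = fmt.index("DS")
                vals = [s.split(":")[k] for s in fields[9:]]
                out[rec_index] = np.array(
                    [np.nan if v in (".", "") else float(v) for v in vals]
                )
            rec_index += 1
    return out


def read_vcf(path: str | Path, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCF into dosages, preferring the ``DS`` field over ``GT``.

    Parameters
    ----------
    on_multiallelic
        ``"error"`` rejects records with more than one ALT allele;
        ``"skip"`` drops them.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples)
    ds_text = _ds_columns_float64(path)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    for rec_index, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(pass on_multiallelic='skip' to drop)"
            )
        if ds_text is not None and ds_text.get(rec_index) is not None:
            col = ds_text[rec_index]
        else:
            gt = np.asarray(rec.gt_types, dtype=np.float64)  # 0/1/2, 3=missing
            col = np.where(gt > 2.5, np.nan, gt)
        cols.append(col)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        meta.append((vid, normalize_chrom(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    imputed = [
        bool(np.nanmax(np.abs(c - np.round(c)), initial=0) > 1e-9) for c in cols
    ]
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    variants["maf"] = [_folded_maf(dosages[:, j]) for j in range(len(cols))]
    variants["imputed"] = imputed
    return GenotypeMatrix(dosages, variants, samples)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages to a plain-text VCF with a ``DS`` FORMAT field.

    Dosages are printed at full precision (``%.17g``) so a write/read
    round trip reproduces them bit-exactly.
    """
    if genotypes.centered:
        raise ValueError("cannot write centered dosages as genotypes")
    v = genotypes.variants
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.individual_ids))
            + "\n"
        )
        for j in order:
            row = v.iloc[j]
            ds = [
                "." if np.isnan(x) else format(x, ".17g")
                for x in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tDS\t" + "\t".join(ds) + "\n"
            )


def read_genotypes(path: str | Path, format: str, **kwargs) -> GenotypeMatrix:
    """Dispatch to :func:`read_plink` or :func:`read_vcf`."""
    if format == "plink":
        return read_plink(path, **kwargs)
    if format == "vcf":
        return read_vcf(path, **kwargs)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path) -> Phenotype:
    """Read a TSV with header columns FID, IID, VALUE (IID is the key)."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    for col in ("FID", "IID", "VALUE"):
        if col not in df.columns:
            raise FormatError(f"phenotype file missing column {col}")
    return Phenotype(df["IID"].to_numpy(), df["VALUE"].to_numpy(dtype=float))


def write_phenotype(phenotype: Phenotype, path: str | Path) -> None:
    pd.DataFrame(
        {
            "FID": phenotype.individual_ids,
            "IID": phenotype.individual_ids,
            "VALUE": phenotype.values,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_gene_annotation(path: str | Path, format: str | None = None) -> list[GeneRegion]:
    """Read BED or GTF into one union-interval :class:`GeneRegion` per gene.

    BED intervals (0-based half-open) are converted to 1-based inclusive;
    GTF rows are used as-is.  A gene annotated with several transcripts
    spans min(start)..max(end) over all of them.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    rows: list[tuple[str, str, int, int]] = []  # gene_id, chrom, start, end
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if format == "bed":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{line_no}: BED needs >= 4 columns")
                chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                if end0 <= start0:
                    raise FormatError(f"{path}:{line_no}: end <= start")
                rows.append((name, chrom, start0 + 1, end0))
            elif format == "gtf":
                if len(parts) < 9:
                    raise FormatError(f"{path}:{line_no}: GTF needs 9 columns")
                chrom, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
                if end < start:
                    raise FormatError(f"{path}:{line_no}: end < start")
                m = _GENE_ID_RE.search(attrs)
                if m is None:
                    raise FormatError(f"{path}:{line_no}: no gene_id attribute")
                rows.append((m.group(1), chrom, start, end))
            else:
                raise ValueError(f"unknown annotation format {format!r}")
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    regions = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        chroms = grp["chrom"].map(normalize_chrom).unique()
        if len(chroms) > 1:
            raise FormatError(f"gene {gene_id} spans multiple chromosomes")
        regions.append(
            GeneRegion(
                gene_id=gene_id,
                chromosome=chroms[0],
                tx_start=int(grp["start"].min()),
                tx_end=int(grp["end"].max()),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# SNP assignment, QC, alignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    genotypes: GenotypeMatrix, genes: list[GeneRegion], flank: int = 20_000
) -> list[GeneRegion]:
    """Assign each SNP to every gene whose flanked region contains it.

    SNP *i* joins gene *g* iff ``tx_start - flank <= pos_i <= tx_end + flank``
    on the same chromosome (boundaries inclusive).  A SNP may be assigned to
    several genes; genes may end up with zero SNPs.  Within each gene the
    indices are ordered by genomic position (ties by column order), which
    downstream search relies on for deterministic tie-breaking.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    v = genotypes.variants
    chrom = v["chrom"].map(normalize_chrom).to_numpy()
    pos = v["pos"].to_numpy(dtype=int)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        mask = np.flatnonzero(chrom == c)
        order = mask[np.argsort(pos[mask], kind="stable")]
        by_chrom[c] = (pos[order], order)
    out = []
    for gene in genes:
        sorted_pos, col_idx = by_chrom.get(gene.chromosome, (np.empty(0, int), np.empty(0, int)))
        lo = np.searchsorted(sorted_pos, gene.tx_start - flank, side="left")
        hi = np.searchsorted(sorted_pos, gene.tx_end + flank, side="right")
        out.append(gene.with_snps(col_idx[lo:hi], flank=flank))
    return out


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Conditional on the allele counts, the heterozygote count follows the
    distribution of Levene/Haldane; the returned p-value sums the
    probabilities of all heterozygote counts no more likely than the one
    observed (the standard exact SNP-HWE test).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over all het counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    log_probs = np.empty(len(hets), dtype=float)
    from scipy.special import gammaln

    n_alleles = 2 * n
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        log_probs[i] = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            - (
                gammaln(n_alleles + 1)
                - gammaln(n_rare + 1)
                - gammaln(n_alleles - n_rare + 1)
            )
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    genotypes: GenotypeMatrix,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.001,
    call_rate_min: float = 0.95,
) -> GenotypeMatrix:
    """Drop SNPs failing MAF, call-rate or HWE thresholds.

    The HWE exact test and the call-rate filter apply to hard-called SNPs
    only; imputed-dosage SNPs bypass both (imputed SNPs are retained down
    to very low minor-allele frequencies, the dosage itself carrying the
    genotype uncertainty).
    """
    for name, val in (("hwe_p_min", hwe_p_min), ("maf_min", maf_min),
                      ("call_rate_min", call_rate_min)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    keep = []
    for j in range(genotypes.n_variants):
        col = genotypes.dosages[:, j]
        maf = _folded_maf(col)
        if maf < maf_min:
            continue
        if not genotypes.variants["imputed"].iloc[j]:
            called = np.isfinite(col)
            if called.mean() < call_rate_min:
                continue
            hard = np.round(col[called]).astype(int)
            n_het = int((hard == 1).sum())
            n_hom_alt = int((hard == 2).sum())
            n_hom_ref = int((hard == 0).sum())
            if hwe_exact_test(n_het, n_hom_ref, n_hom_alt) < hwe_p_min:
                continue
        keep.append(j)
    return genotypes.take_variants(keep)


def align_and_center(
    genotypes: GenotypeMatrix, phenotype: Phenotype
) -> tuple[GenotypeMatrix, Phenotype]:
    """Restrict to shared individuals, mean-impute, and center both.

    Individuals are taken in genotype order restricted to the intersection
    of id sets (deterministic).  Missing dosages are mean-imputed per SNP
    before centering; afterwards every dosage column and the phenotype have
    mean zero.  Centering is idempotent.
    """
    pheno_index = {iid: i for i, iid in enumerate(phenotype.individual_ids)}
    rows_g, rows_p = [], []
    for i, iid in enumerate(genotypes.individual_ids):
        if iid in pheno_index:
            rows_g.append(i)
            rows_p.append(pheno_index[iid])
    if len(rows_g) < 2:
        raise AlignmentError(
            f"only {len(rows_g)} shared individuals between genotypes and phenotype"
        )
    gm = genotypes.take_individuals(rows_g)
    d = gm.dosages
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d = np.where(nan_mask, np.broadcast_to(col_mean, d.shape), d)
    if not genotypes.centered:
        maf = [_folded_maf(d[:, j]) for j in range(d.shape[1])]
        gm.variants = gm.variants.copy()
        gm.variants["maf"] = maf
    d = d - d.mean(axis=0, keepdims=True)
    gm.dosages = d
    gm.centered = True
    values = phenotype.values[rows_p]
    values = values - values.mean()
    ph = Phenotype(gm.individual_ids, values, centered=True)
    return gm, ph
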