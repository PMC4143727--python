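"""Genotype, phenotype and gene-annotation I/O.

Genotypes are held as minor-allele dosage matrices (entries 0/1/2).  Readers
exist for plain TSV (samples x SNPs), PLINK ``.raw`` exports and VCF (through
cyvcf2).  Gene annotations come in as BED4+ intervals and are converted to a
SNP x gene incidence structure; SNP blocks are cut wherever the genomic gap
between adjacent SNPs exceeds a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

VALID_MISSING_POLICIES = ("reject", "impute")


class FormatError(ValueError):
    """Input file does not parse under the declared format."""


class DataError(ValueError):
    """Parsed input violates a data contract (missing calls, unsorted positions...)."""


@dataclass
class GenotypeData:
    """Minor-allele dosage matrix with per-SNP metadata.

    X : (n, p) integer matrix with entries in {0, 1, 2}
    snp_ids, chrom : length-p string arrays
    pos : length-p 1-based base-pair positions, non-decreasing within chromosome
    maf : length-p minor allele frequencies in (0, 0.5]
    sample_ids : optional length-n sample identifiers
    """

    X: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        n, p = self.X.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == len(self.maf) == p):
            raise DataError("SNP metadata length does not match genotype columns")
        if self.X.size and not np.isin(self.X, (0, 1, 2)).all():
            raise DataError("genotype entries must be 0, 1 or 2")
        if p and not (self.maf > 0).all():
            raise DataError("monomorphic SNP (maf == 0) retained; filter before construction")
        if p and (self.maf > 0.5 + 1e-12).any():
            raise DataError("maf above 0.5; dosages must count the minor allele")
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if np.any(np.diff(pc) < 0):
                raise DataError(f"positions not sorted within chromosome {c!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path, snp_info_path=None) -> None:
        """Write genotypes (and optionally SNP metadata) back to TSV."""
        df = pd.DataFrame(self.X, columns=self.snp_ids)
        ids = self.sample_ids if self.sample_ids is not None else np.arange(self.n_samples)
        df.insert(0, "sample_id", ids)
        df.to_csv(path, sep="\t", index=False)
        if snp_info_path is not None:
            pd.DataFrame(
                {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
            ).to_csv(snp_info_path, sep="\t", index=False)


@dataclass
class PhenotypeData:
    """Quantitative trait y (length n) and covariate matrix V (n x q, intercept first)."""

    y: np.ndarray
    V: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[0] != self.y.shape[0]:
            raise DataError("covariate matrix must be n x q with n matching the trait")
        if np.isnan(self.y).any():
            raise DataError("trait vector contains missing values")
        if self.V.shape[1] and np.linalg.matrix_rank(self.V) < self.V.shape[1]:
            raise DataError("covariate matrix is rank deficient")


@dataclass
class GeneMap:
    """Gene intervals with SNP-gene incidence.

    genes : list of (gene_id, chrom, start, end); start/end 1-based inclusive
    incidence : p x G binary sparse matrix, incidence[j, g] = 1 iff gene g covers SNP j
    cover_count : length-p vector n_j = number of genes covering SNP j
    """

    genes: list[tuple]
    incidence: sparse.csr_matrix
    cover_count: np.ndarray = None

    def __post_init__(self) -> None:
        self.incidence = sparse.csr_matrix(self.incidence, dtype=np.int8)
        counts = np.asarray(self.incidence.sum(axis=1)).ravel()
        if self.cover_count is None:
            self.cover_count = counts
        elif not np.array_equal(np.asarray(self.cover_count), counts):
            raise DataError("cover_count inconsistent with incidence row sums")
        self.cover_count = np.asarray(self.cover_count, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_snps(self) -> int:
        return self.incidence.shape[0]

    def gene_ids(self) -> list[str]:
        return [g[0] for g in self.genes]

    def snps_of_gene(self, g: int) -> np.ndarray:
        """Indices of SNPs covered by gene g."""
        return self.incidence.getcol(g).tocoo().row

    def genes_of_snp(self, j: int) -> np.ndarray:
        return self.incidence.getrow(j).indices

    def restrict(self, snp_idx: np.ndarray) -> "GeneMap":
        """Sub-map over a SNP index subset, keeping only genes that still cover a SNP."""
        sub = self.incidence[snp_idx, :]
        keep = np.flatnonzero(np.asarray(sub.sum(axis=0)).ravel() > 0)
        return GeneMap(genes=[self.genes[g] for g in keep], incidence=sub[:, keep])


@dataclass
class BlockPartition:
    """Ordered contiguous SNP index ranges [start, end) covering 1..p."""

    blocks: list[tuple[int, int]]
    gap_threshold_bp: int

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)


def compute_maf(x_col) -> float:
    """Minor allele frequency of one dosage column: min(f, 1-f), f = sum(x)/(2n)."""
    x = np.asarray(x_col, dtype=float)
    if x.size == 0:
        raise DataError("empty genotype column")
    f = x.sum() / (2.0 * x.size)
    return float(min(f, 1.0 - f))


def _apply_missing_policy(X: np.ndarray, snp_ids, sample_ids, missing_policy: str) -> np.ndarray:
    """Resolve NaN entries of a float dosage matrix under the chosen policy."""
    if missing_policy not in VALID_MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {VALID_MISSING_POLICIES}")
    miss = np.isnan(X)
    if not miss.any():
        return X
    if missing_policy == "reject":
        i, j = np.argwhere(miss)[0]
        sid = sample_ids[i] if sample_ids is not None else i
        raise DataError(
            f"missing genotype at SNP {snp_ids[j]!r}, sample {sid!r} "
            "(missing_policy='reject'; use 'impute' to fill per-SNP means)"
        )
    n_miss = int(miss.sum())
    logger.warning("imputing %d missing genotype calls with rounded per-SNP means", n_miss)
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    fill = np.clip(np.rint(col_mean), 0, 2)
    return np.where(miss, fill[None, :], X)


def _finalize(X, snp_ids, chrom, pos, sample_ids) -> GenotypeData:
    """Orient to minor allele, compute MAF, drop monomorphic/constant SNPs."""
    X = np.asarray(X, dtype=float)
    f = X.sum(axis=0) / (2.0 * X.shape[0])
    flip = f > 0.5
    X[:, flip] = 2.0 - X[:, flip]
    maf = np.minimum(f, 1.0 - f)
    keep = (maf > 0) & (X.std(axis=0) > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d monomorphic SNPs (MAF filter)", dropped)
    return GenotypeData(
        X=X[:, keep].astype(np.int8),
        snp_ids=np.asarray(snp_ids, dtype=object)[keep],
        chrom=np.asarray(chrom, dtype=object)[keep],
        pos=np.asarray(pos, dtype=np.int64)[keep],
        maf=maf[keep],
        sample_ids=None if sample_ids is None else np.asarray(sample_ids, dtype=object),
    )


def _read_tsv_genotypes(path, snp_info=None):
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse TSV genotype file {path}: {exc}") from exc
    sample_ids = None
    first = df.columns[0]
    if first.lower() in ("sample", "sample_id", "iid", "id"):
        sample_ids = df[first].to_numpy(dtype=object)
        df = df.drop(columns=[first])
    snp_ids = list(df.columns)
    X = df.to_numpy(dtype=float)
    if snp_info is not None:
        info = pd.read_csv(snp_info, sep="\t").set_index("snp_id")
        missing_meta = [s for s in snp_ids if s not in info.index]
        if missing_meta:
            raise DataError(f"snp_info lacks metadata for SNPs {missing_meta[:5]}")
        chrom = info.loc[snp_ids, "chrom"].astype(str).to_numpy(dtype=object)
        pos = info.loc[snp_ids, "pos"].to_numpy(dtype=np.int64)
    else:
        chrom = np.array(["0"] * len(snp_ids), dtype=object)
        pos = np.arange(1, len(snp_ids) + 1, dtype=np.int64)
    return X, snp_ids, chrom, pos, sample_ids


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path):
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse PLINK .raw file {path}: {exc}") from exc
    meta_cols = [c for c in df.columns if c.upper() in _PLINK_META]
    if "IID" not in [c.upper() for c in meta_cols]:
        raise FormatError("PLINK .raw header lacks the IID column")
    sample_ids = df[[c for c in df.columns if c.upper() == "IID"][0]].to_numpy(dtype=object)
    snp_cols = [c for c in df.columns if c.upper() not in _PLINK_META]
    # .raw column names look like rs123_A (variant id + counted allele)
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    X = df[snp_cols].to_numpy(dtype=float)
    chrom = np.array(["0"] * len(snp_ids), dtype=object)
    pos = np.arange(1, len(snp_ids) + 1, dtype=np.int64)
    return X, snp_ids, chrom, pos, sample_ids


def _read_vcf(path):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = np.asarray(vcf.samples, dtype=object)
    cols, snp_ids, chrom, pos = [], [], [], []
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]; allele -1 = missing
        dos = np.empty(len(gts), dtype=float)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} sample {sample_ids[i]!r}"
                )
            dos[i] = np.nan if min(alleles) < 0 else sum(1 for a in alleles if a > 0)
        cols.append(dos)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(var.POS)
    X = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return X, snp_ids, np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64), sample_ids


def read_genotypes(path, format: str = "tsv", missing_policy: str = "reject",
                   snp_info=None) -> GenotypeData:
    """Read a genotype file into :class:`GenotypeData`.

    Parameters
    ----------
    format : one of ``tsv``, ``plink_raw``, ``vcf``.
    missing_policy : ``reject`` (error on any missing call, the default) or
        ``impute`` (per-SNP mean dosage rounded to the nearest category).
    snp_info : optional TSV with columns ``snp_id, chrom, pos`` giving genomic
        coordinates for TSV-format input.

    Dosages are re-oriented to count the minor allele; monomorphic SNPs are
    removed (the number removed is logged).
    """
    readers = {"tsv": _read_tsv_genotypes, "plink_raw": _read_plink_raw, "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    if format == "tsv":
        X, snp_ids, chrom, pos, sample_ids = readers[format](path, snp_info)
    else:
        X, snp_ids, chrom, pos, sample_ids = readers[format](path)
    bad = ~(np.isnan(X) | np.isin(X, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"dosage {X[i, j]!r} at SNP {snp_ids[j]!r} is not in {{0,1,2}}")
    X = _apply_missing_policy(X, snp_ids, sample_ids, missing_policy)
    order = np.lexsort((pos, np.asarray(chrom, dtype=str)))
    X = X[:, order]
    snp_ids = np.asarray(snp_ids, dtype=object)[order]
    chrom = np.asarray(chrom, dtype=object)[order]
    pos = np.asarray(pos)[order]
    return _finalize(X, snp_ids, chrom, pos, sample_ids)


def read_phenotype(path, trait: str, covariates: list[str] | None = None,
                   add_intercept: bool = True, sample_ids=None) -> PhenotypeData:
    """Read trait and covariates from a one-row-per-sample TSV.

    When both the phenotype file and the genotype data carry sample ids the
    order is checked; rows are never silently reordered.
    """
    df = pd.read_csv(path, sep="\t")
    if trait not in df.columns:
        raise FormatError(f"trait column {trait!r} not in phenotype file")
    id_col = next((c for c in df.columns if c.lower() in ("sample", "sample_id", "iid", "id")), None)
    if sample_ids is not None and id_col is not None:
        file_ids = df[id_col].astype(str).to_numpy()
        if not np.array_equal(file_ids, np.asarray(sample_ids, dtype=str)):
            raise DataError("phenotype sample order does not match genotype sample order")
    covariates = covariates or []
    cols = [df[c].to_numpy(dtype=float) for c in covariates]
    names = list(covariates)
    if add_intercept:
        cols.insert(0, np.ones(len(df)))
        names.insert(0, "intercept")
    V = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return PhenotypeData(y=df[trait].to_numpy(dtype=float), V=V, covariate_names=names)


def read_gene_map(bed_path, snps: GenotypeData) -> GeneMap:
    """Build the SNP-gene incidence from a BED4+ gene interval file.

    BED intervals are 0-based half-open; internal positions are 1-based, so a
    record ``(start, end)`` covers 1-based bases ``start+1 .. end`` inclusive.
    """
    genes = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{bed_path}: line {ln}: expected >=4 BED fields, got {len(parts)}")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{bed_path}: line {ln}: non-integer interval bounds") from exc
            if end < start:
                raise FormatError(f"{bed_path}: line {ln}: end < start")
            genes.append((name, chrom, start + 1, end))  # 1-based inclusive
    p, G = snps.n_snps, len(genes)
    rows, cols = [], []
    for g, (_, gchrom, gstart, gend) in enumerate(genes):
        hit = (snps.chrom == gchrom) & (snps.pos >= gstart) & (snps.pos <= gend)
        idx = np.flatnonzero(hit)
        rows.extend(idx)
        cols.extend([g] * len(idx))
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(p, G)
    )
    return GeneMap(genes=genes, incidence=incidence)


def build_blocks(data: GenotypeData, gap_threshold_bp: int) -> BlockPartition:
    """Cut SNPs into contiguous blocks at large genomic gaps.

    A new block starts when the chromosome changes or when the distance between
    adjacent SNPs exceeds ``gap_threshold_bp``.
    """
    p = data.n_snps
    if p == 0:
        return BlockPartition(blocks=[], gap_threshold_bp=gap_threshold_bp)
    for c in pd.unique(data.chrom):
        if np.any(np.diff(data.pos[data.chrom == c]) < 0):
            raise DataError(f"positions unsorted within chromosome {c!r}")
    breaks = [0]
    for j in range(1, p):
        if data.chrom[j] != data.chrom[j - 1] or data.pos[j] - data.pos[j - 1] > gap_threshold_bp:
            breaks.append(j)
    breaks.append(p)
    blocks = [(breaks[k], breaks[k + 1]) for k in range(len(breaks) - 1)]
    return BlockPartition(blocks=blocks, gap_threshold_bp=gap_threshold_bp)
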