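"""Domain containers and readers for genotype, embedding, covariate and
expression data, plus the elementary transforms used throughout the
pipeline (MAF filtering, mean imputation, rank-based inverse-normal
transform, patch-to-individual aggregation).

Conventions
-----------
* Variant positions are 1-based (VCF convention); genomic windows are
  inclusive on both ends.
* Genotypes are alt-allele dosages in [0, 2]; missing calls are stored as
  NaN until :func:`mean_impute` is applied.
* All matrices are aligned on sample id by inner join before analysis
  (see :func:`align_samples`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("histoqtl")

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "EmbeddingMatrix",
    "CovariateMatrix",
    "ExpressionMatrix",
    "read_genotypes",
    "read_table_matrix",
    "read_embeddings",
    "read_covariates",
    "read_expression",
    "maf_filter",
    "mean_impute",
    "rank_inverse_normal",
    "aggregate_patches",
    "align_samples",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """Metadata for a single biallelic variant (1-based position)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """N x V alt-allele dosage matrix with variant metadata.

    ``dosage`` holds values in [0, 2] with NaN marking missing calls.
    ``maf`` is the folded minor-allele frequency computed over non-missing
    entries, invariant under swapping the ref/alt allele labels.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # (N, V) float, NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n, v = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but dosage has {n} rows")
        if v != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but dosage has {v} columns")
        if n == 0:
            raise ValueError("genotype matrix has zero samples")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency per variant (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in np.atleast_1d(idx)],
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, order: Sequence[int]) -> "GenotypeMatrix":
        order = list(order)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in order],
            variants=list(self.variants),
            dosage=self.dosage[order, :],
        )


@dataclass
class EmbeddingMatrix:
    """rows x L embedding array at patch or individual level.

    ``ids`` identify rows (sample ids at individual level, patch ids at
    patch level). ``cluster`` optionally labels each patch with its
    signature cluster.
    """

    ids: list[str]
    values: np.ndarray  # (rows, L)
    level: Literal["patch", "individual"] = "individual"
    cluster: np.ndarray | None = None  # per-patch signature label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("embedding values must be 2-D with L >= 1")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids / values row mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding values contain non-finite entries")
        if self.level == "individual" and len(set(self.ids)) != len(self.ids):
            raise ValueError("individual-level embedding rows must be unique per sample id")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster)
            if self.cluster.shape[0] != self.values.shape[0]:
                raise ValueError("cluster labels / values row mismatch")

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """N x K covariate design matrix, intercept included as a column."""

    samples: list[str]
    columns: list[str]
    values: np.ndarray  # (N, K)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.samples) or k != len(self.columns):
            raise ValueError("covariate shape does not match sample/column names")
        if k >= n:
            raise ValueError(f"more covariates ({k}) than samples ({n})")
        if np.linalg.matrix_rank(self.values) < k:
            raise ValueError("covariate matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, order: Sequence[int]) -> "CovariateMatrix":
        order = list(order)
        return CovariateMatrix(
            samples=[self.samples[i] for i in order],
            columns=list(self.columns),
            values=self.values[order, :],
        )


@dataclass
class ExpressionMatrix:
    """genes x N expression matrix (log-scale abundance)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # (G, N)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, n = self.values.shape
        if g != len(self.genes) or n != len(self.samples):
            raise ValueError("expression shape does not match gene/sample names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")


# ---------------------------------------------------------------------------
# Genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: Literal["vcf", "plink-bed"] | None = None,
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (plain or bgzipped) or PLINK BED fileset.

    Dosages count alt alleles per sample; missing calls become NaN.
    Multi-allelic VCF records are skipped with a warning unless
    ``split_multiallelic`` is set, in which case one biallelic record per
    alt allele is emitted.
    """
    path = Path(path)
    if format is None:
        format = "plink-bed" if path.suffix == ".bed" else "vcf"
    if format == "vcf":
        return _read_vcf(path, split_multiallelic)
    if format == "plink-bed":
        return _read_plink_bed(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path, split_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains zero samples")
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    n_multi_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                n_multi_skipped += 1
                continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        if len(alts) == 1:
            variants.append(
                VariantRecord(str(rec.CHROM), int(rec.POS), rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, alts[0])
            )
            cols.append(dos)
        else:
            # split: per-sample dosage of each alt allele from the raw genotypes
            raw = rec.genotypes  # list of [a1, a2, phased]
            for ai, alt in enumerate(alts, start=1):
                d = np.full(len(samples), np.nan)
                for si, g in enumerate(raw):
                    alleles = [a for a in g[:-1]]
                    if any(a < 0 for a in alleles):
                        continue
                    d[si] = sum(1 for a in alleles if a == ai)
                variants.append(
                    VariantRecord(str(rec.CHROM), int(rec.POS), f"{rec.ID or rec.POS}_{alt}", rec.REF, alt)
                )
                cols.append(d)
    if n_multi_skipped:
        logger.warning("skipped %d multi-allelic records in %s", n_multi_skipped, path)
    if not variants:
        raise ValueError(f"no biallelic variants parsed from {path}")
    return GenotypeMatrix(samples=samples, variants=variants, dosage=np.column_stack(cols))


# PLINK .bed magic bytes followed by SNP-major flag.
_PLINK_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes -> dosage (00=hom A1 ("alt-minor" convention -> 2 copies
# of allele-1), 01=missing, 10=het, 11=hom A2). PLINK counts allele-1 (usually
# the minor/alt allele), so hom-A1 = dosage 2.
_PLINK_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_plink_bed(bed_path: Path) -> GenotypeMatrix:
    """Minimal SNP-major PLINK 1 BED/BIM/FAM reader (dosage of allele 1)."""
    fam = pd.read_csv(bed_path.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(bed_path.with_suffix(".bim"), sep=r"\s+", header=None)
    samples = [str(s) for s in fam[1]]
    if not samples:
        raise ValueError(f"FAM companion of {bed_path} lists zero samples")
    variants = [
        VariantRecord(str(r[0]), int(r[3]), str(r[1]), str(r[5]), str(r[4]))
        for r in bim.itertuples(index=False)
    ]
    n, v = len(samples), len(variants)
    raw = bed_path.read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{bed_path}: not a SNP-major PLINK 1 BED file (bad magic)")
    bytes_per_var = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_var * v:
        raise ValueError(
            f"{bed_path}: expected {bytes_per_var * v} data bytes for {n} samples x {v} variants, got {body.size}"
        )
    blocks = body.reshape(v, bytes_per_var)
    # unpack 2-bit genotype codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11  # (V, bytes, 4)
    codes = codes.reshape(v, -1)[:, :n]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=_PLINK_CODE[codes].T.copy())


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_table_matrix(
    path: str | Path,
    id_column: str,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited table, optionally renaming via a column mapping.

    ``sep=None`` sniffs between tab and comma from the file extension.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if columns:
        df = df.rename(columns=dict(columns))
    if id_column not in df.columns:
        raise ValueError(f"{path}: required id column {id_column!r} not found in {list(df.columns)}")
    return df


def read_embeddings(
    path: str | Path,
    id_column: str = "sample_id",
    level: Literal["patch", "individual"] = "individual",
    cluster_column: str | None = None,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> EmbeddingMatrix:
    """Load an embedding table: one id column, optional cluster column, L numeric columns."""
    df = read_table_matrix(path, id_column, sep=sep, columns=columns)
    cluster = None
    drop = [id_column]
    if cluster_column is not None:
        cluster = df[cluster_column].to_numpy()
        drop.append(cluster_column)
    vals = df.drop(columns=drop).select_dtypes(include=[np.number])
    return EmbeddingMatrix(
        ids=[str(s) for s in df[id_column]],
        values=vals.to_numpy(dtype=float),
        level=level,
        cluster=cluster,
    )


def read_covariates(
    path: str | Path,
    id_column: str = "sample_id",
    add_intercept: bool = True,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> CovariateMatrix:
    df = read_table_matrix(path, id_column, sep=sep, columns=columns)
    vals = df.drop(columns=[id_column]).select_dtypes(include=[np.number])
    names = list(vals.columns)
    arr = vals.to_numpy(dtype=float)
    if add_intercept and "intercept" not in names:
        arr = np.column_stack([np.ones(len(arr)), arr])
        names = ["intercept"] + names
    return CovariateMatrix(samples=[str(s) for s in df[id_column]], columns=names, values=arr)


def read_expression(
    path: str | Path,
    gene_column: str = "gene",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Genes-by-samples table: first column gene ids, remaining columns samples."""
    df = read_table_matrix(path, gene_column, sep=sep)
    genes = [str(g) for g in df[gene_column]]
    vals = df.drop(columns=[gene_column])
    return ExpressionMatrix(genes=genes, samples=[str(c) for c in vals.columns], values=vals.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def maf_filter(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep variants with folded MAF >= ``threshold`` (order preserved)."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    keep = np.flatnonzero(G.maf >= threshold)
    return G.subset_variants(keep)


def mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the variant's non-missing mean."""
    dos = G.dosage.copy()
    miss = np.isnan(dos)
    if not miss.any():
        return replace(G, dosage=dos)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [G.variants[i].id for i in np.flatnonzero(all_missing)]
        raise ValueError(f"variants with all calls missing: {bad}")
    col_mean = np.nanmean(dos, axis=0)
    dos[miss] = np.broadcast_to(col_mean, dos.shape)[miss]
    return replace(G, dosage=dos)


def rank_inverse_normal(y: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal (Gaussianization) transform.

    Uses Blom scores Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for
    ties; strictly monotone on untied input.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("input must be a 1-D vector of length >= 3")
    if np.ptp(y) == 0:
        raise ValueError("rank transform undefined for constant input")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - offset) / (y.size - 2 * offset + 1))


def aggregate_patches(
    E: EmbeddingMatrix,
    mapping: Mapping[str, str],
    cluster: object | None = None,
) -> EmbeddingMatrix:
    """Average patch-level embeddings per individual.

    ``mapping`` sends each patch id to its individual id. If ``cluster``
    is given, only patches carrying that signature label contribute.
    Individuals with no selected patches are absent from the output.
    """
    if E.level != "patch":
        raise ValueError("aggregate_patches expects a patch-level embedding matrix")
    sel = np.ones(len(E.ids), dtype=bool)
    if cluster is not None:
        if E.cluster is None:
            raise ValueError("cluster filter requested but embeddings carry no cluster labels")
        sel = E.cluster == cluster
    missing = [p for p, keep in zip(E.ids, sel) if keep and p not in mapping]
    if missing:
        raise KeyError(f"patches with no individual mapping: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for i, (pid, keep) in enumerate(zip(E.ids, sel)):
        if keep:
            groups.setdefault(mapping[pid], []).append(i)
    if not groups:
        raise ValueError("no patches selected for any individual")
    indivs = list(groups)
    rows = np.vstack([E.values[groups[s]].mean(axis=0) for s in indivs])
    return EmbeddingMatrix(ids=indivs, values=rows, level="individual")


def align_samples(
    G: GenotypeMatrix,
    F: CovariateMatrix,
    E: EmbeddingMatrix,
) -> tuple[GenotypeMatrix, CovariateMatrix, EmbeddingMatrix]:
    """Inner-join the three matrices on sample id, logging drop counts."""
    if E.level != "individual":
        raise ValueError("alignment requires individual-level embeddings")
    common = [s for s in G.samples if s in set(F.samples) & set(E.ids)]
    if not common:
        raise ValueError("no samples shared across genotype, covariate and embedding matrices")
    for name, ids in (("genotypes", G.samples), ("covariates", F.samples), ("embeddings", E.ids)):
        dropped = len(ids) - len(common)
        if dropped:
            logger.info("align_samples: dropping %d of %d %s samples", dropped, len(ids), name)
    g_idx = {s: i for i, s in enumerate(G.samples)}
    f_idx = {s: i for i, s in enumerate(F.samples)}
    e_idx = {s: i for i, s in enumerate(E.ids)}
    Ga = G.subset_samples([g_idx[s] for s in common])
    Fa = F.subset_samples([f_idx[s] for s in common])
    Ea = EmbeddingMatrix(ids=list(common), values=E.values[[e_idx[s] for s in common]], level="individual")
    return Ga, Fa, Ea
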