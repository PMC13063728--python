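"""Genome-wide scanning and permutation-based multi-trait FWER control.

A scan applies the variance-component score test to every (trait, variant)
pair. Family-wise error control follows the pooled min-P permutation
scheme: for each trait, genotype rows are permuted jointly across variants
(preserving LD and the covariate/embedding structure), the scan is rerun,
and the minimum p-value recorded; the empirical alpha-quantile of the
pooled min-P distribution, divided by the number of traits, is the
genome-wide significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CovariateMatrix, GenotypeMatrix
from .score_test import NormalizedEmbedding, ScoreTest

logger = logging.getLogger("histoqtl")

__all__ = [
    "ScanResultTable",
    "FwerThreshold",
    "scan",
    "permutation_minp",
    "fwer_threshold",
    "qq_manhattan_tables",
]

#: median of chi-square(1): observed/expected medians give genomic inflation
CHI2_1_MEDIAN = 0.45493642311957174


@dataclass
class ScanResultTable:
    """Per-(trait, variant) association results with variant metadata."""

    table: pd.DataFrame  # columns: trait, chrom, pos, id, ref, alt, maf, n, Q, p, method, tested

    def per_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait]

    def write(self, path, trait: str | None = None) -> None:
        df = self.table if trait is None else self.per_trait(trait)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class FwerThreshold:
    alpha: float
    n_traits: int
    pooled_minp: np.ndarray
    percentile_value: float
    threshold: float


def scan(
    G: GenotypeMatrix,
    F: CovariateMatrix,
    embeddings: dict[str, NormalizedEmbedding],
    fast: bool = False,
) -> ScanResultTable:
    """Test every variant against every trait's embedding kernel.

    ``embeddings`` maps trait (signature) names to normalized embeddings
    aligned with ``G``/``F`` sample order. ``fast`` enables grid-interpolated
    p-values within each trait (exact at the extremes); default is exact
    per-variant Davies/Liu.
    """
    if G.n_variants == 0:
        raise ValueError("no variants to scan (empty after filtering?)")
    rows = []
    maf = G.maf
    for trait, Xn in embeddings.items():
        if Xn.n_samples != G.n_samples:
            raise ValueError(f"trait {trait!r}: embeddings have {Xn.n_samples} samples, genotypes {G.n_samples}")
        engine = ScoreTest(F, Xn)
        Q, sigma2 = engine.statistics(G.dosage)
        gg = np.sum(G.dosage**2, axis=0)
        degenerate = sigma2 * (engine.n - engine.k) <= 1e-12 * gg
        p, methods = engine.pvalues(G.dosage, fast=fast)
        for j, v in enumerate(G.variants):
            tested = not degenerate[j]
            rows.append(
                (trait, v.chrom, v.pos, v.id, v.ref, v.alt, maf[j], G.n_samples,
                 Q[j] if tested else np.nan,
                 p[j] if tested else np.nan,
                 methods[j] if tested else "untested",
                 tested)
            )
        logger.info("scan: trait %s done (%d variants)", trait, G.n_variants)
    df = pd.DataFrame(rows, columns=["trait", "chrom", "pos", "id", "ref", "alt",
                                     "maf", "n", "Q", "p", "method", "tested"])
    return ScanResultTable(table=df)


def permutation_minp(
    G: GenotypeMatrix,
    F: CovariateMatrix,
    Xn: NormalizedEmbedding,
    n_perm: int,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Min p-value per genotype permutation for one trait.

    Each permutation shuffles individuals' genotype rows jointly across all
    variants (LD preserved); covariates and embeddings stay fixed. Within a
    trait the eigen-weights are shared up to the residual-variance scalar,
    so the minimum p-value is the mixture tail at ``max_v Q_v / sigma_v^2``
    -- one exact Davies evaluation per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    engine = ScoreTest(F, Xn)
    out = np.empty(n_perm)
    for b, child in enumerate(ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(G.n_samples)
        out[b] = engine.min_pvalue(G.dosage[perm, :])
    return out


def fwer_threshold(pooled_minp: np.ndarray, alpha: float = 0.2, n_traits: int = 1) -> FwerThreshold:
    """Empirical alpha-quantile of pooled min-P, divided by the trait count."""
    pooled_minp = np.asarray(pooled_minp, dtype=float)
    if pooled_minp.size == 0:
        raise ValueError("pooled min-p vector is empty")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    pct = float(np.quantile(pooled_minp, alpha))  # linear-interpolation quantile
    return FwerThreshold(
        alpha=alpha,
        n_traits=n_traits,
        pooled_minp=pooled_minp,
        percentile_value=pct,
        threshold=pct / n_traits,
    )


def qq_manhattan_tables(results: ScanResultTable) -> dict:
    """QQ and Manhattan plotting tables plus the genomic inflation factor.

    Expected quantiles use -log10((rank - 0.5) / n); lambda_GC is the ratio
    of the median implied 1-df chi-square to its null median.
    """
    from scipy import stats

    df = results.table[results.table["tested"]].copy()
    if df.empty:
        raise ValueError("no tested results")
    p = df["p"].to_numpy()
    order = np.argsort(p)
    n = p.size
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed": -np.log10(np.maximum(p[order], 1e-300)),
        "trait": df["trait"].to_numpy()[order],
        "id": df["id"].to_numpy()[order],
    })
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lambda_gc = float(np.median(chi2) / CHI2_1_MEDIAN)

    man = df.sort_values(["chrom", "pos"]).copy()
    offset = 0
    cum = np.empty(len(man), dtype=float)
    for chrom, grp in man.groupby("chrom", sort=False):
        cum[man["chrom"] == chrom] = grp["pos"].to_numpy() + offset
        offset += int(grp["pos"].max()) + 1
    man["cum_pos"] = cum
    man["neglog10p"] = -np.log10(np.maximum(man["p"].to_numpy(), 1e-300))
    return {"qq": qq, "manhattan": man, "lambda_gc": lambda_gc}
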