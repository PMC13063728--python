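"""Synthetic cohorts with the statistical structure the score test assumes.

Embeddings are generated as additive effects of covariates (sex, age and
genetic principal components), a single causal variant, and isotropic
Gaussian noise:

    X = F_c A + (g - mean g) s b^T + E

with b a random unit direction and s chosen so the genetic component
contributes exactly a fraction ``v`` of the total trace variance of X,
using population (expected) variances given the allele frequency so that
small cohorts remain honest about sampling noise. Covariates jointly
explain a configurable fraction of trace variance (default 20%).

The module also hosts the calibration and power harnesses built on this
generator, and a coupled-trait generator for colocalization checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CovariateMatrix, EmbeddingMatrix, GenotypeMatrix, VariantRecord
from .score_test import ScoreTest, cosine_normalize

logger = logging.getLogger("histoqtl")

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_null_variants",
    "simulate_coupled_traits",
    "calibration_run",
    "power_run",
    "POWER_GRID_N",
    "POWER_GRID_V",
]

#: cohort sizes and variance-explained grid of the reference power design
POWER_GRID_N = (650, 1_000, 2_000, 5_000, 10_000)
POWER_GRID_V = (0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01)

COVARIATE_COLUMNS = ["intercept", "sex", "age", "pc1", "pc2", "pc3", "pc4"]
# population variances of the non-intercept covariates (sex is Bernoulli(1/2))
_COV_VARS = np.array([0.25, 1.0, 1.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated cohort."""

    n: int = 650
    L: int = 64
    maf: float = 0.25
    v: float = 0.0                  # variance fraction explained by the variant
    covariate_frac: float = 0.20    # variance fraction explained by covariates
    n_null_variants: int = 2_000
    n_seeds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v < 1.0:
            raise ValueError(f"v must lie in [0, 1), got {self.v}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not 0.0 <= self.covariate_frac < 1.0 - self.v:
            raise ValueError("covariate_frac + v must stay below 1")
        if self.n <= len(COVARIATE_COLUMNS):
            raise ValueError("cohort smaller than the covariate count")


def _rng(cfg_or_seed) -> np.random.Generator:
    if isinstance(cfg_or_seed, np.random.Generator):
        return cfg_or_seed
    return np.random.default_rng(cfg_or_seed)


def _draw_genotype(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    """Binomial(2, maf) dosages, resampling monomorphic draws."""
    n_resampled = 0
    while True:
        g = rng.binomial(2, maf, size=n).astype(float)
        if np.ptp(g) > 0:
            break
        n_resampled += 1
    if n_resampled:
        logger.info("resampled %d monomorphic genotype draws", n_resampled)
    return g


def _covariates(rng: np.random.Generator, n: int) -> CovariateMatrix:
    vals = np.column_stack([
        np.ones(n),
        rng.binomial(1, 0.5, size=n).astype(float),
        rng.standard_normal(n),
        rng.standard_normal((n, 4)),
    ])
    return CovariateMatrix(samples=[f"S{i:06d}" for i in range(n)],
                           columns=list(COVARIATE_COLUMNS), values=vals)


def simulate_cohort(cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, CovariateMatrix, EmbeddingMatrix]:
    """One cohort: causal genotype g, covariates F, embeddings X."""
    rng = _rng(cfg.seed) if rng is None else rng
    g = _draw_genotype(rng, cfg.n, cfg.maf)
    F = _covariates(rng, cfg.n)
    X, effect = _embedding_from(rng, cfg, g, F)
    E = EmbeddingMatrix(ids=list(F.samples), values=X, level="individual")
    # unit direction and scaled per-dosage effect vector, for recovery checks
    E.planted_direction = None if effect is None else effect / np.linalg.norm(effect)
    E.planted_effect = effect
    return g, F, E


def _embedding_from(rng: np.random.Generator, cfg: SimConfig,
                    g: np.ndarray, F: CovariateMatrix) -> tuple[np.ndarray, np.ndarray | None]:
    n, L = cfg.n, cfg.L
    noise_trace = float(L)  # unit noise variance per dimension
    total_trace = noise_trace / (1.0 - cfg.covariate_frac - cfg.v)
    X = rng.standard_normal((n, L))
    # covariate component, scaled to its population trace-variance share
    if cfg.covariate_frac > 0:
        A = rng.standard_normal((len(_COV_VARS), L))
        raw_trace = float(_COV_VARS @ np.sum(A * A, axis=1))
        A *= np.sqrt(cfg.covariate_frac * total_trace / raw_trace)
        X += F.values[:, 1:] @ A
    # genetic component along a random unit direction, scaled so that its
    # population variance contribution is exactly v of the total trace
    effect = None
    if cfg.v > 0:
        b = rng.standard_normal(L)
        b /= np.linalg.norm(b)
        var_g = 2.0 * cfg.maf * (1.0 - cfg.maf)
        effect = np.sqrt(cfg.v * total_trace / var_g) * b
        X += np.outer(g - g.mean(), effect)
    return X, effect


def simulate_null_variants(rng: np.random.Generator, n: int, maf: float,
                           n_variants: int, chrom: str = "1",
                           start_pos: int = 1_000_000,
                           spacing: int = 500) -> GenotypeMatrix:
    """Panel of independent Binomial(2, maf) variants with no phenotype effect."""
    dos = rng.binomial(2, maf, size=(n, n_variants)).astype(float)
    variants = [
        VariantRecord(chrom, start_pos + j * spacing, f"var{j:05d}", "A", "G")
        for j in range(n_variants)
    ]
    return GenotypeMatrix(samples=[f"S{i:06d}" for i in range(n)],
                          variants=variants, dosage=dos)


def simulate_coupled_traits(
    cfg: SimConfig,
    n_variants: int = 50,
    shared: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, CovariateMatrix, EmbeddingMatrix, EmbeddingMatrix, tuple[int, int]]:
    """Two embedding traits driven by the same or distinct causal variants.

    Returns (variant panel, covariates, X1, X2, (causal1, causal2)). The
    panel holds independent variants (no LD); causal indices differ when
    ``shared`` is False.
    """
    rng = _rng(cfg.seed) if rng is None else rng
    F = _covariates(rng, cfg.n)
    G = simulate_null_variants(rng, cfg.n, cfg.maf, n_variants)
    c1 = int(rng.integers(n_variants))
    c2 = c1 if shared else int((c1 + 1 + rng.integers(n_variants - 1)) % n_variants)
    X1, _ = _embedding_from(rng, cfg, G.dosage[:, c1], F)
    X2, _ = _embedding_from(rng, cfg, G.dosage[:, c2], F)
    E1 = EmbeddingMatrix(ids=list(F.samples), values=X1, level="individual")
    E2 = EmbeddingMatrix(ids=list(F.samples), values=X2, level="individual")
    return G, F, E1, E2, (c1, c2)


def calibration_run(cfg: SimConfig, n_tests: int | None = None,
                    seed: int | None = None) -> np.ndarray:
    """p-values of independent null variants against one simulated trait.

    Requires ``cfg.v == 0`` so the embeddings carry no genetic signal.
    """
    if cfg.v != 0:
        raise ValueError("calibration requires v = 0 (no genetic effect)")
    n_tests = cfg.n_null_variants if n_tests is None else n_tests
    rng = _rng(cfg.seed if seed is None else seed)
    _, F, E = simulate_cohort(cfg, rng)
    Xn = cosine_normalize(E)
    engine = ScoreTest(F, Xn)
    G = rng.binomial(2, cfg.maf, size=(cfg.n, n_tests)).astype(float)
    p, _ = engine.pvalues(G)
    return p


def power_run(
    grid_n: tuple[int, ...] = POWER_GRID_N,
    grid_v: tuple[float, ...] = POWER_GRID_V,
    alpha: float = 5e-8,
    n_seeds: int = 100,
    base_cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Power table over a (cohort size x variance explained) grid.

    Per cell, power is the fraction of seeds whose causal-variant p-value
    falls below ``alpha``; the binomial standard error accompanies it.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in grid_n:
        for v in grid_v:
            cfg = replace(base_cfg, n=n, v=v)
            hits = 0
            for child in ss.spawn(n_seeds):
                rng = np.random.default_rng(child)
                g, F, E = simulate_cohort(cfg, rng)
                engine = ScoreTest(F, cosine_normalize(E))
                res = engine.test(g)
                hits += bool(res.tested and res.p_value < alpha)
            power = hits / n_seeds
            rows.append((n, v, power, np.sqrt(power * (1 - power) / n_seeds), n_seeds))
            logger.info("power n=%d v=%g: %.3f", n, v, power)
    return pd.DataFrame(rows, columns=["n", "v", "power", "se", "n_seeds"])
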