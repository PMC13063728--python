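"""Embedding-space interpretation of a significant variant.

A variant's "genetic effect axis" is the unit direction in embedding space
along which alt-allele dosage shifts the tissue phenotype: the covariate-
residualized cross-covariance between embeddings and genotype, which is the
per-dimension least-squares effect vector of the variance-component model's
fixed-effect dual. Patches are scored by projection onto the axis;
averaging patches inside extreme percentile bands of the score yields
representative extreme embeddings whose linear interpolation traces the
phenotypic gradient, and slides enriched for extreme patches provide
genotype-independent visualization in native tissue context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EffectAxis",
    "InterpolationPath",
    "estimate_axis",
    "projection_scores",
    "extreme_embeddings",
    "interpolation_path",
    "select_extreme_slides",
]


@dataclass
class EffectAxis:
    """Unit-norm direction of genotype effect; positive = higher alt dosage."""

    beta: np.ndarray
    variant_id: str = ""


@dataclass
class InterpolationPath:
    x_low: np.ndarray
    x_high: np.ndarray
    steps: np.ndarray  # (n_steps, L), steps[0] = x_low, steps[-1] = x_high


def _residualize(A: np.ndarray, F: np.ndarray) -> np.ndarray:
    qf, _ = np.linalg.qr(F)
    return A - qf @ (qf.T @ A)


def estimate_axis(g: np.ndarray, F, X: np.ndarray, variant_id: str = "") -> EffectAxis:
    """Direction of the genotype effect in embedding space.

    beta is proportional to X_res^T g_res (covariate-residualized cross-
    covariance; equivalently the vector of per-dimension OLS genotype
    coefficients), unit-normalized, oriented so higher alt dosage raises
    projection scores.
    """
    from .io import EmbeddingMatrix
    from .score_test import _covariate_array

    if isinstance(X, EmbeddingMatrix):
        X = X.values
    Fv = _covariate_array(F)
    g = np.asarray(g, dtype=float)
    g_res = _residualize(g[:, None], Fv)[:, 0]
    X_res = _residualize(np.asarray(X, dtype=float), Fv)
    beta = X_res.T @ g_res
    norm = np.linalg.norm(beta)
    if norm <= 1e-12 * max(np.linalg.norm(g_res), 1e-300) * max(np.linalg.norm(X_res), 1e-300):
        raise ValueError(f"variant {variant_id or '?'}: zero effect vector in embedding space")
    return EffectAxis(beta=beta / norm, variant_id=variant_id)


def projection_scores(Ep, axis: EffectAxis) -> np.ndarray:
    """Per-patch scalar score: patch embedding row dotted with the axis."""
    from .io import EmbeddingMatrix

    values = Ep.values if isinstance(Ep, EmbeddingMatrix) else np.asarray(Ep, dtype=float)
    if values.shape[1] != axis.beta.size:
        raise ValueError("patch embeddings and axis have different dimensions")
    return values @ axis.beta


def extreme_embeddings(
    Ep,
    scores: np.ndarray,
    low_band: tuple[float, float] = (1.0, 5.0),
    high_band: tuple[float, float] = (95.0, 99.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean patch embedding within closed percentile bands of the scores.

    Band membership uses the linear-interpolation percentile convention;
    an empty band raises with the occupancy of both bands.
    """
    from .io import EmbeddingMatrix

    values = Ep.values if isinstance(Ep, EmbeddingMatrix) else np.asarray(Ep, dtype=float)
    scores = np.asarray(scores, dtype=float)
    for band in (low_band, high_band):
        if not (0.0 <= band[0] <= band[1] <= 100.0):
            raise ValueError(f"percentile band {band} outside [0, 100]")
    if low_band[1] > high_band[0]:
        raise ValueError(f"bands {low_band} and {high_band} overlap")

    def band_mask(band: tuple[float, float]) -> np.ndarray:
        lo, hi = np.percentile(scores, band)
        return (scores >= lo) & (scores <= hi)

    m_low, m_high = band_mask(low_band), band_mask(high_band)
    if not m_low.any() or not m_high.any():
        raise ValueError(
            f"empty percentile band: low {low_band} holds {int(m_low.sum())} patches, "
            f"high {high_band} holds {int(m_high.sum())}"
        )
    return values[m_low].mean(axis=0), values[m_high].mean(axis=0)


def interpolation_path(x_low: np.ndarray, x_high: np.ndarray, n_steps: int) -> InterpolationPath:
    """Linear path from x_low to x_high with n_steps points inclusive."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    x_low = np.asarray(x_low, dtype=float)
    x_high = np.asarray(x_high, dtype=float)
    t = np.linspace(0.0, 1.0, n_steps)[:, None]
    return InterpolationPath(x_low=x_low, x_high=x_high, steps=x_low + t * (x_high - x_low))


def select_extreme_slides(
    scores: np.ndarray,
    slide_of_patch: Sequence[str],
    min_patches: int = 40,
    tail: float = 0.05,
) -> dict[str, dict[str, list[int]]]:
    """Slides with at least ``min_patches`` patches in the global score tails.

    Returns ``{"high": {slide: [patch indices]}, "low": {...}}``; a slide
    qualifies for the high (low) list when at least ``min_patches`` of its
    patches fall in the top (bottom) ``tail`` fraction of all scores.
    """
    scores = np.asarray(scores, dtype=float)
    slide_of_patch = np.asarray(slide_of_patch)
    if not 0.0 <= tail <= 1.0:
        raise ValueError("tail must lie in [0, 1]")
    n = scores.size
    k = int(np.floor(tail * n))
    out: dict[str, dict[str, list[int]]] = {"high": {}, "low": {}}
    if k == 0:
        return out
    order = np.argsort(scores, kind="stable")
    for name, members in (("low", order[:k]), ("high", order[-k:])):
        for slide in np.unique(slide_of_patch[members]):
            idx = [int(i) for i in members if slide_of_patch[i] == slide]
            if len(idx) >= min_patches:
                out[name][str(slide)] = sorted(idx)
    return out
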