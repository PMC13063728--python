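"""BIC-approximated Bayes factors and colocalization posteriors.

Per-variant evidence for association is summarized as a natural-log Bayes
factor obtained from the Schwarz (BIC) approximation with one extra
parameter: the score-test p-value is converted to an implied 1-df
chi-square statistic Lambda, and lbf = (Lambda - ln N) / 2.

Colocalization of two traits in a genomic window follows the standard
single-causal-variant posterior algebra over five hypotheses (H0 no
association, H1/H2 one trait only, H3 two distinct causal variants, H4 one
shared causal variant), with per-hypothesis evidence accumulated by
log-sum-exp over variants and scaled by the usual prior probabilities
(p1 = p2 = 1e-4, p12 = 1e-5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger("histoqtl")

__all__ = [
    "VariantLogBF",
    "ColocResult",
    "chisq_from_p",
    "log_bf_bic",
    "abf_from_beta_se",
    "coloc_posteriors",
    "window_select",
]

P_UNDERFLOW_FLOOR = 1e-300


@dataclass
class VariantLogBF:
    variant_id: str
    pos: int
    lbf: float  # natural-log Bayes factor, alternative vs null


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]  # keys H0..H4, sums to 1
    priors: tuple[float, float, float]
    n_variants: int


def chisq_from_p(p: float, df: int = 1) -> float:
    """Implied chi-square statistic at upper-tail probability ``p``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if p < P_UNDERFLOW_FLOOR:
        logger.warning("p-value %g below underflow floor; clipped to %g", p, P_UNDERFLOW_FLOOR)
        p = P_UNDERFLOW_FLOOR
    return float(stats.chi2.isf(p, df))


def log_bf_bic(chisq: float, n: int) -> float:
    """Schwarz approximation to the log Bayes factor: (Lambda - ln n) / 2."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if chisq < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return 0.5 * (chisq - np.log(n))


def abf_from_beta_se(beta, se, prior_sd: float = 0.2) -> np.ndarray:
    """Approximate log Bayes factor from an effect estimate and its SE.

    Wakefield's asymptotic BF with prior effect SD ``prior_sd`` (the
    convention for quantitative summary statistics); provided so external
    traits shipped as (beta, se) can enter the posterior algebra.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + z2 * r)


def _aligned_lbf(lbf1, lbf2) -> tuple[np.ndarray, np.ndarray, int]:
    def as_map(lst):
        if isinstance(lst, pd.DataFrame):
            return dict(zip(lst["id"].astype(str), lst["lbf"].astype(float)))
        return {v.variant_id: v.lbf for v in lst}

    m1, m2 = as_map(lbf1), as_map(lbf2)
    if set(m1) != set(m2):
        diff = sorted(set(m1) ^ set(m2))
        raise ValueError(f"variant sets differ between traits; symmetric difference: {diff[:10]}")
    ids = sorted(m1)
    return (np.array([m1[i] for i in ids]), np.array([m2[i] for i in ids]), len(ids))


def coloc_posteriors(
    lbf1,
    lbf2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Single-causal-variant colocalization posteriors from two lbf tracks.

    Accepts lists of :class:`VariantLogBF` or DataFrames with ``id``/``lbf``
    columns; variants must match exactly between traits. All sums run in
    log space.
    """
    l1, l2, nv = _aligned_lbf(lbf1, lbf2)
    s1 = logsumexp(l1)                 # log sum_i BF1_i
    s2 = logsumexp(l2)                 # log sum_j BF2_j
    s12 = logsumexp(l1 + l2)           # log sum_i BF1_i BF2_i  (H4)
    # H3: log sum_{i != j} BF1_i BF2_j = log(exp(s1 + s2) - exp(s12))
    both = s1 + s2
    if both <= s12 + 1e-12 and nv == 1:
        lh3 = -np.inf
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            lh3 = both + np.log1p(-np.exp(np.minimum(s12 - both, 0.0)))
        if not np.isfinite(lh3):
            lh3 = -np.inf
    logw = np.array([
        0.0,                       # H0
        np.log(p1) + s1,           # H1
        np.log(p2) + s2,           # H2
        np.log(p1) + np.log(p2) + lh3,  # H3
        np.log(p12) + s12,         # H4
    ])
    logz = logsumexp(logw[np.isfinite(logw)])
    pp = np.where(np.isfinite(logw), np.exp(logw - logz), 0.0)
    return ColocResult(
        pp={f"H{i}": float(pp[i]) for i in range(5)},
        priors=(p1, p2, p12),
        n_variants=nv,
    )


def window_select(results, chrom: str, center: int, width: int = 1_000_000) -> pd.DataFrame:
    """Variants within ``width``/2 of ``center`` on ``chrom`` (both ends inclusive)."""
    from .scan import ScanResultTable

    if width < 0:
        raise ValueError("window width must be non-negative")
    df = results.table if isinstance(results, ScanResultTable) else results
    half = width / 2.0
    sel = df[(df["chrom"].astype(str) == str(chrom)) & (np.abs(df["pos"] - center) <= half)]
    if sel.empty:
        logger.warning("empty %d bp window at %s:%d", width, chrom, center)
    return sel.copy()
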