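"""Cluster-signature bookkeeping and proportion-expression association.

Signatures are morphologically coherent patch clusters (labels are
consumed, not computed here). A cluster is retained for genetic analysis
only when enough slides carry enough of its patches; slide-level abundance
is the proportion of a slide's patches assigned to the cluster, and
abundance-expression association uses a univariate Gaussian linear model
assessed by likelihood-ratio test against the intercept-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("histoqtl")

__all__ = [
    "SignatureAssignment",
    "retain_clusters",
    "slide_proportions",
    "lrt_association",
]


@dataclass
class SignatureAssignment:
    """Patch-level cluster assignment table."""

    table: pd.DataFrame  # columns: patch_id, slide_id, individual_id, cluster

    REQUIRED = ("patch_id", "slide_id", "individual_id", "cluster")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"assignment table missing columns: {missing}")
        if self.table["patch_id"].duplicated().any():
            raise ValueError("each patch must be assigned to exactly one cluster")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "SignatureAssignment":
        return cls(pd.read_csv(path, sep=sep))


def retain_clusters(assignments: SignatureAssignment,
                    min_patches: int = 10, min_slides: int = 650) -> list:
    """Clusters with >= min_patches patches per slide in >= min_slides slides."""
    counts = (assignments.table
              .groupby(["cluster", "slide_id"], sort=False)
              .size()
              .reset_index(name="n"))
    enough = counts[counts["n"] >= min_patches]
    per_cluster = enough.groupby("cluster").size()
    return sorted(per_cluster[per_cluster >= min_slides].index.tolist())


def slide_proportions(assignments: SignatureAssignment) -> pd.DataFrame:
    """Slide x cluster proportion table; rows sum to 1."""
    tab = assignments.table
    counts = pd.crosstab(tab["slide_id"], tab["cluster"])
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("excluding %d empty slides", int(empty.sum()))
        counts = counts[~empty]
        totals = totals[~empty]
    return counts.div(totals, axis=0)


def lrt_association(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Univariate Gaussian LM with likelihood-ratio significance.

    ``y`` should be Gaussianized expression across slides, ``x`` the
    signature proportion. Returns (slope, p) with Lambda = n ln(RSS0/RSS1)
    against chi-square(1); a perfect fit clips p at the floor.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant proportion vector")
    n = y.size
    yc = y - y.mean()
    xc = x - x.mean()
    beta = float(xc @ yc / (xc @ xc))
    rss0 = float(yc @ yc)
    rss1 = float(np.sum((yc - beta * xc) ** 2))
    if rss1 <= 0:
        logger.warning("perfect fit in lrt_association; p clipped to floor")
        return beta, 1e-300
    lam = n * np.log(rss0 / rss1)
    return beta, float(stats.chi2.sf(lam, df=1))
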