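"""Variance-component prediction of gene expression from embeddings.

The predictor fits y = F alpha + u + e with u ~ N(0, sigma_x^2 K) on the
cosine kernel of training embeddings and e ~ N(0, sigma_e^2 I). The single
hyperparameter delta = sigma_e^2 / sigma_x^2 is chosen by maximizing the
Gaussian marginal likelihood over a log-spaced grid; out-of-sample
prediction is the BLUP of the random effect at test points, equivalent to
kernel ridge regression with penalty delta on covariate-residualized data.
Since the kernel has unit diagonal, the implied embedding signal fraction
is 1 / (1 + delta).

The module also hosts the reconstruction-deterioration test: Steiger's z
for two dependent correlations sharing the observed-expression variable,
with Bonferroni screening across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .score_test import NormalizedEmbedding, _covariate_array

__all__ = [
    "VcPredictor",
    "fit_vc_expression",
    "blup_predict",
    "loo_predict",
    "spearman_eval",
    "steiger_test",
    "deterioration_screen",
]

DELTA_GRID = np.logspace(-4, 4, 41)


@dataclass
class VcPredictor:
    delta: float
    alpha_hat: np.ndarray
    Xn_train: np.ndarray        # (n_train, L) unit-norm rows
    dual_weights: np.ndarray    # (K_train + delta I)^-1 (y - F alpha)
    F_columns: int
    log_marginal: float

    @property
    def signal_fraction(self) -> float:
        """sigma_x^2 / (sigma_x^2 + sigma_e^2); kernel diagonal is 1."""
        return 1.0 / (1.0 + self.delta)


def _profile_loglik(d_eigs, Fh, yh, delta):
    """Profile ML log-likelihood at fixed delta (alpha, sigma_x^2 profiled out)."""
    n = yh.size
    w = 1.0 / (d_eigs + delta)
    Fw = Fh * w[:, None]
    alpha = np.linalg.solve(Fh.T @ Fw, Fw.T @ yh)
    r = yh - Fh @ alpha
    sigma_x2 = float(r * w @ r) / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_x2) + np.sum(np.log(d_eigs + delta)) + n)
    return ll, alpha, sigma_x2


def fit_vc_expression(y: np.ndarray, F, Xn_train: NormalizedEmbedding,
                      delta_grid: np.ndarray = DELTA_GRID) -> VcPredictor:
    """Fit the variance-component expression model on the training set."""
    y = np.asarray(y, dtype=float)
    Fv = _covariate_array(F)
    n, k = Fv.shape
    if n <= k + 2:
        raise ValueError(f"training set of {n} too small for {k} covariates")
    if np.ptp(y) == 0:
        raise ValueError("constant expression vector")
    K = Xn_train.values @ Xn_train.values.T
    d_eigs, U = np.linalg.eigh(K)
    d_eigs = np.clip(d_eigs, 0.0, None)
    yh = U.T @ y
    Fh = U.T @ Fv
    best = (-np.inf, None, None, None)
    for delta in delta_grid:
        ll, alpha, _ = _profile_loglik(d_eigs, Fh, yh, delta)
        if ll > best[0]:
            best = (ll, float(delta), alpha, None)
    ll, delta, alpha, _ = best
    w = 1.0 / (d_eigs + delta)
    resid = y - Fv @ alpha
    dual = U @ (w * (U.T @ resid))
    return VcPredictor(delta=delta, alpha_hat=alpha, Xn_train=Xn_train.values.copy(),
                       dual_weights=dual, F_columns=k, log_marginal=ll)


def blup_predict(model: VcPredictor, Xn_test: NormalizedEmbedding, F_test=None) -> np.ndarray:
    """BLUP at test points: F* alpha + K*(K + delta I)^-1 (y - F alpha)."""
    Xt = Xn_test.values if isinstance(Xn_test, NormalizedEmbedding) else np.asarray(Xn_test)
    if Xt.shape[1] != model.Xn_train.shape[1]:
        raise ValueError("test embeddings have a different dimension than training")
    pred = (Xt @ model.Xn_train.T) @ model.dual_weights
    if F_test is not None:
        pred = pred + _covariate_array(F_test) @ model.alpha_hat
    return pred


def loo_predict(y: np.ndarray, F, Xn_train: NormalizedEmbedding, delta: float) -> np.ndarray:
    """Leave-one-out BLUP inside the training set, via the smoother leverage.

    For the linear smoother S with fitted values y_hat = S y, the LOO
    prediction is (y_hat_i - S_ii y_i) / (1 - S_ii).
    """
    y = np.asarray(y, dtype=float)
    Fv = _covariate_array(F)
    K = Xn_train.values @ Xn_train.values.T
    n = y.size
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    A = Fv @ np.linalg.solve(Fv.T @ Vi @ Fv, Fv.T @ Vi)   # GLS hat for F alpha
    S = A + K @ Vi @ (np.eye(n) - A)                      # full smoother
    y_hat = S @ y
    lev = np.clip(np.diag(S), None, 1.0 - 1e-10)
    return (y_hat - lev * y) / (1.0 - lev)


def spearman_eval(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks) with two-sided p-value."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(y_obs, y_pred)
    return float(rho), float(p)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing one variable.

    Tests whether corr(obs, pred_reconstructed) = r_jh is weaker than
    corr(obs, pred_original) = r_jk given corr(preds) = r_kh; one-sided
    alternative r_jh < r_jk (positive z favors deterioration).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} = {r} outside (-1, 1): Fisher z undefined")
    if n < 4:
        raise ValueError("need n >= 4")
    z1 = np.arctanh(r_jk)
    z2 = np.arctanh(r_jh)
    rm = 0.5 * (r_jk + r_jh)
    # covariance of the two Fisher z's with pooled correlation (Steiger 1980)
    psi = r_kh * (1.0 - 2.0 * rm**2) - 0.5 * rm**2 * (1.0 - 2.0 * rm**2 - r_kh**2)
    c = psi / (1.0 - rm**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    return float(z), float(stats.norm.sf(z))


def deterioration_screen(triples: list[tuple[float, float, float, int]],
                         alpha: float = 0.05) -> list[int]:
    """Indices of genes with Bonferroni-significant deterioration.

    ``triples`` holds per-gene (r_jk, r_jh, r_kh, n); a gene is flagged
    when its one-sided Steiger p times the number of genes is below alpha.
    """
    if not triples:
        raise ValueError("need at least one gene")
    m = len(triples)
    flagged = []
    for i, (r_jk, r_jh, r_kh, n) in enumerate(triples):
        _, p = steiger_test(r_jk, r_jh, r_kh, n)
        if p * m < alpha:
            flagged.append(i)
    return flagged
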