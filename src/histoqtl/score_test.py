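"""Single-variant multivariate association test.

The model treats the genotype as the outcome of a generalized variance
component model,

    g = F alpha + u,   u ~ N(0, sigma_x^2 K(X)),

where ``K(X) = Xn Xn^T`` is the cosine-similarity kernel of the row-unit-
normalized embedding matrix and ``F`` the fixed covariates. Association is
a score test of ``sigma_x^2 > 0``: with ``r`` the covariate residual of
``g`` and ``M`` the residual projector, the statistic

    Q = r^T K r = || Xn^T r ||^2

is asymptotically a weighted sum of independent 1-df chi-squares under the
null, with weights ``sigma^2 * eig(Xn^T M Xn)``. Everything is computed in
the L-dimensional embedding space (O(N L) per variant, O(N L^2 + L^3) once
per trait), never forming the N x N kernel.

Tail probabilities of the chi-square mixture come from numerical inversion
of its characteristic function (the Davies method, via Imhof's integral
with analytic integration-by-parts tail corrections), with the Liu
moment-matching approximation as fallback when inversion does not converge
or the p-value underflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NormalizedEmbedding",
    "NullModel",
    "AssociationResult",
    "DegenerateVariantError",
    "cosine_normalize",
    "fit_null",
    "score_statistic",
    "null_weights",
    "davies_pvalue",
    "liu_pvalue",
    "mixture_pvalue",
    "ratio_pvalue",
    "test_variant",
    "ScoreTest",
]

#: eigen-weights below this fraction of the largest are treated as null space
EIG_DROP_RTOL = 1e-12
#: absolute accuracy target for characteristic-function inversion
DAVIES_ACC = 1e-9
#: p-values below this are beyond inversion accuracy; Liu fallback is used
DAVIES_P_FLOOR = 1e-12


class DegenerateVariantError(ValueError):
    """Genotype lies in the covariate span; the score test is undefined."""


# ---------------------------------------------------------------------------
# Embedding normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedEmbedding:
    """Row-unit-norm embedding matrix Xn; implied kernel K = Xn Xn^T."""

    values: np.ndarray  # (N, L), each row unit Euclidean norm
    ids: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def kernel(self) -> np.ndarray:
        """Dense N x N cosine-similarity kernel (test/diagnostic use)."""
        return self.values @ self.values.T


def cosine_normalize(X, ids: list[str] | None = None) -> NormalizedEmbedding:
    """Scale each embedding row to unit norm so K(X) is cosine similarity."""
    from .io import EmbeddingMatrix

    if isinstance(X, EmbeddingMatrix):
        if ids is None:
            ids = list(X.ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms <= 0
    if zero.any():
        which = ids[int(np.flatnonzero(zero)[0])] if ids else f"row {int(np.flatnonzero(zero)[0])}"
        raise ValueError(f"zero-norm embedding row ({which}): cosine similarity undefined")
    return NormalizedEmbedding(values=X / norms[:, None], ids=ids)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """OLS fit of a genotype on the covariates under the Gaussian likelihood.

    ``qf`` is an orthonormal basis of the covariate column space; applying
    the residual projector ``M = I - qf qf^T`` to any vector is O(N K).
    """

    alpha_hat: np.ndarray
    residuals: np.ndarray
    sigma2: float
    qf: np.ndarray  # (N, K) orthonormal covariate basis

    def project_residual(self, A: np.ndarray) -> np.ndarray:
        """Apply M = I - qf qf^T to a vector or matrix."""
        return A - self.qf @ (self.qf.T @ A)


def _covariate_array(F) -> np.ndarray:
    from .io import CovariateMatrix

    return F.values if isinstance(F, CovariateMatrix) else np.asarray(F, dtype=float)


def fit_null(g: np.ndarray, F) -> NullModel:
    """Least-squares null model g = F alpha + e; unbiased sigma^2 (N - K)."""
    g = np.asarray(g, dtype=float)
    Fv = _covariate_array(F)
    n, k = Fv.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than covariates ({k})")
    qf, rr = np.linalg.qr(Fv)
    if np.min(np.abs(np.diag(rr))) <= 1e-10 * np.max(np.abs(np.diag(rr))):
        raise ValueError("covariate matrix is rank deficient")
    coef_q = qf.T @ g
    alpha = np.linalg.solve(rr, coef_q)
    r = g - qf @ coef_q
    rss = float(r @ r)
    if rss <= 1e-12 * float(g @ g):
        raise DegenerateVariantError("genotype is (numerically) in the covariate span")
    return NullModel(alpha_hat=alpha, residuals=r, sigma2=rss / (n - k), qf=qf)


def score_statistic(null: NullModel, Xn: NormalizedEmbedding) -> float:
    """Q = || Xn^T r ||^2 = r^T K r, computed without forming K."""
    t = Xn.values.T @ null.residuals
    return float(t @ t)


def null_weights(null: NullModel, Xn: NormalizedEmbedding, F=None) -> np.ndarray:
    """Nonzero eigen-weights of the null mixture: sigma^2 * eig(Xn^T M Xn).

    The nonzero spectrum of the N x N matrix ``M K M`` equals that of the
    L x L matrix ``Xn^T M Xn``, which is what makes the test low-rank.
    """
    B = null.project_residual(Xn.values)  # M Xn, (N, L)
    eig = np.linalg.eigvalsh(B.T @ B)
    lam = null.sigma2 * np.clip(eig, 0.0, None)
    return _clean_weights(lam)


def _clean_weights(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0 or np.max(lam) <= 0:
        raise ValueError("all mixture eigen-weights are zero")
    return np.sort(lam[lam > EIG_DROP_RTOL * np.max(lam)])[::-1]


# ---------------------------------------------------------------------------
# Mixture-of-chi-square tail probabilities
# ---------------------------------------------------------------------------

def _imhof_parts(u: np.ndarray, lam: np.ndarray, q: float, mult: np.ndarray | None = None):
    """theta(u) and 1/(u rho(u)) of Imhof's inversion integrand.

    ``mult`` gives integer multiplicities per weight (default all 1);
    weights may be signed when q = 0 (ratio statistics).
    """
    lu = lam[:, None] * u[None, :]
    if mult is None:
        theta = 0.5 * np.sum(np.arctan(lu), axis=0) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p(lu * lu), axis=0)
    else:
        m = mult[:, None]
        theta = 0.5 * np.sum(m * np.arctan(lu), axis=0) - 0.5 * q * u
        log_rho = 0.25 * np.sum(m * np.log1p(lu * lu), axis=0)
    g = np.exp(-np.log(u) - log_rho)
    return theta, g


def _signed_mixture_positive_prob(lam: np.ndarray, mult: np.ndarray) -> tuple[float, bool]:
    """P(sum_j m_j lam_j chi^2_1 > 0) for signed weights by Imhof inversion.

    The amplitude decays like u^(-1 - sum(m)/2), so the integral needs no
    oscillatory truncation analysis: integration stops where the amplitude
    underflows the accuracy target. Returns (prob, converged).
    """
    lam = np.asarray(lam, dtype=float)
    mult = np.asarray(mult, dtype=float)
    keep = lam != 0
    lam, mult = lam[keep], mult[keep]
    if lam.size == 0:
        raise ValueError("all mixture weights are zero")
    if np.all(lam > 0):
        return 1.0, True
    if np.all(lam < 0):
        return 0.0, True
    scale = np.max(np.abs(lam))
    lam = lam / scale

    def integral(factor: float) -> float:
        edges = [0.0]
        a = 0.0
        # frequency scale |theta'|, amplitude scale from log rho
        for _ in range(200_000):
            lu2 = (lam * a) ** 2
            dtheta = 0.5 * float(np.sum(mult * lam / (1.0 + lu2)))
            log_rho = 0.25 * float(np.sum(mult * np.log1p(lu2)))
            if log_rho > 60.0:  # amplitude below ~1e-26
                break
            w = factor * np.pi / (abs(dtheta) + 0.05)
            if a > 0:
                w = min(w, factor * 0.7 * a)
            a = a + w
            edges.append(a)
        edges_arr = np.asarray(edges)
        a_arr, b_arr = edges_arr[:-1], edges_arr[1:]
        widths = b_arr - a_arr
        nodes = (a_arr[:, None] + widths[:, None] * _GL_X[None, :]).ravel()
        theta, g = _imhof_parts(nodes, lam, 0.0, mult)
        vals = (np.sin(theta) * g).reshape(-1, _GL_X.size)
        return float(np.sum(vals @ _GL_W * widths))

    coarse = integral(0.5)
    fine = integral(0.25)
    p = 0.5 + fine / np.pi
    # halving panel widths gains many digits with the 12-point rule, so the
    # coarse/fine gap is a conservative bound on the fine value's error
    err = abs(fine - coarse)
    converged = bool(np.isfinite(p) and err <= 1e-6
                     and p > DAVIES_P_FLOOR and p <= 1.0 + 1e-9)
    return float(min(max(p, 0.0), 1.0)), converged


def ratio_pvalue(q_std: float, base_eigs: np.ndarray, dof: int) -> tuple[float, bool]:
    """Exact finite-sample tail of the standardized statistic Q / sigma_hat^2.

    Under Gaussian residual noise, {Q/sigma^2 > t} = {r^T (K - t/(N-K) I) r > 0}
    with r the projected residual: a signed chi-square mixture with weights
    mu_i - t/(N-K) (mu_i the kernel spectrum on the residual space) and
    -t/(N-K) with multiplicity N - K - L. This removes the error of plugging
    the estimated residual variance into the asymptotic mixture. Returns
    (p, converged); non-convergence signals the asymptotic fallback.
    """
    base_eigs = np.asarray(base_eigs, dtype=float)
    if q_std <= 0:
        return 1.0, True
    if dof <= base_eigs.size:
        raise ValueError("residual degrees of freedom must exceed the kernel rank")
    c = q_std / dof
    lam = np.concatenate([base_eigs - c, [-c]])
    mult = np.concatenate([np.ones(base_eigs.size), [dof - base_eigs.size]])
    return _signed_mixture_positive_prob(lam, mult)


def _imhof_tail_correction(U: float, lam: np.ndarray, q: float) -> tuple[float, float]:
    """Analytic integration-by-parts value of the integral beyond U.

    For I = int_U^inf g(u) sin(theta(u)) du with monotone theta:
    I = h(U) cos(theta(U)) - h2(U) sin(theta(U)) + O(int |h2'|),
    h = g/theta', h2 = h'/theta'. Returns (value, error_estimate).
    """
    u = float(U)
    lu2 = (lam * u) ** 2
    theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
    g = np.exp(-np.log(u) - 0.25 * np.sum(np.log1p(lu2)))
    dtheta = 0.5 * np.sum(lam / (1.0 + lu2)) - 0.5 * q
    d2theta = -np.sum(lam**3 * u / (1.0 + lu2) ** 2)
    dg = g * (-1.0 / u - 0.5 * np.sum(lam**2 * u / (1.0 + lu2)))
    h = g / dtheta
    dh = (dg * dtheta - g * d2theta) / dtheta**2
    h2 = dh / dtheta
    value = h * np.cos(theta) - h2 * np.sin(theta)
    return float(value), 2.0 * abs(float(h2))


# 12-point Gauss-Legendre nodes/weights on [0, 1], fixed panel rule
_GL_X, _GL_W = np.polynomial.legendre.leggauss(12)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _imhof_panels(lam: np.ndarray, q: float, U: float, factor: float = 1.0) -> float:
    """Panel-wise 12-point Gauss-Legendre integral of Imhof's integrand on [0, U].

    Panel widths are capped at ``factor`` times half the local oscillation
    period (the local frequency of sin(theta) is at most phi'(u) + q/2) and
    grow at most geometrically so the power-law amplitude decay is resolved.
    """
    sum_lam = float(np.sum(lam))
    edges = [0.0]
    a = 0.0
    while a < U:
        phi_prime = 0.5 * float(np.sum(lam / (1.0 + (lam * a) ** 2))) if a > 0 else 0.5 * sum_lam
        w = factor * np.pi / (phi_prime + 0.5 * q)
        if a > 0:
            w = min(w, factor * 0.7 * a)
            if phi_prime < 0.125 * q:
                # frequency now dominated by q: constant-width fill to U
                edges.extend(np.arange(a + w, U, w).tolist())
                edges.append(U)
                a = U
                break
        a = min(a + w, U)
        edges.append(a)
    edges_arr = np.asarray(edges)
    a_arr, b_arr = edges_arr[:-1], edges_arr[1:]
    widths = b_arr - a_arr
    nodes = (a_arr[:, None] + widths[:, None] * _GL_X[None, :]).ravel()
    theta, g = _imhof_parts(nodes, lam, q)
    vals = (np.sin(theta) * g).reshape(-1, _GL_X.size)
    return float(np.sum(vals @ _GL_W * widths))


def _imhof_quadrature(lam: np.ndarray, q: float, U: float) -> tuple[float, float]:
    """Two-resolution panel integration; the coarse/fine gap is the error estimate."""
    coarse = _imhof_panels(lam, q, U, factor=1.0)
    fine = _imhof_panels(lam, q, U, factor=0.5)
    return fine, max(abs(fine - coarse), 1e-14)


def davies_pvalue(Q: float, lambdas: np.ndarray, acc: float = DAVIES_ACC) -> tuple[float, bool]:
    """P(sum_i lambda_i chi^2_1 > Q) by characteristic-function inversion.

    Returns ``(p, converged)``; ``converged=False`` signals that the Liu
    fallback should be used (inversion error above target, or p below the
    achievable absolute accuracy floor).
    """
    lam = _clean_weights(np.asarray(lambdas, dtype=float))
    if np.any(lam < 0):
        raise ValueError("negative eigen-weights")
    if Q <= 0:
        return 1.0, True
    # exact special cases: single weight / all weights equal
    if lam.size == 1:
        return float(stats.chi2.sf(Q / lam[0], df=1)), True
    if np.allclose(lam, lam[0], rtol=1e-12):
        return float(stats.chi2.sf(Q / lam[0], df=lam.size)), True
    # condition by scaling to lambda_max = 1 (p is scale invariant)
    s = lam.max()
    lam = lam / s
    q = Q / s
    # choose the truncation point U: theta must be decreasing beyond U and
    # the second-order tail term below the accuracy target
    inv_sum = float(np.sum(1.0 / lam))
    U = max(2.0 * np.sqrt(2.0 * inv_sum / q), 1.0)
    tail_val = tail_err = np.inf
    for _ in range(200):
        dtheta = 0.5 * float(np.sum(lam / (1.0 + (lam * U) ** 2))) - 0.5 * q
        if dtheta < -0.25 * q:
            tail_val, tail_err = _imhof_tail_correction(U, lam, q)
            if tail_err <= 0.5 * acc or q * U / (4 * np.pi) > 2e5:
                break
        U *= 1.6

    val, quad_err = _imhof_quadrature(lam, q, U)
    p = 0.5 + (val + tail_val) / np.pi
    err = quad_err + tail_err
    converged = bool(np.isfinite(p) and err <= 100.0 * acc and p > DAVIES_P_FLOOR and p <= 1.0 + 1e-9)
    return float(min(max(p, 0.0), 1.0)), converged


def liu_pvalue(Q: float, lambdas: np.ndarray) -> float:
    """Moment-matching chi-square approximation to the mixture tail.

    Liu et al.'s noncentral chi-square matching, with the kurtosis-based
    modification of the degrees of freedom in the skewness-deficient branch
    (the variant standard in kernel association testing, which tracks far
    tails more closely); exact for a single weight or equal weights.
    """
    lam = _clean_weights(np.asarray(lambdas, dtype=float))
    if Q <= 0:
        return 1.0
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    t = (Q - c1) / np.sqrt(2.0 * c2)
    x = t * np.sqrt(2.0 * (df + 2.0 * delta)) + df + delta
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def mixture_pvalue(Q: float, lambdas: np.ndarray) -> tuple[float, str]:
    """Davies with Liu fallback; returns (p, method)."""
    p, converged = davies_pvalue(Q, lambdas)
    if converged:
        return p, "davies"
    return liu_pvalue(Q, lambdas), "liu"


# ---------------------------------------------------------------------------
# Per-variant association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    variant_id: str
    trait_id: str
    Q: float
    lambdas: np.ndarray
    p_value: float
    method: str  # "davies" | "liu" | "untested"
    converged: bool
    tested: bool = True


def _standardized_pvalue(q_std: float, base_eigs: np.ndarray, dof: int) -> tuple[float, str]:
    """Exact finite-sample ratio null with asymptotic Davies/Liu fallback."""
    p, converged = ratio_pvalue(q_std, base_eigs, dof)
    if converged:
        return p, "davies"
    return mixture_pvalue(q_std, base_eigs)


def test_variant(g: np.ndarray, F, Xn: NormalizedEmbedding,
                 variant_id: str = "", trait_id: str = "") -> AssociationResult:
    """Full single-variant test: null fit, score statistic, mixture p-value.

    The p-value uses the exact finite-sample null of the standardized
    statistic Q / sigma_hat^2 (see :func:`ratio_pvalue`), falling back to
    the asymptotic Davies/Liu mixture when the inversion does not converge
    (extreme tails).
    """
    try:
        null = fit_null(g, F)
    except DegenerateVariantError:
        return AssociationResult(variant_id, trait_id, np.nan, np.array([]), np.nan,
                                 "untested", False, tested=False)
    Q = score_statistic(null, Xn)
    lam = null_weights(null, Xn)
    dof = len(g) - null.qf.shape[1]
    p, method = _standardized_pvalue(Q / null.sigma2, lam / null.sigma2, dof)
    return AssociationResult(variant_id, trait_id, Q, lam, p, method, method == "davies")


class ScoreTest:
    """Per-trait engine amortizing everything that does not depend on g.

    The eigen-weights factor as ``sigma_v^2 * eig(Xn^T M Xn)``: the base
    spectrum is shared by all variants of a trait, so the per-variant null
    distribution differs only by the scalar ``sigma_v^2`` and p-values are
    ``S(Q_v / sigma_v^2)`` for a single mixture survival function S. That
    also makes the per-scan minimum p-value a single tail evaluation at
    ``max_v Q_v / sigma_v^2`` (S is decreasing).
    """

    def __init__(self, F, Xn: NormalizedEmbedding):
        Fv = _covariate_array(F)
        self.n, self.k = Fv.shape
        self.qf, rr = np.linalg.qr(Fv)
        if np.min(np.abs(np.diag(rr))) <= 1e-10 * np.max(np.abs(np.diag(rr))):
            raise ValueError("covariate matrix is rank deficient")
        self.Xn = Xn
        B = Xn.values - self.qf @ (self.qf.T @ Xn.values)
        eig = np.clip(np.linalg.eigvalsh(B.T @ B), 0.0, None)
        self.base_eigs = _clean_weights(eig)  # weights for sigma^2 = 1

    def statistics(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (Q, sigma^2) for a dosage matrix G of shape (N, V)."""
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        R = G - self.qf @ (self.qf.T @ G)  # residuals, (N, V)
        Q = np.sum((self.Xn.values.T @ R) ** 2, axis=0)
        rss = np.sum(R * R, axis=0)
        sigma2 = rss / (self.n - self.k)
        return Q, sigma2

    def test(self, g: np.ndarray, variant_id: str = "", trait_id: str = "") -> AssociationResult:
        Q, sigma2 = self.statistics(g)
        Q, sigma2 = float(Q[0]), float(sigma2[0])
        gg = float(np.asarray(g, dtype=float) @ np.asarray(g, dtype=float))
        if sigma2 * (self.n - self.k) <= 1e-12 * gg:
            return AssociationResult(variant_id, trait_id, np.nan, np.array([]), np.nan,
                                     "untested", False, tested=False)
        lam = sigma2 * self.base_eigs
        p, method = _standardized_pvalue(Q / sigma2, self.base_eigs, self.n - self.k)
        return AssociationResult(variant_id, trait_id, Q, lam, p, method, method == "davies")

    def pvalues(self, G: np.ndarray, fast: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant p-values; returns (p, method_codes).

        ``fast=True`` evaluates the shared survival function exactly at a
        monotone grid of standardized statistics and PCHIP-interpolates
        log p between nodes, refining the extreme tail exactly. Intended
        for permutation/replication workloads; default is exact per variant.
        """
        Q, sigma2 = self.statistics(G)
        qt = Q / sigma2  # standardized statistic, shared mixture weights
        p = np.empty_like(qt)
        methods = np.empty(qt.size, dtype=object)
        if not fast or qt.size <= 64:
            for i, q in enumerate(qt):
                p[i], methods[i] = _standardized_pvalue(float(q), self.base_eigs,
                                                        self.n - self.k)
            return p, methods
        return self._pvalues_interpolated(qt)

    def _pvalues_interpolated(self, qt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from scipy.interpolate import PchipInterpolator

        lo, hi = float(qt.min()), float(qt.max())
        nodes = np.linspace(lo, hi, 96)
        logp_nodes = np.empty(nodes.size)
        for i, q in enumerate(nodes):
            pv, _ = _standardized_pvalue(float(q), self.base_eigs, self.n - self.k)
            logp_nodes[i] = np.log(max(pv, 1e-300))
        interp = PchipInterpolator(nodes, logp_nodes, extrapolate=True)
        p = np.exp(interp(qt))
        methods = np.full(qt.size, "davies-grid", dtype=object)
        # refine the most significant variants exactly
        for i in np.argsort(qt)[-8:]:
            p[i], methods[i] = _standardized_pvalue(float(qt[i]), self.base_eigs,
                                                    self.n - self.k)
        return p, methods

    def min_pvalue(self, G: np.ndarray) -> float:
        """Minimum p-value over variants: one tail evaluation at max Q/sigma^2.

        Valid because within a trait all variants share the base spectrum,
        so the p-value is a decreasing function of the standardized statistic.
        """
        Q, sigma2 = self.statistics(G)
        p, _ = _standardized_pvalue(float(np.max(Q / sigma2)), self.base_eigs,
                                    self.n - self.k)
        return p
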