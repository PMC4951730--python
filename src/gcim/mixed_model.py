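"""Mixed linear model core for the genome scan.

The trait model is y = X a + z_k g_k + xi + e with polygene
xi ~ N(0, K phi^2) and residual e ~ N(0, I s2). The polygenic variance
ratio lambda = phi^2/s2 is estimated once by REML under the pure polygenic
model (no marker term) and frozen during the scan (P3D). With the
eigen-decomposition K = U diag(delta) U', rotating by U' diagonalizes the
background covariance: var(U'y) = (delta*lambda + 1) s2.

At each scanned locus the marker effect is a random effect with its own
ratio lambda_k = phi_k^2/s2. After projecting out the fixed effects, the
profiled restricted log-likelihood depends on lambda_k only through two
scalars,

    theta = z*' P0 z*,   kappa = z*' P0 y*,

where P0 is the GLS projection under the background covariance, because a
rank-one update of the covariance updates the projection by
Sherman-Morrison. The REML criterion (up to constants) is

    f(l) = nu * log(Q0 - l kappa^2/(1 + l theta)) + log(1 + l theta),

with Q0 = y*' P0 y* and nu = n - p, minimized over l >= 0 by Newton with
analytic derivatives. The BLUP of the effect, its variance and the Wald
statistic all follow from (theta, kappa, Q0) in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .genome import Kinship

__all__ = [
    "PolygenicFit",
    "LocusFit",
    "fit_polygenic",
    "profiled_reml_locus",
    "fixed_effect_locus",
    "wald_p",
    "reml_loglik_dense",
]

LAMBDA_MIN = 1e-6
LAMBDA_MAX = 1e6
LAMBDA_K_MAX = 1e6


@dataclass
class PolygenicFit:
    """REML fit of the pure polygenic model (no marker term)."""

    lambda_: float          # polygenic variance ratio phi^2 / sigma^2
    sigma2: float           # residual variance
    eigenvalues: np.ndarray  # delta, eigenvalues of K
    rotation: np.ndarray     # U, orthonormal eigenvectors of K
    restricted_loglik: float


@dataclass
class LocusFit:
    """Per-locus fit: variance ratio, effect estimate, Wald test."""

    lambda_k: float
    gamma_blup: float
    gamma_var: float
    wald: float
    p_value: float
    sigma2: float
    loglik: float


def wald_p(wald):
    """Upper-tail 1-df chi-square probability of a Wald statistic."""
    w = np.asarray(wald, dtype=float)
    if np.any(w < 0):
        raise ValueError("Wald statistic must be nonnegative")
    p = stats.chi2.sf(w, df=1)
    return float(p) if np.isscalar(wald) else p


def _reml_criterion(lam, delta, y_rot, X_rot):
    """-2 x profiled restricted log-likelihood (up to constants) at lambda."""
    D = delta * lam + 1.0
    Dinv = 1.0 / D
    Xw = X_rot * Dinv[:, None]
    A = X_rot.T @ Xw
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    b = Xw.T @ y_rot
    coef = np.linalg.solve(A, b)
    resid = y_rot - X_rot @ coef
    rss = float(resid @ (Dinv * resid))
    nu = y_rot.size - X_rot.shape[1]
    return nu * np.log(rss / nu) + float(np.sum(np.log(D))) + logdet_A


def fit_polygenic(y, X, K, eig=None) -> PolygenicFit:
    """REML estimate of the polygenic variance ratio via eigen-rotation.

    Profiles the restricted likelihood down to the single ratio lambda and
    optimizes it by a coarse log-grid followed by Brent refinement (exact
    here: one unknown ratio). ``eig=(delta, U)`` reuses a precomputed
    eigen-decomposition of K.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if n <= p:
        raise ValueError("need more individuals than fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is singular")
    Kmat = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    if eig is None:
        delta, U = np.linalg.eigh(Kmat)
        delta = np.clip(delta, 0.0, None)
    else:
        delta, U = eig
    y_rot = U.T @ y
    X_rot = U.T @ X

    grid = np.logspace(np.log10(LAMBDA_MIN), np.log10(LAMBDA_MAX), 61)
    vals = np.array([_reml_criterion(g, delta, y_rot, X_rot) for g in grid])
    if np.max(vals) - np.min(vals) < 1e-8:
        warnings.warn(
            "restricted likelihood is flat in the polygenic ratio "
            "(polygenic and residual variances are not separately "
            "identifiable); returning the lower bound",
            stacklevel=2,
        )
        lam_hat = LAMBDA_MIN
    else:
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        if i in (0, grid.size - 1):
            lam_hat = grid[i]
        else:
            res = optimize.minimize_scalar(
                lambda t: _reml_criterion(np.exp(t), delta, y_rot, X_rot),
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam_hat = float(np.exp(res.x))

    D = delta * lam_hat + 1.0
    Dinv = 1.0 / D
    Xw = X_rot * Dinv[:, None]
    A = X_rot.T @ Xw
    coef = np.linalg.solve(A, Xw.T @ y_rot)
    resid = y_rot - X_rot @ coef
    nu = n - p
    sigma2 = float(resid @ (Dinv * resid)) / nu
    # full-constant form, consistent with reml_loglik_dense
    loglik = -0.5 * (
        nu * np.log(2.0 * np.pi * sigma2)
        + nu
        + float(np.sum(np.log(D)))
        + float(np.linalg.slogdet(A)[1])
    )
    return PolygenicFit(
        lambda_=lam_hat,
        sigma2=sigma2,
        eigenvalues=delta,
        rotation=U,
        restricted_loglik=loglik,
    )


# ---------------------------------------------------------------------------
# per-locus machinery on projection scalars

def _projection_scalars(y_rot, X_rot, Z_rot, D):
    """theta, kappa, Q0 and log-det pieces under background covariance diag(D).

    ``Z_rot`` is n x L (one column per scanned locus).
    """
    Dinv = 1.0 / D
    Xw = X_rot * Dinv[:, None]
    A = X_rot.T @ Xw
    G = np.linalg.inv(A)
    b0 = Xw.T @ y_rot
    P0y = Dinv * y_rot - Xw @ (G @ b0)
    Q0 = float(y_rot @ P0y)
    V = Xw.T @ Z_rot                       # p x L
    theta = np.einsum("nl,nl->l", Z_rot * Dinv[:, None], Z_rot) - np.einsum(
        "pl,pq,ql->l", V, G, V
    )
    kappa = Z_rot.T @ P0y
    logdet_D = float(np.sum(np.log(D)))
    logdet_A = float(np.linalg.slogdet(A)[1])
    return theta, np.asarray(kappa), Q0, logdet_D, logdet_A


def _f_criterion(lam, theta, kappa, Q0, nu):
    s = 1.0 + lam * theta
    g = Q0 - lam * kappa**2 / s
    return nu * np.log(g) + np.log(s)


def _newton_lambda_k(theta, kappa, Q0, nu, max_iter=100, tol=1e-8):
    """Vectorized Newton minimization of the per-locus REML criterion.

    Start at lambda_k = 1; step-halving when the criterion increases;
    projection to 0 when the gradient at 0 is nonnegative (boundary
    optimum). Returns the estimate and a flag for entries that needed the
    bounded Brent fallback.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    L = theta.size
    lam = np.ones(L)
    k2 = kappa**2
    degenerate = theta <= 1e-12 * max(Q0, 1.0)
    # gradient at 0: nu * (-kappa^2)/Q0 + theta
    interior = (~degenerate) & (nu * k2 > theta * Q0)
    lam[~interior] = 0.0
    active = interior.copy()
    fallback = np.zeros(L, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        l0 = lam[idx]
        th, kk2 = theta[idx], k2[idx]
        s = 1.0 + l0 * th
        g = Q0 - l0 * kk2 / s
        gp = -kk2 / s**2
        gpp = 2.0 * th * kk2 / s**3
        f1 = nu * gp / g + th / s
        f2 = nu * (gpp * g - gp**2) / g**2 - th**2 / s**2
        step = np.where(f2 > 0, -f1 / f2, -np.sign(f1) * (1.0 + l0))
        f_cur = nu * np.log(g) + np.log(s)
        l_new = np.clip(l0 + step, 0.0, LAMBDA_K_MAX)
        # step halving toward l0 until the criterion does not increase
        for _h in range(40):
            f_new = _f_criterion(l_new, th, kappa[idx], Q0, nu)
            bad = f_new > f_cur + 1e-12
            if not bad.any():
                break
            l_new = np.where(bad, 0.5 * (l_new + l0), l_new)
        converged = np.abs(l_new - l0) < tol * (1.0 + l_new)
        lam[idx] = l_new
        active[idx] = ~converged

    if active.any():
        for j in np.flatnonzero(active):
            fallback[j] = True
            res = optimize.minimize_scalar(
                lambda t, jj=j: _f_criterion(
                    np.exp(t), theta[jj], kappa[jj], Q0, nu
                ),
                bounds=(np.log(1e-8), np.log(LAMBDA_K_MAX)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            cand = float(np.exp(res.x))
            if _f_criterion(cand, theta[j], kappa[j], Q0, nu) < _f_criterion(
                0.0, theta[j], kappa[j], Q0, nu
            ):
                lam[j] = cand
            else:
                lam[j] = 0.0
    return lam, fallback


def _random_effect_stats(lam, theta, kappa, Q0, nu):
    """BLUP, its conditional variance, sigma2 and Wald from the scalars.

    The Wald statistic divides the squared BLUP by its conditional
    (prediction-error) variance var(g_k | y) = lambda_k s2 / (1 + lambda_k
    theta); at an interior REML optimum it equals lambda_k * theta.
    """
    s = 1.0 + lam * theta
    g = Q0 - lam * kappa**2 / s
    sigma2 = g / nu
    gamma = lam * kappa / s
    gamma_var = lam * sigma2 / s
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(lam > 0, gamma**2 / gamma_var, 0.0)
    wald = np.where(np.isfinite(wald), wald, 0.0)
    return gamma, gamma_var, sigma2, wald


def profiled_reml_locus(y_rot, X_rot, z_rot, D, lambda0) -> LocusFit:
    """Random-effect fit of one locus with the polygenic ratio frozen (P3D).

    ``D`` holds the eigenvalues delta of K; the background covariance in the
    rotated frame is diag(delta*lambda0 + 1). Newton maximizes the profiled
    restricted likelihood in lambda_k; the rank-one structure makes every
    evaluation O(n).
    """
    y_rot = np.asarray(y_rot, dtype=float).ravel()
    X_rot = np.atleast_2d(np.asarray(X_rot, dtype=float))
    if X_rot.shape[0] != y_rot.size:
        X_rot = X_rot.T
    z = np.asarray(z_rot, dtype=float).reshape(-1, 1)
    Dfull = np.asarray(D, dtype=float) * float(lambda0) + 1.0
    nu = y_rot.size - X_rot.shape[1]
    theta, kappa, Q0, logdet_D, logdet_A = _projection_scalars(
        y_rot, X_rot, z, Dfull
    )
    lam, _ = _newton_lambda_k(theta, kappa, Q0, nu)
    gamma, gvar, sigma2, wald = _random_effect_stats(lam, theta, kappa, Q0, nu)
    loglik = -0.5 * (
        nu * np.log(2.0 * np.pi * sigma2[0])
        + nu
        + logdet_D
        + logdet_A
        + np.log(1.0 + lam[0] * theta[0])
    )
    return LocusFit(
        lambda_k=float(lam[0]),
        gamma_blup=float(gamma[0]),
        gamma_var=float(gvar[0]),
        wald=float(wald[0]),
        p_value=wald_p(float(wald[0])),
        sigma2=float(sigma2[0]),
        loglik=float(loglik),
    )


def fixed_effect_locus(y_rot, X_rot, z_rot, D, lambda0) -> LocusFit:
    """GLS fixed-effect fit of one locus under the frozen polygenic ratio."""
    y_rot = np.asarray(y_rot, dtype=float).ravel()
    X_rot = np.atleast_2d(np.asarray(X_rot, dtype=float))
    if X_rot.shape[0] != y_rot.size:
        X_rot = X_rot.T
    z = np.asarray(z_rot, dtype=float).reshape(-1, 1)
    Dfull = np.asarray(D, dtype=float) * float(lambda0) + 1.0
    nu = y_rot.size - X_rot.shape[1]
    theta, kappa, Q0, _, _ = _projection_scalars(y_rot, X_rot, z, Dfull)
    gamma, gvar, sigma2, wald = _fixed_effect_stats(theta, kappa, Q0, nu)
    if theta[0] <= 1e-12 * max(Q0, 1.0):
        warnings.warn("locus column is collinear with fixed effects", stacklevel=2)
    return LocusFit(
        lambda_k=np.nan,
        gamma_blup=float(gamma[0]),
        gamma_var=float(gvar[0]),
        wald=float(wald[0]),
        p_value=wald_p(float(wald[0])),
        sigma2=float(sigma2[0]),
        loglik=np.nan,
    )


def _fixed_effect_stats(theta, kappa, Q0, nu):
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    ok = theta > 1e-12 * max(Q0, 1.0)
    th = np.where(ok, theta, 1.0)
    gamma = np.where(ok, kappa / th, 0.0)
    rss = np.maximum(Q0 - kappa**2 / th, 1e-300)
    sigma2 = rss / max(nu - 1, 1)
    gvar = sigma2 / th
    wald = np.where(ok, gamma**2 / gvar, 0.0)
    return gamma, np.where(ok, gvar, np.nan), sigma2, wald


def reml_loglik_dense(y, X, H, sigma2=None):
    """Restricted log-likelihood under covariance H * sigma2, O(n^3).

    With ``sigma2=None`` the scale is profiled out (REML estimate). Dense
    oracle for the rank-one scalar computations, used in verification.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    nu = n - p
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    Hi_y = np.linalg.solve(H, y)
    Hi_X = np.linalg.solve(H, X)
    A = X.T @ Hi_X
    signA, logdet_A = np.linalg.slogdet(A)
    coef = np.linalg.solve(A, X.T @ Hi_y)
    resid_quad = float(y @ Hi_y - (X.T @ Hi_y) @ coef)
    if sigma2 is None:
        sigma2 = resid_quad / nu
        return -0.5 * (
            nu * np.log(2.0 * np.pi * sigma2) + nu + logdet_H + logdet_A
        )
    return -0.5 * (
        nu * np.log(2.0 * np.pi * sigma2)
        + resid_quad / sigma2
        + logdet_H
        + logdet_A
    )
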