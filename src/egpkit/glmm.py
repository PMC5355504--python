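"""Poisson generalized linear mixed model via the Laplace approximation.

Implements maximum-likelihood estimation for a Poisson log-link mixed model
with an offset and independent (diagonal) random-effect variance terms,

    y_i ~ Poisson(mu_i),   log mu_i = x_i' beta + z_i' Lambda(theta) u + o_i,

with ``u ~ N(0, I)`` spherical and ``Lambda = diag(theta[theta_map])``
mapping each random-effect column to its standard-deviation parameter
(random intercepts and slopes are mutually uncorrelated).  For fixed
``(beta, theta)`` the random effects are profiled out by a penalized Newton
solve (PIRLS) and the marginal likelihood is approximated by Laplace's
method; the outer optimization runs over ``(beta, theta)`` jointly with
``theta >= 0``, mirroring how glmer fits the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve
from scipy.special import gammaln

_ETA_MAX = 30.0  # linear-predictor clip to avoid overflow in exp


@dataclass
class GLMMDesign:
    """Numeric design for one model: response, fixed/random matrices, offset."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    offset: np.ndarray
    theta_map: np.ndarray          # (q,) int: Z column -> theta index
    fixed_names: Sequence[str]
    theta_names: Sequence[str]

    @property
    def n_theta(self) -> int:
        return len(self.theta_names)


@dataclass
class GLMMResult:
    beta: np.ndarray
    se: np.ndarray
    theta: np.ndarray              # random-effect standard deviations
    u: np.ndarray                  # spherical random-effect modes
    loglik: float
    converged: bool
    singular: bool
    n_iter: int
    design: GLMMDesign
    message: str = ""

    @property
    def eta(self) -> np.ndarray:
        lam = self.theta[self.design.theta_map]
        return (self.design.X @ self.beta
                + (self.design.Z * lam) @ self.u + self.design.offset)

    @property
    def fitted(self) -> np.ndarray:
        """Conditional means (random effects at their modes)."""
        return np.exp(self.eta)

    @property
    def random_effects(self) -> np.ndarray:
        """Random effects on the natural scale, Lambda @ u."""
        return self.theta[self.design.theta_map] * self.u


def _pirls(y, eta_fixed, M, u0, max_iter=200, tol=1e-14):
    """Maximize the penalized Poisson log-likelihood over u.

    Returns (u, f, mu, H_chol_lower) at the optimum, where
    f = y'eta - sum(mu) - ||u||^2 / 2 and H = M' W M + I.
    """
    q = M.shape[1]
    u = u0.copy()
    eta = np.clip(eta_fixed + M @ u, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    f = y @ eta - mu.sum() - 0.5 * (u @ u)
    I = np.eye(q)
    L = None
    for it in range(max_iter):
        g = M.T @ (y - mu) - u
        H = (M.T * mu) @ M + I
        L = _safe_cho_factor(H)
        du = cho_solve(L, g)
        step = 1.0
        for _ in range(30):
            u_new = u + step * du
            eta_new = np.clip(eta_fixed + M @ u_new, -_ETA_MAX, _ETA_MAX)
            mu_new = np.exp(eta_new)
            f_new = y @ eta_new - mu_new.sum() - 0.5 * (u_new @ u_new)
            if f_new >= f - 1e-13:
                break
            step *= 0.5
        moved = abs(f_new - f)
        u, eta, mu, f = u_new, eta_new, mu_new, f_new
        if moved <= tol * (1.0 + abs(f)) and np.max(np.abs(g)) < 1e-6:
            break
    # refresh Hessian at the optimum
    H = (M.T * mu) @ M + np.eye(q)
    L = cholesky(_jitter(H), lower=True)
    return u, f, mu, L


def _jitter(H, tries=4):
    """Tiny escalating ridge; H is PD in exact arithmetic but extreme
    weights during outer-optimizer exploration can break potrf."""
    eps = 0.0
    for _ in range(tries):
        try:
            cholesky(H + eps * np.eye(H.shape[0]), lower=True)
            return H + eps * np.eye(H.shape[0])
        except np.linalg.LinAlgError:
            eps = max(eps * 100.0, 1e-10 * max(np.trace(H) / H.shape[0], 1.0))
    return H + eps * np.eye(H.shape[0])


def _safe_cho_factor(H):
    try:
        return cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        return cho_factor(_jitter(H), lower=True)


def laplace_nll_factory(design: GLMMDesign):
    """Closure computing the negative Laplace log-likelihood at (beta, theta),
    warm-starting the random-effect modes across calls."""
    y, X, Z, off = design.y, design.X, design.Z, design.offset
    p = X.shape[1]
    q = Z.shape[1]
    const = -gammaln(y + 1.0).sum()
    state = {"u": np.zeros(q)}

    def nll(params):
        beta = params[:p]
        theta = np.abs(params[p:])
        lam = theta[design.theta_map]
        M = Z * lam
        eta_fixed = X @ beta + off
        try:
            u, f, mu, L = _pirls(y, eta_fixed, M, state["u"])
        except np.linalg.LinAlgError:
            state["u"] = np.zeros(q)
            return 1e10
        state["u"] = u
        ll = f + const - np.log(np.diag(L)).sum()
        if not np.isfinite(ll):
            return 1e10
        return -ll

    return nll, state


def fit_laplace(design: GLMMDesign, beta0: Optional[np.ndarray] = None,
                theta0: float = 0.3, tol: float = 1e-8,
                max_outer: int = 500) -> GLMMResult:
    """ML fit of the Poisson mixed model by Laplace approximation.

    Non-convergence is flagged on the result, never raised; variance
    components estimated on the zero boundary set the ``singular`` flag.
    """
    y, X = design.y, design.X
    p, k = X.shape[1], design.n_theta
    if beta0 is None:
        beta0 = _poisson_glm_start(y, X, design.offset)
    x0 = np.concatenate([beta0, np.full(k, theta0)])
    nll, state = laplace_nll_factory(design)
    bounds = [(None, None)] * p + [(0.0, 50.0)] * k
    # the inner solve is converged to ~1e-14 relative, so a 1e-6 difference
    # step keeps finite-difference gradients well above the noise floor;
    # smaller steps stall the optimizer on the flat theta ridge
    opts = {"maxfun": 20000, "maxiter": max_outer, "ftol": tol * 1e-4,
            "gtol": 1e-8, "eps": 1e-6}
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options=opts)
    beta = res.x[:p]
    theta = np.abs(res.x[p:])
    # final inner solve at the optimum for SEs and fitted values
    lam = theta[design.theta_map]
    M = design.Z * lam
    u, f, mu, L = _pirls(y, X @ beta + design.offset, M, state["u"])
    se = _wald_se(X, M, mu)
    singular = bool(k > 0 and np.any(theta < 1e-4))
    ll = -nll(res.x)
    return GLMMResult(beta=beta, se=se, theta=theta, u=u, loglik=float(ll),
                      converged=bool(res.success), singular=singular,
                      n_iter=int(res.nit), design=design,
                      message=str(res.message))


def _poisson_glm_start(y, X, offset, n_iter=25):
    """Plain Poisson GLM IRLS for starting values."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.1)) - offset.mean() if X.shape[1] else 0.0
    for _ in range(n_iter):
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-10)
        XtW = X.T * W
        try:
            beta_new = solve(XtW @ X, XtW @ z, assume_a="pos")
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _wald_se(X, M, mu):
    """Standard errors conditional on the variance parameters.

    Uses the Schur complement of the joint (beta, u) Hessian:
    cov(beta) = (X'WX - X'WM (M'WM + I)^-1 M'WX)^-1.
    """
    XtW = X.T * mu
    A = XtW @ X
    if M.shape[1] > 0:
        B = XtW @ M
        H = (M.T * mu) @ M + np.eye(M.shape[1])
        A = A - B @ solve(H, B.T, assume_a="pos")
    cov = np.linalg.inv(A)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))
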