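"""Maximum-likelihood beta regression with logit mean link and constant
precision, a Gaussian random-intercept variant integrated by adaptive
Gauss-Hermite quadrature, and the likelihood-ratio test.

The beta density is parameterized by mean mu and precision phi:

    f(y; mu, phi) = Gamma(phi) / (Gamma(mu phi) Gamma((1-mu) phi))
                    * y^(mu phi - 1) (1-y)^((1-mu) phi - 1),

with logit(mu_i) = x_i' beta. Estimation is deterministic: starting values
come from a least-squares fit on the logit scale and a method-of-moments
precision, and the optimizer is quasi-Newton with the analytic gradient.
Responses must lie strictly inside (0, 1); use squeeze() first for data
containing exact 0s or 1s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats
from scipy.special import expit

from ._design import Design

_LOG_2PI = np.log(2.0 * np.pi)


class NonConvergenceError(RuntimeError):
    pass


def squeeze(y: np.ndarray, n: int) -> np.ndarray:
    """Smithson-Verkuilen transform mapping [0,1] responses into (0,1):
    y' = (y (n-1) + 0.5) / n. Order-preserving, with 0.5 a fixed point."""
    y = np.asarray(y, dtype=float)
    if n < 2:
        raise ValueError("squeeze requires n >= 2")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """A fitted fixed-effects beta regression."""

    coefficients: np.ndarray  # logit scale
    names: list[str]
    phi: float
    loglik: float
    vcov: np.ndarray  # covariance of coefficients
    phi_se: float
    n: int
    converged: bool
    design_info: Design | None = None
    y_key: tuple = field(default=(), repr=False)

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + 1  # beta plus phi


@dataclass
class MixedBetaRegFit(BetaRegFit):
    """Beta regression with a Gaussian random intercept on the logit scale."""

    sigma_u: float = 0.0
    boundary: bool = False
    group_modes: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + 2  # beta, phi, sigma_u


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def _beta_loglik_terms(y, ystar, log1my, eta, phi):
    # clip keeps the likelihood finite when a line-search step saturates the link
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * log1my
    )
    return ll, mu, a, b


def _negloglik_and_grad(theta, y, X, ystar, logy, log1my):
    p = X.shape[1]
    beta = theta[:p]
    phi = np.exp(theta[p])
    eta = X @ beta
    ll, mu, a, b = _beta_loglik_terms(y, ystar, log1my, eta, phi)
    mustar = special.digamma(a) - special.digamma(b)
    w = mu * (1.0 - mu)
    dl_deta = phi * (ystar - mustar) * w
    g_beta = X.T @ dl_deta
    dl_dphi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * logy
        + (1.0 - mu) * log1my
    )
    g = np.concatenate([g_beta, [phi * dl_dphi]])
    return -np.sum(ll), -g


def _start_values(y, X):
    z = special.logit(y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta0
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    mu0 = expit(X @ beta0)
    w = mu0 * (1.0 - mu0)
    sigma2 = np.maximum(s2 * w**2, 1e-10)
    phi0 = float(np.mean(w / sigma2) - 1.0)
    phi0 = min(max(phi0, 0.5), 1e6)
    return beta0, phi0


def _numerical_hessian(fun, x, eps=1e-5):
    k = len(x)
    H = np.empty((k, k))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        gp = fun(x + e)
        gm = fun(x - e)
        H[i] = (gp - gm) / (2.0 * steps[i])
    return 0.5 * (H + H.T)


def fit_beta(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    design_info: Design | None = None,
    maxiter: int = 500,
) -> BetaRegFit:
    """Fit a beta regression by maximum likelihood.

    Deterministic given (y, X): no randomness enters the optimization.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("rows of X must match length of y")
    if len(y) < X.shape[1] + 1:
        raise ValueError("need at least p + 1 observations")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1); squeeze first")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    p = X.shape[1]
    names = names or [f"x{j}" for j in range(p)]

    ystar = special.logit(y)
    logy = np.log(y)
    log1my = np.log1p(-y)
    beta0, phi0 = _start_values(y, X)
    theta0 = np.concatenate([beta0, [np.log(phi0)]])

    res = optimize.minimize(
        _negloglik_and_grad,
        theta0,
        args=(y, X, ystar, logy, log1my),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1.0, len(y)):
        raise NonConvergenceError(
            f"beta regression did not converge: {res.message}; "
            f"|grad|={np.linalg.norm(res.jac):.3g}"
        )
    theta = res.x
    phi = float(np.exp(theta[p]))

    grad_only = lambda t: _negloglik_and_grad(t, y, X, ystar, logy, log1my)[1]
    H = _numerical_hessian(grad_only, theta)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    vcov_beta = V[:p, :p]
    var_tau = max(V[p, p], 0.0)
    phi_se = phi * np.sqrt(var_tau)  # delta method from log phi

    return BetaRegFit(
        coefficients=theta[:p].copy(),
        names=list(names),
        phi=phi,
        loglik=float(-res.fun),
        vcov=0.5 * (vcov_beta + vcov_beta.T),
        phi_se=float(phi_se),
        n=len(y),
        converged=bool(res.success),
        design_info=design_info,
        y_key=(len(y), float(y.sum()), float((y**2).sum())),
    )


# ---------------------------------------------------------------------------
# Mixed model: Gaussian random intercept, adaptive Gauss-Hermite quadrature


def _group_index(group_ids) -> tuple[np.ndarray, int]:
    _, idx = np.unique(np.asarray(group_ids), return_inverse=True)
    return idx, int(idx.max()) + 1


def _mixed_negloglik(theta, y, X, ystar, logy, log1my, gidx, G, nodes, weights):
    """Marginal negative log-likelihood, integrating the random intercept
    per group by adaptive Gauss-Hermite quadrature centred on each group's
    conditional mode."""
    p = X.shape[1]
    beta = theta[:p]
    # clip keeps exploratory optimizer steps finite
    phi = np.exp(np.clip(theta[p], -30.0, 30.0))
    sigma = np.exp(np.clip(theta[p + 1], -30.0, 10.0))
    eta0 = X @ beta

    def h_of(u):
        # per-group log-integrand: group log-likelihood plus log prior
        eta = eta0 + u[gidx]
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll_i = (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * logy
            + (b - 1.0) * log1my
        )
        return (
            np.bincount(gidx, weights=ll_i, minlength=G)
            - 0.5 * (u / sigma) ** 2
            - np.log(sigma)
            - 0.5 * _LOG_2PI
        )

    def score_curv(u):
        eta = eta0 + u[gidx]
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * phi
        b = (1.0 - mu) * phi
        mustar = special.digamma(a) - special.digamma(b)
        w = mu * (1.0 - mu)
        score_i = phi * (ystar - mustar) * w
        curv_i = phi * (
            -phi * w**2 * (special.polygamma(1, a) + special.polygamma(1, b))
            + (ystar - mustar) * (1.0 - 2.0 * mu) * w
        )
        g1 = np.bincount(gidx, weights=score_i, minlength=G) - u / sigma**2
        g2 = np.bincount(gidx, weights=curv_i, minlength=G) - 1.0 / sigma**2
        return g1, g2

    # conditional modes: coarse-grid start (the log-integrand need not be
    # concave for extreme responses), then backtracking Newton
    resid = ystar - eta0
    span = max(4.0 * sigma, float(np.max(np.abs(resid))) + 1.0)
    grid = np.linspace(-span, span, 25)
    eta_grid = eta0[:, None] + grid[None, :]  # same offsets for every group
    mu_g = np.clip(expit(eta_grid), 1e-12, 1.0 - 1e-12)
    a_g = mu_g * phi
    b_g = (1.0 - mu_g) * phi
    ll_grid_i = (
        special.gammaln(phi)
        - special.gammaln(a_g)
        - special.gammaln(b_g)
        + (a_g - 1.0) * logy[:, None]
        + (b_g - 1.0) * log1my[:, None]
    )
    h_grid = np.empty((G, grid.size))
    for k in range(grid.size):
        h_grid[:, k] = np.bincount(gidx, weights=ll_grid_i[:, k], minlength=G)
    h_grid -= 0.5 * (grid[None, :] / sigma) ** 2
    u = grid[np.argmax(h_grid, axis=1)]
    h_cur = h_of(u)
    for _ in range(40):
        g1, g2 = score_curv(u)
        g2 = np.minimum(g2, -1e-10)
        step = np.clip(-g1 / g2, -3.0, 3.0)
        for _ in range(8):
            h_new = h_of(u + step)
            worse = h_new < h_cur - 1e-13
            if not worse.any():
                break
            step = np.where(worse, 0.5 * step, step)
        u = u + step
        h_cur = h_of(u)
        if np.max(np.abs(step)) < 1e-11:
            break

    # curvature at the mode sets the quadrature scale per group
    eta = eta0 + u[gidx]
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    mustar = special.digamma(a) - special.digamma(b)
    w = mu * (1.0 - mu)
    curv_i = phi * (
        -phi * w**2 * (special.polygamma(1, a) + special.polygamma(1, b))
        + (ystar - mustar) * (1.0 - 2.0 * mu) * w
    )
    h2 = np.bincount(gidx, weights=curv_i, minlength=G) - 1.0 / sigma**2
    scale = 1.0 / np.sqrt(-np.minimum(h2, -1e-10))  # (G,)

    # evaluate h at shifted nodes: u_gk = mode_g + scale_g * z_k
    z = nodes[None, :]  # (1, K)
    ugk = u[:, None] + scale[:, None] * z  # (G, K)
    eta_gk = eta0[:, None] + ugk[gidx]  # (n, K) via broadcasting of group rows
    mu_gk = np.clip(expit(eta_gk), 1e-12, 1.0 - 1e-12)
    a_gk = mu_gk * phi
    b_gk = (1.0 - mu_gk) * phi
    ll_ik = (
        special.gammaln(phi)
        - special.gammaln(a_gk)
        - special.gammaln(b_gk)
        + (a_gk - 1.0) * logy[:, None]
        + (b_gk - 1.0) * log1my[:, None]
    )
    ll_gk = np.zeros((G, nodes.size))
    for k in range(nodes.size):
        ll_gk[:, k] = np.bincount(gidx, weights=ll_ik[:, k], minlength=G)
    h_gk = ll_gk - 0.5 * (ugk / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI

    log_terms = h_gk + 0.5 * z**2 + np.log(weights)[None, :]
    ll_g = special.logsumexp(log_terms, axis=1) + np.log(scale)
    return -float(np.sum(ll_g)), u


def fit_beta_mixed(
    y: np.ndarray,
    X: np.ndarray,
    group_ids,
    names: list[str] | None = None,
    design_info: Design | None = None,
    n_nodes: int = 21,
    maxiter: int = 300,
    fix_sigma: float | None = None,
) -> MixedBetaRegFit:
    """Beta regression with a Gaussian random intercept u_g ~ N(0, sigma_u^2)
    on the logit scale, marginal likelihood by adaptive Gauss-Hermite
    quadrature (default 21 nodes).

    A fit driven to the sigma_u = 0 boundary is returned with
    ``boundary=True``, not raised. ``fix_sigma=0`` profiles the random
    intercept out entirely (the model collapses to the fixed-effects fit;
    useful because sigma_u is weakly identified when all groups are
    singletons).
    """
    if fix_sigma is not None and fix_sigma == 0.0:
        base = fit_beta(y, X, names=names, design_info=design_info)
        return MixedBetaRegFit(
            coefficients=base.coefficients,
            names=base.names,
            phi=base.phi,
            loglik=base.loglik,
            vcov=base.vcov,
            phi_se=base.phi_se,
            n=base.n,
            converged=base.converged,
            design_info=base.design_info,
            y_key=base.y_key,
            sigma_u=0.0,
            boundary=True,
            group_modes=None,
        )
    if fix_sigma is not None and fix_sigma < 0:
        raise ValueError("fix_sigma must be >= 0")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1); squeeze first")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    p = X.shape[1]
    names = names or [f"x{j}" for j in range(p)]
    gidx, G = _group_index(group_ids)

    ystar = special.logit(y)
    logy = np.log(y)
    log1my = np.log1p(-y)
    # probabilists' Hermite: sum_k w_k f(z_k) ~= int f(z) e^{-z^2/2} dz,
    # so int e^{h(u)} du = scale * sum_k w_k e^{h(m + scale z_k) + z_k^2 / 2}
    nodes, weights = hermegauss(n_nodes)

    # Identification restriction: when a group holds duplicated responses
    # (e.g. the same proportion entered once per listing body), the marginal
    # likelihood is unbounded along a phi -> inf, sigma > 0 ridge (each such
    # group contributes ~ sqrt(phi)). The scientifically meaningful optimum
    # is the interior mode, so the fit starts at the fixed-effects solution
    # and keeps phi within a wide window around it and sigma below 5 on the
    # logit scale.
    anchor = fit_beta(y, X, names=names)
    theta0 = np.concatenate(
        [anchor.coefficients, [np.log(anchor.phi)], [np.log(0.3)]]
    )
    log_phi_lo = np.log(anchor.phi) - np.log(50.0)
    log_phi_hi = np.log(anchor.phi) + np.log(50.0)
    log_sigma_floor = np.log(1e-4)
    log_sigma_cap = np.log(5.0)

    def obj(theta):
        return _mixed_negloglik(
            theta, y, X, ystar, logy, log1my, gidx, G, nodes, weights
        )[0]

    if fix_sigma is not None:
        sigma_bounds = (np.log(fix_sigma), np.log(fix_sigma))
    else:
        sigma_bounds = (log_sigma_floor, log_sigma_cap)
    bounds = (
        [(None, None)] * p + [(log_phi_lo, log_phi_hi)] + [sigma_bounds]
    )
    res = optimize.minimize(
        obj, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    theta = res.x
    phi = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    boundary = theta[p + 1] <= log_sigma_floor + 1e-6

    nll, modes = _mixed_negloglik(
        theta, y, X, ystar, logy, log1my, gidx, G, nodes, weights
    )

    # observed information; at a sigma boundary the sigma direction is
    # profiled out (its curvature is not informative there)
    dims = p + 1 if boundary else p + 2
    th_red = theta[:dims]

    def obj_red(t):
        full = np.concatenate([t, theta[dims:]])
        return obj(full)

    def grad_red(t):
        k = len(t)
        g = np.empty(k)
        steps = 1e-5 * np.maximum(1.0, np.abs(t))
        for i in range(k):
            e = np.zeros(k)
            e[i] = steps[i]
            g[i] = (obj_red(t + e) - obj_red(t - e)) / (2.0 * steps[i])
        return g

    H = _numerical_hessian(grad_red, th_red, eps=1e-4)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    vcov_beta = 0.5 * (V[:p, :p] + V[:p, :p].T)
    phi_se = phi * np.sqrt(max(V[p, p], 0.0))

    return MixedBetaRegFit(
        coefficients=theta[:p].copy(),
        names=list(names),
        phi=phi,
        loglik=float(-nll),
        vcov=vcov_beta,
        phi_se=float(phi_se),
        n=len(y),
        converged=bool(res.success),
        design_info=design_info,
        y_key=(len(y), float(y.sum()), float((y**2).sum())),
        sigma_u=0.0 if boundary else sigma,
        boundary=bool(boundary),
        group_modes=modes,
    )


def lrt(full: BetaRegFit, reduced: BetaRegFit) -> LRTResult:
    """Likelihood-ratio test of nested fits: chi2 = max(0, 2 dll) against a
    chi-square with df = difference in free-parameter counts."""
    if not set(reduced.names) <= set(full.names):
        raise ValueError(
            "models are not nested: reduced design columns "
            f"{set(reduced.names) - set(full.names)} absent from the full model"
        )
    if full.y_key != reduced.y_key:
        raise ValueError("fits were made on different response vectors")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# Estimator-style wrappers


class BetaRegression:
    """Fixed-effects beta regression with a scikit-learn flavoured API.

    Parameters are the link/precision conventions above; ``fit`` expects a
    design matrix (including any intercept column) and a response strictly
    inside (0, 1).
    """

    def __init__(self, maxiter: int = 500):
        self.maxiter = maxiter

    def get_params(self, deep: bool = True) -> dict:
        return {"maxiter": self.maxiter}

    def set_params(self, **params) -> "BetaRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BetaRegression":
        fit = fit_beta(y, X, maxiter=self.maxiter)
        self.result_ = fit
        self.coef_ = fit.coefficients
        self.phi_ = fit.phi
        self.loglik_ = fit.loglik
        self.vcov_ = fit.vcov
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted means on the response scale."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        return expit(np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef_)


class MixedBetaRegression(BetaRegression):
    """Random-intercept beta regression (adaptive Gauss-Hermite)."""

    def __init__(self, n_nodes: int = 21, maxiter: int = 300):
        self.n_nodes = n_nodes
        self.maxiter = maxiter

    def get_params(self, deep: bool = True) -> dict:
        return {"n_nodes": self.n_nodes, "maxiter": self.maxiter}

    def fit(self, X: np.ndarray, y: np.ndarray, group_ids=None) -> "MixedBetaRegression":
        if group_ids is None:
            raise ValueError("group_ids is required")
        fit = fit_beta_mixed(y, X, group_ids, n_nodes=self.n_nodes, maxiter=self.maxiter)
        self.result_ = fit
        self.coef_ = fit.coefficients
        self.phi_ = fit.phi
        self.sigma_u_ = fit.sigma_u
        self.loglik_ = fit.loglik
        self.vcov_ = fit.vcov
        self.n_features_in_ = X.shape[1]
        return self
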