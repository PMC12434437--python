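"""Beta regression with logit mean link, optionally with a random intercept.

The response y in (0,1) follows Beta(mu*phi, (1-mu)*phi) with logit(mu) = X b
and constant precision phi (log-parameterized). The mixed model adds a
group-level (year-level) Gaussian random intercept integrated out by a
Laplace approximation: per-group modes are found by an inner Newton
iteration (the groups are conditionally independent scalars), and the outer
quasi-Newton optimization runs over (b, log phi, log sigma).

Observations sharing a design row (and group) also share mu, so the
likelihood depends on them only through per-cell sufficient statistics
(count, sum log y, sum log(1-y)); duplicate rows are collapsed before
optimization, which makes fits on large pairwise-overlap tables cheap.

Pianka overlap can touch the boundaries 0 and 1, which the beta density
excludes; :func:`boundary_transform` applies the usual compression
y' = (y (n-1) + 0.5) / n, only when boundary values are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger(__name__)

_LOGIT_CLIP = 30.0


def boundary_transform(y, n: int | None = None):
    """Compress [0,1] data into (0,1): y' = (y(n-1) + 0.5)/n.

    Applied only when some value sits on a boundary; otherwise the data are
    returned unchanged. ``n`` defaults to the sample size.
    """
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("response values must lie in [0, 1]")
    if not ((y == 0) | (y == 1)).any():
        return y
    n = len(y) if n is None else n
    return (y * (n - 1) + 0.5) / n


def _sigmoid(eta):
    return special.expit(np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP))


@dataclass
class _Cells:
    """Sufficient statistics of observations collapsed by design row."""

    X: np.ndarray  # unique design rows (c, p)
    m: np.ndarray  # observations per cell
    sy: np.ndarray  # sum log y per cell
    s1y: np.ndarray  # sum log(1-y) per cell
    codes: np.ndarray | None = None  # group code per cell (GLMM)

    @property
    def ys(self) -> np.ndarray:
        return self.sy - self.s1y


def _collapse(Xm, y, codes=None) -> _Cells:
    key = Xm if codes is None else np.column_stack([Xm, codes])
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    m = np.bincount(inv).astype(float)
    sy = np.bincount(inv, weights=np.log(y))
    s1y = np.bincount(inv, weights=np.log1p(-y))
    return _Cells(
        X=Xm[first],
        m=m,
        sy=sy,
        s1y=s1y,
        codes=None if codes is None else np.asarray(codes)[first],
    )


def _cell_loglik(c: _Cells, mu, phi) -> float:
    a = mu * phi
    b = (1 - mu) * phi
    terms = (
        c.m * (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b))
        + (a - 1) * c.sy
        + (b - 1) * c.s1y
    )
    return float(terms.sum())


def _cell_dl_deta(c: _Cells, mu, phi) -> np.ndarray:
    mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
    return phi * (c.ys - c.m * mustar) * mu * (1 - mu)


def _cell_d2l_deta2(c: _Cells, mu, phi) -> np.ndarray:
    w = mu * (1 - mu)
    mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
    trig = special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
    return -(phi**2) * w**2 * c.m * trig + phi * (c.ys - c.m * mustar) * (1 - 2 * mu) * w


def _cell_dl_dphi(c: _Cells, mu, phi) -> float:
    term = c.m * (
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1 - mu) * special.digamma((1 - mu) * phi)
    )
    return float((term + mu * c.sy + (1 - mu) * c.s1y).sum())


@dataclass
class BetaFit:
    """A fitted beta regression (fixed effects, optional random intercept)."""

    params: pd.Series  # fixed-effect coefficients
    se: pd.Series
    phi: float
    loglik: float
    aic: float
    n_params: int
    fitted: np.ndarray
    converged: bool
    sigma_group: float | None = None
    group_effects: pd.Series | None = None
    boundary: bool = False
    message: str = ""
    meta: dict = field(default_factory=dict)

    def predict(self, X_new) -> np.ndarray:
        """Population-level predicted means (random intercept at 0)."""
        X_new = np.asarray(X_new, dtype=float)
        return _sigmoid(X_new @ self.params.to_numpy())


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _start_values(X, y):
    z = np.log(y) - np.log1p(-y)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sigma2 = max(float(resid.var()), 1e-6)
    mu = _sigmoid(X @ beta)
    # delta method: var(y) ~ sigma2 * (mu(1-mu))^2 and var(y) = mu(1-mu)/(1+phi)
    phi0 = float(np.mean(1.0 / (sigma2 * mu * (1 - mu)) - 1.0))
    phi0 = min(max(phi0, 0.5), 1e4)
    return beta, np.log(phi0)


def fit_beta_glm(X, y, names: list[str] | None = None) -> BetaFit:
    """Maximum-likelihood beta GLM with logit mean link and constant phi.

    Quasi-Newton (L-BFGS-B) with analytic gradient from a least-squares-on-
    logit start; standard errors from the numerically differentiated
    observed information.
    """
    Xm, colnames = _as_design(X)
    if names is not None:
        colnames = list(names)
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError(
            "y must lie strictly inside (0, 1); apply boundary_transform first"
        )
    n, p = Xm.shape
    cells = _collapse(Xm, y)
    beta0, logphi0 = _start_values(Xm, y)
    theta0 = np.concatenate([beta0, [logphi0]])

    def unpack(theta):
        return theta[:p], np.exp(theta[p])

    def negll(theta):
        beta, phi = unpack(theta)
        mu = _sigmoid(cells.X @ beta)
        return -_cell_loglik(cells, mu, phi)

    def grad(theta):
        beta, phi = unpack(theta)
        mu = _sigmoid(cells.X @ beta)
        g_beta = cells.X.T @ _cell_dl_deta(cells, mu, phi)
        return -np.concatenate([g_beta, [_cell_dl_dphi(cells, mu, phi) * phi]])

    res = optimize.minimize(
        negll, theta0, jac=grad, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    ll_start = -negll(theta0)
    if -res.fun < ll_start - 1e-6:
        logger.warning("fit_beta_glm: optimizer below start loglik")
    beta, phi = unpack(res.x)
    hess = _numeric_hessian(grad, res.x)
    se_full = _se_from_hessian(hess)
    k = p + 1
    ll = -res.fun
    fit = BetaFit(
        params=pd.Series(beta, index=colnames),
        se=pd.Series(se_full[:p], index=colnames),
        phi=float(phi),
        loglik=ll,
        aic=-2 * ll + 2 * k,
        n_params=k,
        fitted=_sigmoid(Xm @ beta),
        converged=bool(res.success),
        message=str(res.message),
    )
    if not res.success:
        logger.warning("fit_beta_glm did not converge: %s", res.message)
    return fit


def _numeric_hessian(grad_fn, theta, eps: float = 1e-5) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(theta[j]))
        H[:, j] = (grad_fn(theta + step) - grad_fn(theta - step)) / (2 * step[j])
    return (H + H.T) / 2


def _se_from_hessian(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(H.shape[0], np.nan)


# ---------------------------------------------------------------------------
# Laplace GLMM
# ---------------------------------------------------------------------------


def fit_beta_glmm(
    X,
    y,
    groups,
    names: list[str] | None = None,
    start: BetaFit | None = None,
) -> BetaFit:
    """Beta mixed model with a Gaussian random intercept per group.

    Marginal ML via the Laplace approximation. The inner problem (posterior
    modes of the per-group intercepts) is solved by Newton iterations, warm-
    started between outer steps; the outer L-BFGS-B runs over
    (b, log phi, log sigma). A sigma estimate collapsing to ~0 is flagged
    ``boundary`` and the fit then coincides with :func:`fit_beta_glm`.
    """
    Xm, colnames = _as_design(X)
    if names is not None:
        colnames = list(names)
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("y must lie strictly inside (0, 1)")
    codes_full, levels = pd.factorize(np.asarray(groups))
    G = len(levels)
    if G < 2:
        raise ValueError("grouping factor needs at least 2 levels")
    n, p = Xm.shape
    cells = _collapse(Xm, y, codes=codes_full)
    codes = cells.codes.astype(int)

    if start is None:
        start = fit_beta_glm(Xm, y, names=colnames)
    theta0 = np.concatenate(
        [start.params.to_numpy(), [np.log(start.phi)], [np.log(0.1)]]
    )
    u_cache = np.zeros(G)

    def inner_modes(beta, phi, sigma, u0):
        u = u0.copy()
        fixed = cells.X @ beta
        for _ in range(100):
            mu = _sigmoid(fixed + u[codes])
            g = np.bincount(codes, weights=_cell_dl_deta(cells, mu, phi), minlength=G)
            g -= u / sigma**2
            h = np.bincount(codes, weights=_cell_d2l_deta2(cells, mu, phi), minlength=G)
            h -= 1.0 / sigma**2
            h = np.minimum(h, -1e-10)
            step = g / h
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = _sigmoid(fixed + u[codes])
        h = np.bincount(codes, weights=_cell_d2l_deta2(cells, mu, phi), minlength=G)
        h -= 1.0 / sigma**2
        return u, mu, np.minimum(h, -1e-10)

    def neg_laplace(theta):
        beta = theta[:p]
        phi = np.exp(theta[p])
        sigma = np.exp(theta[p + 1])
        u, mu, h = inner_modes(beta, phi, sigma, u_cache)
        u_cache[:] = u
        ll = (
            _cell_loglik(cells, mu, phi)
            - (u**2).sum() / (2 * sigma**2)
            - G * np.log(sigma)
            - 0.5 * np.log(-h).sum()
        )
        return -ll

    bounds = [(None, None)] * p + [(-3.0, 14.0), (-10.0, 4.0)]
    res = optimize.minimize(
        neg_laplace, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 400, "ftol": 1e-11},
    )
    beta = res.x[:p]
    phi = float(np.exp(res.x[p]))
    sigma = float(np.exp(res.x[p + 1]))
    u, _, _ = inner_modes(beta, phi, sigma, u_cache)
    ll = -res.fun
    k = p + 2
    se = _se_from_laplace(neg_laplace, res.x, p)
    boundary = sigma < 1e-3
    fit = BetaFit(
        params=pd.Series(beta, index=colnames),
        se=pd.Series(se, index=colnames),
        phi=phi,
        loglik=ll,
        aic=-2 * ll + 2 * k,
        n_params=k,
        fitted=_sigmoid(Xm @ beta + u[codes_full]),
        converged=bool(res.success),
        sigma_group=sigma,
        group_effects=pd.Series(u, index=list(levels)),
        boundary=boundary,
        message=str(res.message),
    )
    if boundary:
        logger.info("fit_beta_glmm: sigma_group at boundary (~0)")
    if not res.success:
        logger.warning("fit_beta_glmm did not converge: %s", res.message)
    return fit


def _se_from_laplace(negll, theta, p, eps: float = 1e-4) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    f0 = negll(theta)
    steps = eps * np.maximum(1.0, np.abs(theta))
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fp[i] = negll(theta + ei)
        fm[i] = negll(theta - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = negll(theta + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
    se = _se_from_hessian(H)
    return se[:p]


def sample_beta(mu, phi, rng: np.random.Generator):
    """Draw Beta(mu*phi, (1-mu)*phi) variates (simulation helper)."""
    mu = np.asarray(mu, dtype=float)
    return rng.beta(mu * phi, (1 - mu) * phi)
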