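"""Dense EM-REML mixed-model solver on Henderson's mixed-model equations.

Model: y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k I) and
e ~ N(0, sigma2_e I).  Variance components are estimated by EM-REML:

    sigma2_k <- (u_k' u_k + sigma2_e * tr(C_kk)) / q_k
    sigma2_e <- y'(y - X b - Z u) / (n - rank(X))

where C_kk is the k-th diagonal block of the inverse MME coefficient matrix
(so that sigma2_e * C is the joint covariance of (b, u - u_hat)).  EM keeps
components non-negative by construction; a component collapsing toward zero
is frozen at zero to preserve conditioning.  Iteration stops when the
relative change of every component falls below ``rtol`` or after
``max_iter`` iterations.

Designs here are small (a few hundred plots, a few hundred effect levels),
so dense Cholesky factorisations of the MME are the fastest reliable route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


def indicator(levels: np.ndarray) -> tuple[np.ndarray, list]:
    """Dense 0/1 design matrix for a categorical vector; returns (Z, level list)."""
    uniq, inv = np.unique(levels, return_inverse=True)
    z = np.zeros((levels.size, uniq.size))
    z[np.arange(levels.size), inv] = 1.0
    return z, list(uniq)


@dataclass
class RandomTerm:
    name: str
    z: np.ndarray
    levels: list


@dataclass
class MixedModelFit:
    beta: np.ndarray
    cov_beta: np.ndarray          # sampling covariance of beta
    u: dict[str, np.ndarray]
    pev: dict[str, np.ndarray]    # prediction error variance (diagonal)
    variances: dict[str, float]
    sigma2_e: float
    n_iter: int
    converged: bool
    loglik_history: list[float]
    n_obs: int
    rank_x: int

    @property
    def residual_df(self) -> int:
        return self.n_obs - self.rank_x


def reml_loglik(
    y: np.ndarray, x: np.ndarray, terms: list[RandomTerm],
    variances: dict[str, float], sigma2_e: float,
) -> float:
    """Direct restricted log-likelihood (dense V; for small n / diagnostics)."""
    n = y.size
    v = sigma2_e * np.eye(n)
    for t in terms:
        s2 = variances[t.name]
        if s2 > 0:
            v += s2 * (t.z @ t.z.T)
    cv = linalg.cho_factor(v, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cv[0])))
    vi_x = linalg.cho_solve(cv, x)
    xtvix = x.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvix)
    beta = np.linalg.solve(xtvix, vi_x.T @ y)
    r = y - x @ beta
    quad = r @ linalg.cho_solve(cv, r)
    return -0.5 * (logdet_v + logdet_x + quad)


def fit_mixed(
    y: np.ndarray,
    x: np.ndarray,
    terms: list[RandomTerm],
    max_iter: int = 500,
    rtol: float = 1e-8,
    init: dict[str, float] | None = None,
    fixed_variances: dict[str, float] | None = None,
    fixed_sigma2_e: float | None = None,
    track_loglik: bool = False,
) -> MixedModelFit:
    """Fit the mixed model by EM-REML (or solve at fixed variances).

    ``fixed_variances``/``fixed_sigma2_e``: supply all components to skip
    estimation and just solve the MME (used by oracle tests and when a
    caller already knows the variance parameters).
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    rank_x = np.linalg.matrix_rank(x)

    w = np.hstack([x] + [t.z for t in terms]) if terms else x
    wtw = w.T @ w
    wty = w.T @ y
    yty = float(y @ y)

    sizes = [t.z.shape[1] for t in terms]
    ends = np.cumsum([p] + sizes)[1:]
    slices = {t.name: slice(int(ends[i] - sizes[i]), int(ends[i]))
              for i, t in enumerate(terms)}

    estimating = fixed_variances is None and fixed_sigma2_e is None
    if estimating:
        vy = float(np.var(y)) or 1.0
        sigma2_e = (init or {}).get("residual", 0.5 * vy)
        variances = {t.name: (init or {}).get(t.name, 0.1 * vy) for t in terms}
    else:
        if fixed_variances is None or fixed_sigma2_e is None:
            raise ValueError("fixed_variances and fixed_sigma2_e must be given together")
        variances = dict(fixed_variances)
        sigma2_e = float(fixed_sigma2_e)

    frozen = {t.name: variances[t.name] <= 0 for t in terms}
    floor = 1e-12
    loglik_history: list[float] = []
    n_iter = 0
    converged = not estimating

    def solve(variances, sigma2_e):
        a = wtw.copy()
        for t in terms:
            sl = slices[t.name]
            ridge = sigma2_e / max(variances[t.name], floor) if not frozen[t.name] else 1e12
            a[sl, sl] += np.eye(sl.stop - sl.start) * ridge
        c = linalg.cho_factor(a, lower=True)
        ainv = linalg.cho_solve(c, np.eye(a.shape[0]))
        sol = ainv @ wty
        return sol, ainv

    for n_iter in range(1, max_iter + 1 if estimating else 2):
        sol, ainv = solve(variances, sigma2_e)
        if not estimating:
            break
        new_vars = {}
        for t in terms:
            sl = slices[t.name]
            if frozen[t.name]:
                new_vars[t.name] = 0.0
                continue
            uk = sol[sl]
            tr = np.trace(ainv[sl, sl])
            s2 = (uk @ uk + sigma2_e * tr) / t.z.shape[1]
            if s2 < 1e-8 * max(sigma2_e, 1e-30):
                frozen[t.name] = True
                s2 = 0.0
            new_vars[t.name] = s2
        new_sigma2_e = (yty - sol @ wty) / (n - rank_x)
        if track_loglik:
            loglik_history.append(reml_loglik(y, x, terms, new_vars, new_sigma2_e))
        old = np.array([sigma2_e] + [variances[t.name] for t in terms])
        new = np.array([new_sigma2_e] + [new_vars[t.name] for t in terms])
        variances, sigma2_e = new_vars, new_sigma2_e
        denom = np.maximum(np.abs(old), 1e-12 * max(sigma2_e, 1.0))
        if np.all(np.abs(new - old) / denom < rtol):
            converged = True
            sol, ainv = solve(variances, sigma2_e)
            break

    beta = sol[:p]
    cov_beta = sigma2_e * ainv[:p, :p]
    u = {t.name: sol[slices[t.name]] for t in terms}
    pev = {t.name: sigma2_e * np.diag(ainv[slices[t.name], slices[t.name]]).copy()
           for t in terms}
    return MixedModelFit(
        beta=beta, cov_beta=cov_beta, u=u, pev=pev,
        variances={k: float(v) for k, v in variances.items()},
        sigma2_e=float(sigma2_e), n_iter=n_iter, converged=converged,
        loglik_history=loglik_history, n_obs=n, rank_x=int(rank_x),
    )
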