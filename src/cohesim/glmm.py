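"""Maximum-likelihood generalized linear mixed models via the Laplace
approximation.

Fits Poisson and Bernoulli (logit) mixed models with any number of
independent Gaussian random-effect terms — random intercepts or random
slopes, each with its own variance.  The algorithm is the classic
penalized-IRLS / Laplace scheme (the default in mixed-model packages across
languages):

1. for fixed variance parameters, the joint mode of (fixed effects β,
   random effects u) maximizes the penalized log-likelihood
   ``ll(y | Xβ + Zu) − u'Λ⁻¹u / 2`` via Newton steps solved with a sparse
   Schur complement on the random-effects block;
2. the Laplace-approximate marginal log-likelihood
   ``ll(û) − û'Λ⁻¹û/2 − log|Λ|/2 − log|Z'WZ + Λ⁻¹|/2``
   is maximized over the log standard deviations with a derivative-free
   outer optimizer.

Fixed-effect covariances are the Schur complement of the random-effects
block of the joint negative Hessian at the optimum, i.e. conditional on the
estimated variance parameters, matching mixed-model software convention.
Pseudo-R² values follow the variance-decomposition (marginal/conditional)
definition, with the lognormal approximation for the Poisson
observation-level variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import gammaln
from scipy.stats import norm

__all__ = ["RandomTerm", "GLMMFit", "fit_glmm"]

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class RandomTerm:
    """One variance component: ``values`` (1s for an intercept term, a
    covariate for a random slope) varying over the levels of ``codes``."""

    name: str
    codes: np.ndarray  # (n,) int level codes 0..n_levels-1
    n_levels: int
    values: np.ndarray | None = None  # None -> intercept (all ones)

    @classmethod
    def intercept(cls, name: str, labels: Sequence) -> "RandomTerm":
        codes, levels = pd.factorize(np.asarray(labels))
        return cls(name=name, codes=codes, n_levels=len(levels))

    @classmethod
    def slope(cls, name: str, labels: Sequence, values: Sequence) -> "RandomTerm":
        codes, levels = pd.factorize(np.asarray(labels))
        return cls(
            name=name, codes=codes, n_levels=len(levels),
            values=np.asarray(values, dtype=float),
        )


@dataclass
class GLMMFit:
    """Result of a Laplace-approximate GLMM fit."""

    family: str
    fe_names: list[str]
    fe_params: np.ndarray
    fe_se: np.ndarray
    fe_vcov: np.ndarray
    vc_sd: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    r2_marginal: float
    r2_conditional: float
    ranef: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def fe_zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.fe_params / self.fe_se

    @property
    def fe_pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.fe_zvalues))

    def ci95(self) -> dict[str, tuple[float, float]]:
        lo = self.fe_params - 1.959963984540054 * self.fe_se
        hi = self.fe_params + 1.959963984540054 * self.fe_se
        return {n: (float(a), float(b)) for n, a, b in zip(self.fe_names, lo, hi)}

    def coef(self, name: str) -> float:
        return float(self.fe_params[self.fe_names.index(name)])


def _build_z(terms: Sequence[RandomTerm], n: int) -> tuple[sparse.csc_matrix, np.ndarray]:
    """Sparse random-effects design and the per-column term index."""
    cols, rows, vals, term_of_col = [], [], [], []
    offset = 0
    for t_idx, term in enumerate(terms):
        v = np.ones(n) if term.values is None else term.values
        rows.append(np.arange(n))
        cols.append(term.codes + offset)
        vals.append(v)
        term_of_col.extend([t_idx] * term.n_levels)
        offset += term.n_levels
    if not terms:
        return sparse.csc_matrix((n, 0)), np.array([], dtype=int)
    z = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, offset),
    )
    return z, np.asarray(term_of_col)


def _loglik_mu_w(y: np.ndarray, eta: np.ndarray, family: str):
    """Pointwise log-likelihood sum, mean, and IRLS weight."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "poisson":
        mu = np.exp(eta)
        ll = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
        w = mu
    elif family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = mu * (1.0 - mu)
    else:
        raise ValueError(f"unsupported family {family!r}")
    return ll, mu, np.maximum(w, 1e-10)


class _LaplaceCore:
    """Stateful objective: penalized IRLS inner loop with warm starts."""

    def __init__(self, y, X, terms, family, offset):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.terms = list(terms)
        self.family = family
        self.n, self.p = self.X.shape
        self.offset = np.zeros(self.n) if offset is None else np.asarray(offset, float)
        self.Z, self.term_of_col = _build_z(self.terms, self.n)
        self.q = self.Z.shape[1]
        self.ZT = self.Z.T.tocsr()
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.q)
        self.last: dict | None = None

    def _penalized(self, beta, u, lam_inv):
        eta = self.X @ beta + self.Z @ u + self.offset
        ll, mu, w = _loglik_mu_w(self.y, eta, self.family)
        return ll - 0.5 * float(u @ (lam_inv * u)), mu, w

    def inner(
        self,
        log_sd: np.ndarray,
        beta_fixed: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-9,
    ):
        """Penalized-mode Newton iteration for the given per-term log-SDs.

        With ``beta_fixed=None`` the fixed effects are profiled at the joint
        (β, u) penalized mode; otherwise β is held at the supplied value and
        only the random-effects mode is found (used when β is part of the
        outer optimization, which maximizes the full Laplace objective the
        way lme4's glmer does).
        """
        sd = np.exp(np.clip(log_sd, -8.0, 4.0))
        lam_inv = (
            1.0 / (sd[self.term_of_col] ** 2) if self.q else np.zeros(0)
        )
        profile_beta = beta_fixed is None
        beta = self.beta.copy() if profile_beta else np.asarray(beta_fixed, float)
        u = self.u.copy()
        pll, mu, w = self._penalized(beta, u, lam_inv)
        X, Z, ZT, y = self.X, self.Z, self.ZT, self.y
        for _ in range(max_iter):
            resid = y - mu
            g_u = ZT @ resid - lam_inv * u if self.q else np.zeros(0)
            if self.q:
                U = (ZT @ (Z.multiply(w[:, None]))).tocsc()
                U = U + sparse.diags(lam_inv)
                U_lu = splu(U)
            if profile_beta:
                g_beta = X.T @ resid
                wx = X * w[:, None]
                A = X.T @ wx  # p x p
                if self.q:
                    C = ZT @ wx  # q x p (dense, p is small)
                    Uinv_C = U_lu.solve(np.asarray(C))
                    Uinv_gu = U_lu.solve(g_u)
                    S = A - C.T @ Uinv_C
                    rhs = g_beta - C.T @ Uinv_gu
                    d_beta = np.linalg.solve(S, rhs)
                    d_u = U_lu.solve(g_u - C @ d_beta)
                else:
                    d_beta = np.linalg.solve(A, g_beta)
                    d_u = np.zeros(0)
            else:
                d_beta = np.zeros(self.p)
                d_u = U_lu.solve(g_u) if self.q else np.zeros(0)
                if not self.q:
                    break
            # step halving on the penalized log-likelihood
            step = 1.0
            for _half in range(30):
                nb, nu = beta + step * d_beta, u + step * d_u
                new_pll, new_mu, new_w = self._penalized(nb, nu, lam_inv)
                if new_pll >= pll - 1e-12:
                    break
                step *= 0.5
            improved = new_pll - pll
            beta, u, mu, w = nb, nu, new_mu, new_w
            pll = new_pll
            if abs(improved) < tol * (1.0 + abs(pll)):
                break
        if profile_beta:
            self.beta = beta  # warm start for the next call
        self.u = u
        # log|U| and Schur complement at the converged mode
        if self.q:
            wx = X * w[:, None]
            A = X.T @ wx
            C = ZT @ wx
            U = (ZT @ (Z.multiply(w[:, None]))).tocsc() + sparse.diags(lam_inv)
            U_lu = splu(U)
            logdet_U = float(np.sum(np.log(np.abs(U_lu.U.diagonal()))))
            Uinv_C = U_lu.solve(np.asarray(C))
            S = A - C.T @ Uinv_C
            logdet_lam = float(np.sum(np.log(sd[self.term_of_col] ** 2)))
            laplace_ll = pll - 0.5 * logdet_lam - 0.5 * logdet_U
        else:
            wx = X * w[:, None]
            S = X.T @ wx
            laplace_ll = pll
        self.last = {
            "beta": beta, "u": u, "S": S, "pll": pll, "loglik": laplace_ll,
            "sd": sd,
        }
        return laplace_ll

    def objective(self, log_sd: np.ndarray) -> float:
        return -self.inner(np.atleast_1d(log_sd))

    def objective_full(self, params: np.ndarray) -> float:
        """Negative Laplace log-likelihood over (log-SDs, β) jointly."""
        k = len(self.terms)
        return -self.inner(params[:k], beta_fixed=params[k:])


def fit_glmm(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    terms: Sequence[RandomTerm],
    family: str = "poisson",
    offset: Sequence[float] | None = None,
    start_sd: float = 0.3,
) -> GLMMFit:
    """Fit a Poisson or Bernoulli-logit mixed model by Laplace-approximate ML.

    Parameters
    ----------
    y:
        Response vector (non-negative integers for ``poisson``, 0/1 for
        ``binomial``).
    X:
        Fixed-effects design; a DataFrame contributes its column names.
    terms:
        Independent random-effect terms (see :class:`RandomTerm`); may be
        empty, in which case a plain GLM is fitted.
    """
    if isinstance(X, pd.DataFrame):
        fe_names = [str(c) for c in X.columns]
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        fe_names = [f"x{i}" for i in range(X_arr.shape[1])]
    y_arr = np.asarray(y, dtype=float)
    if family == "poisson" and np.any((y_arr < 0) | (y_arr != np.round(y_arr))):
        raise ValueError("poisson response must be non-negative integers")
    if family == "binomial" and not np.isin(y_arr, (0.0, 1.0)).all():
        raise ValueError("binomial response must be binary 0/1")

    core = _LaplaceCore(y_arr, X_arr, terms, family, offset)
    converged = True
    if terms:
        k = len(terms)
        x0 = np.full(k, np.log(start_sd))
        # stage 1: variance parameters with β profiled at the joint mode
        res = optimize.minimize(
            core.objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400 * k},
        )
        core.inner(res.x)
        # stage 2: polish (θ, β) against the full Laplace objective, the
        # criterion glmer-style estimators maximize
        x1 = np.concatenate([res.x, core.beta])
        res2 = optimize.minimize(
            core.objective_full, x1, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 300 * len(x1)},
        )
        converged = bool(res.success and res2.success)
        theta_hat, beta_hat = res2.x[:k], res2.x[k:]
        core.inner(theta_hat, beta_fixed=beta_hat)  # leave `last` at the optimum
        sd_hat = np.exp(np.clip(theta_hat, -8.0, 4.0))
    else:
        core.inner(np.zeros(0))
        sd_hat = np.zeros(0)

    last = core.last
    fe_vcov = np.linalg.inv(last["S"])
    fe_se = np.sqrt(np.diag(fe_vcov))

    # Nakagawa-style variance decomposition
    eta_fixed = X_arr @ last["beta"]
    var_f = float(np.var(eta_fixed))
    var_re = 0.0
    for t_idx, term in enumerate(terms):
        v = 1.0 if term.values is None else float(np.mean(np.square(term.values)))
        var_re += float(sd_hat[t_idx] ** 2) * v
    if family == "binomial":
        var_dist = np.pi**2 / 3.0
    else:
        lam_bar = float(np.exp(np.mean(eta_fixed) + var_re / 2.0))
        var_dist = float(np.log1p(1.0 / max(lam_bar, 1e-12)))
    denom = var_f + var_re + var_dist
    ranef: dict[str, np.ndarray] = {}
    off = 0
    for term in terms:
        ranef[term.name] = last["u"][off : off + term.n_levels]
        off += term.n_levels
    return GLMMFit(
        family=family,
        fe_names=fe_names,
        fe_params=last["beta"],
        fe_se=fe_se,
        fe_vcov=fe_vcov,
        vc_sd={t.name: float(s) for t, s in zip(terms, sd_hat)},
        loglik=float(last["loglik"]),
        n_obs=core.n,
        converged=converged,
        r2_marginal=var_f / denom if denom > 0 else np.nan,
        r2_conditional=(var_f + var_re) / denom if denom > 0 else np.nan,
        ranef=ranef,
    )
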