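"""Gaussian linear mixed models with crossed random intercepts.

Fits ``y = X beta + sum_k Z_k u_k + e`` by REML, where each ``u_k`` is a
vector of independent random intercepts for one grouping factor (e.g.
participant 1, participant 2, target) and the factors may be fully crossed.
The variance-ratio parameters ``lambda_k = var(u_k) / var(e)`` are profiled
out of the REML deviance using the low-rank (Woodbury) identity, so each
objective evaluation costs O(q^3) with q the total number of random levels
-- small for dyadic designs even when n_obs is large.

Satterthwaite degrees of freedom for each fixed effect are computed from
the gradient of the effect's sampling variance with respect to the variance
components and the inverse Hessian of the REML deviance (the same
construction used by the reference mixed-model literature), with
finite-difference derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = ["MixedLMResult", "fit_crossed_lmm"]

# variance ratios below this (relative to residual variance) are treated as
# on the boundary and excluded from the Satterthwaite Hessian
_BOUNDARY_TOL = 1e-8


@dataclass
class MixedLMResult:
    """REML fit of a crossed-random-intercepts model."""

    params: np.ndarray              # fixed-effect estimates
    se: np.ndarray                  # standard errors
    df_sat: np.ndarray              # Satterthwaite df per fixed effect
    sigma2: float                   # residual variance
    re_var: dict[str, float]        # random-intercept variances by factor
    fe_names: list[str]
    n_obs: int
    converged: bool
    reml_deviance: float
    notes: list[str] = field(default_factory=list)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.se

    def pvalues(self, df: np.ndarray | None = None) -> np.ndarray:
        """Two-tailed p values at the given (default Satterthwaite) df."""
        df = self.df_sat if df is None else np.asarray(df, dtype=float)
        return 2.0 * stats.t.sf(np.abs(self.tvalues), df)


def _design(groups: dict[str, np.ndarray]):
    """Integer-code each grouping factor and build a dense indicator Z."""
    codes, sizes, names = [], [], []
    for name, g in groups.items():
        c, levels = pd.factorize(np.asarray(g))
        if (c < 0).any():
            raise ValueError(f"missing values in grouping factor {name!r}")
        codes.append(c)
        sizes.append(len(levels))
        names.append(name)
    n = len(codes[0])
    q = int(np.sum(sizes))
    Z = np.zeros((n, q))
    offset = 0
    block = np.empty(len(sizes), dtype=object)
    for k, (c, s) in enumerate(zip(codes, sizes)):
        Z[np.arange(n), offset + c] = 1.0
        block[k] = slice(offset, offset + s)
        offset += s
    return Z, list(block), sizes, names


class _REMLWorkspace:
    """Precomputed cross-products for fast profiled-REML evaluations."""

    def __init__(self, y, X, Z, blocks):
        self.n, self.p = X.shape
        self.blocks = blocks
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.q = Z.shape[1]

    def _scale(self, lam):
        s = np.empty(self.q)
        for lk, bl in zip(lam, self.blocks):
            s[bl] = np.sqrt(max(lk, 0.0))
        return s

    def core(self, lam):
        """Return (XtVX, XtVy, ytVy, logdetW) for V0 = I + Z G Z'."""
        s = self._scale(lam)
        W = (self.ZtZ * s[:, None]) * s[None, :]
        W[np.diag_indices_from(W)] += 1.0
        L = np.linalg.cholesky(W)
        logdetW = 2.0 * np.sum(np.log(np.diag(L)))
        B = s[:, None] * self.ZtX          # S Z'X
        a = s * self.Zty                   # S Z'y
        LiB = solve_triangular(L, B, lower=True)
        Lia = solve_triangular(L, a, lower=True)
        XtVX = self.XtX - LiB.T @ LiB
        XtVy = self.Xty - LiB.T @ Lia
        ytVy = self.yty - Lia @ Lia
        return XtVX, XtVy, ytVy, logdetW

    def profiled_deviance(self, lam):
        """-2 REML log-likelihood with sigma2 profiled out (up to const)."""
        XtVX, XtVy, ytVy, logdetW = self.core(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - beta @ XtVy, 1e-12)
        nmp = self.n - self.p
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return nmp * np.log(rss / nmp) + logdetW + logdetX

    def reml_deviance_v(self, v):
        """-2 REML log-likelihood as a function of raw variances.

        ``v = (var_1, ..., var_K, var_e)`` on the variance scale; used for
        the Satterthwaite Hessian.
        """
        ve = v[-1]
        lam = np.maximum(v[:-1], 0.0) / ve
        XtVX, XtVy, ytVy, logdetW = self.core(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - beta @ XtVy, 1e-12)
        _, logdetX = np.linalg.slogdet(XtVX)
        return ((self.n - self.p) * np.log(ve) + logdetW + logdetX
                + rss / ve)

    def fe_variance(self, v, c):
        """Sampling variance of contrast c'beta at variance parameters v."""
        ve = v[-1]
        lam = np.maximum(v[:-1], 0.0) / ve
        XtVX, _, _, _ = self.core(lam)
        return ve * float(c @ np.linalg.solve(XtVX, c))


def _satterthwaite(ws: _REMLWorkspace, v_hat: np.ndarray) -> np.ndarray:
    """Satterthwaite df for every fixed effect at the REML estimate."""
    free = [k for k in range(len(v_hat) - 1)
            if v_hat[k] > _BOUNDARY_TOL * v_hat[-1]]
    free.append(len(v_hat) - 1)
    steps = np.array([max(abs(v_hat[k]), v_hat[-1]) * 1e-4 for k in free])

    def dev(vsub):
        v = v_hat.copy()
        v[free] = vsub
        return ws.reml_deviance_v(v)

    m = len(free)
    v0 = v_hat[free]
    H = np.empty((m, m))
    f0 = dev(v0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            if i == j:
                H[i, i] = (dev(v0 + ei) - 2 * f0 + dev(v0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    dev(v0 + ei + ej) - dev(v0 + ei - ej)
                    - dev(v0 - ei + ej) + dev(v0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)

    df = np.empty(ws.p)
    for j in range(ws.p):
        c = np.zeros(ws.p); c[j] = 1.0
        f = ws.fe_variance(v_hat, c)
        g = np.empty(m)
        for i in range(m):
            e = np.zeros(m); e[i] = steps[i]
            vp, vm = v_hat.copy(), v_hat.copy()
            vp[free] += e
            vm[free] -= e
            g[i] = (ws.fe_variance(vp, c) - ws.fe_variance(vm, c)) / (2 * steps[i])
        denom = float(g @ cov @ g)
        df[j] = 2.0 * f ** 2 / denom if denom > 0 else np.inf
    return df


def fit_crossed_lmm(
    y,
    X,
    groups: dict[str, np.ndarray],
    fe_names: list[str] | None = None,
    satterthwaite: bool = True,
) -> MixedLMResult:
    """Fit a Gaussian LMM with crossed random intercepts by REML.

    Parameters
    ----------
    y : array-like, shape (n,)
        Outcome.
    X : array-like, shape (n, p)
        Fixed-effect design (include an intercept column explicitly).
    groups : dict mapping factor name -> length-n label array
        One random intercept per factor; factors may be crossed.
    fe_names : optional fixed-effect names for reporting.
    satterthwaite : compute Satterthwaite df (skip for speed if unused).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have mismatched lengths")
    if not groups:
        raise ValueError("at least one random-intercept factor is required")
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]

    Z, blocks, sizes, names = _design(groups)
    ws = _REMLWorkspace(y, X, Z, blocks)
    K = len(blocks)

    notes: list[str] = []
    best = None
    for start in ([1.0] * K, [0.1] * K, [0.01] * K):
        res = optimize.minimize(
            ws.profiled_deviance, x0=np.array(start),
            method="L-BFGS-B", bounds=[(0.0, None)] * K,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    lam = np.maximum(best.x, 0.0)
    converged = bool(best.success) or np.isfinite(best.fun)
    if not best.success:
        notes.append(f"optimizer message: {best.message}")

    XtVX, XtVy, ytVy, _ = ws.core(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-12)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtVX)))
    v_hat = np.append(lam * sigma2, sigma2)

    if satterthwaite:
        df = _satterthwaite(ws, v_hat)
    else:
        df = np.full(p, np.nan)

    for k, name in enumerate(names):
        if lam[k] <= _BOUNDARY_TOL:
            notes.append(f"random-intercept variance for {name!r} "
                         "estimated at the zero boundary")

    return MixedLMResult(
        params=beta, se=se, df_sat=df, sigma2=sigma2,
        re_var={name: float(lam[k] * sigma2) for k, name in enumerate(names)},
        fe_names=list(fe_names), n_obs=n, converged=converged,
        reml_deviance=float(best.fun), notes=notes,
    )
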