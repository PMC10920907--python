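"""Restricted-maximum-likelihood linear mixed models with AR(1) residuals.

A compact REML engine for the model family used by the temporal-trend
stage: Gaussian responses with

* fixed effects ``X beta``,
* independent random effects (intercepts and slopes) whose grouping
  factors all nest inside one top-level blocking factor (the site), one
  variance per effect column (diagonal G), and
* residuals that are AR(1)-correlated within declared time series
  (``corr = phi ** |t_i - t_j|``, a continuous-time AR(1) that handles
  gapped years) and independent across series.

The implementation exploits two structures.  The AR(1) correlation is
Markov, so its Cholesky whitening is exact quasi-differencing: within
a series ordered by time, ``x~_t = (x_t - phi**d * x_{t-1}) /
sqrt(1 - phi**(2d))`` with gap ``d``, vectorized over all rows at
once.  The random effects enter through the Woodbury identity on the
whitened cross-products, so each REML objective evaluation costs a few
small q x q Cholesky factorizations per site block instead of an
n x n one.  Variance components are profiled on the residual variance
and optimized on the log scale; phi on an atanh scale (constrained
non-negative: positive temporal autocorrelation).

Denominator degrees of freedom for the Wald F tests (all fixed terms
in the trend models are single-df) come from a numerical Satterthwaite
approximation, or a fast containment-style residual count.

This module is deliberately small: it fits exactly the structures the
trend models need, no more.  statsmodels' MixedLM covers the random
effects but not the AR(1) residual correlation, which is essential for
calibrated year-effect tests on repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve


@dataclass
class RandomComponent:
    """One independent random-effect column: var * Σ_levels z_l z_l'."""

    name: str
    codes: np.ndarray   # int level codes per row; levels nest within blocks
    z: np.ndarray       # covariate multiplying the effect (1.0 for intercepts)


@dataclass
class LMMFit:
    """A converged REML fit."""

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    varcomps: dict            # component name -> variance (response scale)
    sigma2: float             # residual variance
    phi: float                # AR(1) parameter (0 if not modelled)
    m2reml: float             # -2 * restricted log-likelihood
    aic: float
    ftable: pd.DataFrame      # term, df, ddf, F, p (one-sided F test)
    n: int
    converged: bool
    log: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return -0.5 * self.m2reml


class _Workspace:
    """Row ordering, per-block random designs, AR(1) predecessor links."""

    def __init__(self, X, y, blocks, components, series, times, ar1):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        blocks = np.asarray(blocks)
        n = len(y)
        if ar1:
            if series is None or times is None:
                raise ValueError("ar1=True needs series and times")
            series = np.asarray(series)
            times = np.asarray(times, dtype=float)
            order = np.lexsort((times, series, blocks))
        else:
            order = np.argsort(blocks, kind="stable")
        self.X = X[order]
        self.y = y[order]
        blocks = blocks[order]
        self.n, self.p = self.X.shape
        if self.p != np.linalg.matrix_rank(self.X):
            raise ValueError("fixed-effects design is rank deficient")
        self.ar1 = ar1
        self.component_names = [c.name for c in components]

        # AR(1) predecessor gap per row (NaN marks the first row of a series)
        if ar1:
            s = series[order]
            t = times[order]
            gap = np.full(n, np.nan)
            same = np.empty(n, dtype=bool)
            same[0] = False
            same[1:] = s[1:] == s[:-1]
            gap[same] = t[np.flatnonzero(same)] - t[np.flatnonzero(same) - 1]
            if np.any(gap[same] <= 0):
                raise ValueError("duplicate or non-increasing times within a series")
            self.gap = gap
        else:
            self.gap = None

        # contiguous block slices
        change = np.flatnonzero(blocks[1:] != blocks[:-1]) + 1
        bounds = np.concatenate([[0], change, [n]])
        self.block_slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

        # dense per-block random designs; col_comp maps columns -> component
        self.Z = []
        self.col_comp = []
        for sl in self.block_slices:
            mats = []
            comp_idx = []
            for k, c in enumerate(components):
                codes = np.asarray(c.codes)[order][sl]
                z = np.asarray(c.z, dtype=float)[order][sl]
                levels, inv = np.unique(codes, return_inverse=True)
                Zk = np.zeros((sl.stop - sl.start, len(levels)))
                Zk[np.arange(len(inv)), inv] = z
                mats.append(Zk)
                comp_idx.extend([k] * len(levels))
            self.Z.append(np.hstack(mats) if mats else np.zeros((sl.stop - sl.start, 0)))
            self.col_comp.append(np.asarray(comp_idx, dtype=int))
        self.k_comp = len(components)

    # ---- parameter transforms -------------------------------------------
    def n_theta(self) -> int:
        return self.k_comp + (1 if self.ar1 else 0)

    def split(self, theta):
        gammas = np.exp(theta[: self.k_comp])
        phi = float(np.tanh(theta[self.k_comp])) if self.ar1 else 0.0
        return gammas, phi

    # ---- core linear algebra --------------------------------------------
    def _whiten_coefs(self, phi):
        """Rowwise (a, b): x~ = (x - a * x_prev) / b; logdet of D."""
        if not self.ar1 or phi == 0.0:
            return None
        a = np.zeros(self.n)
        b = np.ones(self.n)
        has_prev = ~np.isnan(self.gap)
        d = self.gap[has_prev]
        a[has_prev] = phi**d
        b[has_prev] = np.sqrt(1.0 - phi ** (2 * d))
        return a, b

    def _pieces(self, theta):
        """X'V0⁻¹X, X'V0⁻¹y, y'V0⁻¹y, log|V0| via whitening + Woodbury."""
        gammas, phi = self.split(theta)
        ab = self._whiten_coefs(phi)
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        logdet = 0.0
        for sl, Z, cc in zip(self.block_slices, self.Z, self.col_comp):
            Xb = self.X[sl]
            yb = self.y[sl]
            if ab is not None:
                a = ab[0][sl][:, None]
                b = ab[1][sl][:, None]
                first = a[:, 0] == 0.0
                Xw = np.where(first[:, None], Xb, Xb - a * np.vstack([Xb[:1], Xb[:-1]])) / b
                yb2 = yb[:, None]
                yw = (np.where(first[:, None], yb2, yb2 - a * np.vstack([yb2[:1], yb2[:-1]])) / b)[:, 0]
                Zw = np.where(first[:, None], Z, Z - a * np.vstack([Z[:1], Z[:-1]])) / b
                logdet += 2.0 * np.log(ab[1][sl]).sum()
            else:
                Xw, yw, Zw = Xb, yb, Z
            Sxx = Xw.T @ Xw
            Sxy = Xw.T @ yw
            Syy = yw @ yw
            if Z.shape[1]:
                g = gammas[cc]
                Szz = Zw.T @ Zw
                M = Szz + np.diag(1.0 / g)
                cf = cho_factor(M, lower=True)
                logdet += np.log(g).sum() + 2.0 * np.log(np.diag(cf[0])).sum()
                Szx = Zw.T @ Xw
                Szy = Zw.T @ yw
                MiSzx = cho_solve(cf, Szx)
                MiSzy = cho_solve(cf, Szy)
                Sxx = Sxx - Szx.T @ MiSzx
                Sxy = Sxy - Szx.T @ MiSzy
                Syy = Syy - Szy @ MiSzy
            XtViX += Sxx
            XtViy += Sxy
            ytViy += Syy
        return XtViX, XtViy, ytViy, logdet

    def m2reml_profiled(self, theta):
        try:
            XtViX, XtViy, ytViy, logdet = self._pieces(theta)
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = float(ytViy - beta @ XtViy)
        df = self.n - self.p
        sigma2 = rss / df
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0 or sigma2 <= 0 or not np.isfinite(sigma2):
            return np.inf
        return df * (1.0 + np.log(2 * np.pi * sigma2)) + logdet + logdetXtViX

    def m2reml_full(self, psi):
        """Unprofiled -2 REML with psi = (theta..., log sigma2)."""
        theta, logs2 = psi[:-1], psi[-1]
        s2 = np.exp(logs2)
        XtViX, XtViy, ytViy, logdet = self._pieces(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = float(ytViy - beta @ XtViy)
        df = self.n - self.p
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        return df * np.log(2 * np.pi) + df * np.log(s2) + logdet + logdetXtViX + rss / s2

    def beta_cov(self, theta, sigma2):
        XtViX, XtViy, _, _ = self._pieces(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        cov = sigma2 * np.linalg.inv(XtViX)
        return beta, cov


def fit_lmm(
    y,
    X: pd.DataFrame,
    blocks,
    components: list[RandomComponent] = (),
    series=None,
    times=None,
    ar1: bool = False,
    ddf_method: str = "satterthwaite",
    maxiter: int = 200,
) -> LMMFit:
    """Fit the mixed model by REML.

    ``X`` is the fixed-effects design (DataFrame; column names label
    the F table).  ``blocks`` is the top-level grouping factor (site);
    every random component's levels and every AR(1) series must nest
    inside it.  ``series``/``times`` declare the repeated-measures
    structure when ``ar1`` is on (times in integer experiment years).
    """
    names = list(X.columns)
    ws = _Workspace(X.to_numpy(dtype=float), np.asarray(y, float), blocks,
                    list(components), series, times, ar1)

    log: list[str] = []
    k = ws.n_theta()
    if k:
        theta0 = np.full(k, np.log(0.1))
        if ar1:
            theta0[-1] = np.arctanh(0.3)
        bounds = [(-12.0, 8.0)] * ws.k_comp + ([(0.0, 2.8)] if ar1 else [])
        res = optimize.minimize(
            ws.m2reml_profiled, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        converged = bool(res.success and np.isfinite(res.fun))
        if not converged:
            log.append(f"optimizer: {res.message}")
        theta = res.x
        m2 = float(res.fun)
    else:
        theta = np.zeros(0)
        m2 = float(ws.m2reml_profiled(theta))
        converged = True

    XtViX, XtViy, ytViy, _ = ws._pieces(theta)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = float(ytViy - beta @ XtViy)
    sigma2 = rss / (ws.n - ws.p)
    cov = sigma2 * np.linalg.inv(XtViX)
    gammas, phi = ws.split(theta) if k else (np.zeros(0), 0.0)

    varcomps = {name: float(g * sigma2) for name, g in zip(ws.component_names, gammas)}
    aic = m2 + 2 * (ws.p + k + 1)

    se = np.sqrt(np.diag(cov))
    if ddf_method == "satterthwaite" and k:
        psi_hat = np.concatenate([theta, [np.log(sigma2)]])
        ddfs = _satterthwaite_ddf(ws, psi_hat, cov)
    else:
        # containment-style: observations minus finest-grouping levels minus rank
        n_levels = np.zeros(ws.k_comp, dtype=int)
        for cc_blk in ws.col_comp:
            for j in range(ws.k_comp):
                n_levels[j] += int(np.sum(cc_blk == j))
        finest = int(n_levels.max()) if ws.k_comp else 0
        ddfs = np.full(ws.p, float(max(ws.n - finest - ws.p, 2)))

    F = (beta / se) ** 2
    pvals = stats.f.sf(F, 1, ddfs)
    ftable = pd.DataFrame(
        {"term": names, "df": 1, "ddf": ddfs, "F": F, "p": pvals}
    ).set_index("term")

    return LMMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        varcomps=varcomps,
        sigma2=float(sigma2),
        phi=float(phi),
        m2reml=m2,
        aic=float(aic),
        ftable=ftable,
        n=ws.n,
        converged=converged,
        log=log,
    )


def _satterthwaite_ddf(ws: _Workspace, psi_hat: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Numerical Satterthwaite denominator df per fixed coefficient.

    ddf_j = 2 var_j² / (g_j' A g_j) with var_j = Cov(beta)_jj as a
    function of the variance parameters psi, g_j its finite-difference
    gradient at the REML estimate, and A the asymptotic covariance of
    psi (twice the inverse Hessian of -2 REML).
    """
    m = len(psi_hat)
    h = 1e-3

    def covdiag(psi):
        theta, logs2 = psi[:-1], psi[-1]
        _, c = ws.beta_cov(theta, np.exp(logs2))
        return np.diag(c).copy()

    base = np.diag(cov).copy()
    grads = np.zeros((ws.p, m))
    for i in range(m):
        up = psi_hat.copy()
        dn = psi_hat.copy()
        up[i] += h
        dn[i] -= h
        grads[:, i] = (covdiag(up) - covdiag(dn)) / (2 * h)

    H = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            pp = psi_hat.copy(); pp[i] += h; pp[j] += h
            pm = psi_hat.copy(); pm[i] += h; pm[j] -= h
            mp = psi_hat.copy(); mp[i] -= h; mp[j] += h
            mm = psi_hat.copy(); mm[i] -= h; mm[j] -= h
            H[i, j] = H[j, i] = (
                ws.m2reml_full(pp) - ws.m2reml_full(pm) - ws.m2reml_full(mp) + ws.m2reml_full(mm)
            ) / (4 * h * h)
    try:
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        A = 2.0 * np.linalg.pinv(H)

    ddfs = np.empty(ws.p)
    fallback = float(max(ws.n - ws.p, 2))
    for j in range(ws.p):
        denom = grads[j] @ A @ grads[j]
        if denom <= 0 or not np.isfinite(denom):
            ddfs[j] = fallback
        else:
            ddfs[j] = min(2.0 * base[j] ** 2 / denom, fallback)
        ddfs[j] = max(ddfs[j], 1.0)
    return ddfs
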