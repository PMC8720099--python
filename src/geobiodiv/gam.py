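"""Gaussian additive models with penalized cubic regression splines.

Each predictor enters through a natural cubic regression spline with four
knots placed at quantiles of the observed values.  The smoothness penalty is
the integrated squared second derivative (Green-Silverman construction on
the knot values), whose null space is exactly the linear functions: as the
smoothing parameter grows a term collapses to a straight line (edf -> 1),
and at most edf 3 of flexibility is available after the identifiability
(sum-to-zero) constraint.  Smoothing parameters are chosen by generalized
cross validation,

    GCV = n * RSS / (n - gamma * edf_total)^2 ,

with ``gamma = 1`` by default.  The family is Gaussian with identity link, so
explained deviance is 1 - RSS/RSS_null with RSS_null the total sum of
squares about the mean.

AIC uses the Gaussian log-likelihood at the profiled error variance with the
total effective degrees of freedom plus one (the variance) as the parameter
count.  Adjusted R^2 uses residual degrees of freedom n - edf_total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize, minimize_scalar

__all__ = ["SmoothTerm", "GamFit", "fit_gam", "explained_deviance"]

_N_KNOTS = 4  # basis dimension per smooth; max edf 3 after centering


# ---------------------------------------------------------------------------
# basis and penalty
# ---------------------------------------------------------------------------

def _choose_knots(x: np.ndarray, n_knots: int = _N_KNOTS) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_knots)
    knots = np.unique(np.quantile(x, qs))
    if knots.size < 2:
        raise ValueError("predictor is (numerically) constant; cannot build a smooth")
    if knots.size < n_knots:
        # few distinct values: spread knots over the observed range instead
        knots = np.unique(np.linspace(x.min(), x.max(), knots.size))
    return knots


def _cardinal_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline cardinal basis evaluated at x (linear
    extrapolation beyond the end knots, as natural splines demand)."""
    m = knots.size
    B = np.empty((x.size, m))
    lo, hi = knots[0], knots[-1]
    inside = np.clip(x, lo, hi)
    for j in range(m):
        e = np.zeros(m)
        e[j] = 1.0
        cs = CubicSpline(knots, e, bc_type="natural")
        col = cs(inside)
        left = x < lo
        right = x > hi
        if np.any(left):
            col[left] = cs(lo) + cs(lo, 1) * (x[left] - lo)
        if np.any(right):
            col[right] = cs(hi) + cs(hi, 1) * (x[right] - hi)
        B[:, j] = col
    return B


def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative of the natural interpolating
    spline, as a quadratic form in the knot values: K = D' W^{-1} D with the
    classic tridiagonal W and second-difference D."""
    h = np.diff(knots)
    m = knots.size
    if m < 3:
        return np.zeros((m, m))
    D = np.zeros((m - 2, m))
    W = np.zeros((m - 2, m - 2))
    for i in range(m - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < m - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


@dataclass
class SmoothTerm:
    """One fitted smooth: its knots, constraint transform and summary."""

    name: str
    knots: np.ndarray
    Z: np.ndarray                # (m, m-1) sum-to-zero constraint transform
    penalty: np.ndarray          # constrained penalty, (m-1, m-1)
    lam: float = np.nan          # smoothing parameter
    edf: float = np.nan          # effective degrees of freedom

    def design(self, x: np.ndarray) -> np.ndarray:
        return _cardinal_basis(np.asarray(x, dtype=float), self.knots) @ self.Z


def _build_term(name: str, x: np.ndarray) -> tuple[SmoothTerm, np.ndarray]:
    knots = _choose_knots(x)
    B = _cardinal_basis(x, knots)
    C = B.sum(axis=0, keepdims=True)          # sum-to-zero constraint
    Z = sla.null_space(C)
    K = Z.T @ _penalty_matrix(knots) @ Z
    # make the penalty's null space (the linear functions) exact, so the
    # unpenalized linear part survives arbitrarily strong smoothing
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    w[w < 1e-10 * max(w.max(), 0.0)] = 0.0
    K = (V * w) @ V.T
    term = SmoothTerm(name=name, knots=knots, Z=Z, penalty=K)
    return term, B @ Z


@dataclass
class GamFit:
    """Summary of a fitted Gaussian additive model."""

    terms: dict[str, SmoothTerm]
    intercept: float
    coef: np.ndarray
    n: int
    rss: float
    rss_null: float
    edf_total: float
    gcv: float
    aic: float
    lambdas: dict[str, float]
    fitted: np.ndarray
    _slices: dict[str, slice] = field(default_factory=dict, repr=False)

    @property
    def explained_deviance(self) -> float:
        if self.rss_null <= 0:
            return 1.0
        return 1.0 - self.rss / self.rss_null

    @property
    def adj_r2(self) -> float:
        denom = self.n - self.edf_total
        if denom <= 0 or self.rss_null <= 0:
            return np.nan
        return 1.0 - (self.rss / denom) / (self.rss_null / (self.n - 1))

    def predict(self, predictors: Mapping[str, np.ndarray]) -> np.ndarray:
        cols = [np.ones(len(next(iter(predictors.values()))))]
        for name, term in self.terms.items():
            cols.append(term.design(np.asarray(predictors[name], dtype=float)))
        return np.column_stack(cols) @ np.concatenate([[self.intercept], self.coef])


def explained_deviance(fit: GamFit) -> float:
    """Explained deviance of a Gaussian fit, 1 - RSS/RSS_null."""
    return fit.explained_deviance


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_columns(predictors) -> dict[str, np.ndarray]:
    if isinstance(predictors, pd.DataFrame):
        return {str(c): predictors[c].to_numpy(dtype=float) for c in predictors.columns}
    return {str(k): np.asarray(v, dtype=float) for k, v in predictors.items()}


class _PLSProblem:
    """Penalized least squares with per-term penalty blocks, precomputed
    cross-products so a (lambda) evaluation costs O(p^3) on a tiny p."""

    def __init__(self, y: np.ndarray, cols: dict[str, np.ndarray]):
        self.n = y.size
        self.term_objs: dict[str, SmoothTerm] = {}
        blocks = [np.ones((self.n, 1))]
        self.slices: dict[str, slice] = {}
        start = 1
        for name, x in cols.items():
            term, Bt = _build_term(name, x)
            self.term_objs[name] = term
            self.slices[name] = slice(start, start + Bt.shape[1])
            blocks.append(Bt)
            start += Bt.shape[1]
        self.X = np.column_stack(blocks)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise ValueError(
                f"n = {self.n} is too small for {len(cols)} smooth term(s) "
                f"({self.p} coefficients); need n > {self.p}")
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)
        self.y = y
        # scale-invariant reference for each penalty block
        self.pen_scale = {
            name: np.trace(self.XtX[self.slices[name], self.slices[name]])
            / max(np.trace(self.term_objs[name].penalty), 1e-300)
            for name in cols
        }

    def _S(self, lams: Mapping[str, float]) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for name, sl in self.slices.items():
            S[sl, sl] = lams[name] * self.term_objs[name].penalty
        return S

    def solve(self, lams: Mapping[str, float]):
        A = self.XtX + self._S(lams)
        try:
            cf = sla.cho_factor(A)
            beta = sla.cho_solve(cf, self.Xty)
            F = sla.cho_solve(cf, self.XtX)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
            beta = Ainv @ self.Xty
            F = Ainv @ self.XtX
        rss = self.yty - 2 * beta @ self.Xty + beta @ self.XtX @ beta
        rss = max(float(rss), 0.0)
        edf = {name: float(np.trace(F[sl, sl])) for name, sl in self.slices.items()}
        edf_total = 1.0 + sum(edf.values())
        return beta, rss, edf, edf_total

    def gcv(self, lams: Mapping[str, float], gamma: float) -> float:
        _, rss, _, edf_total = self.solve(lams)
        denom = self.n - gamma * edf_total
        if denom <= 0:
            return np.inf
        return self.n * rss / denom ** 2


def _optimize_lambdas(prob: _PLSProblem, gamma: float) -> dict[str, float]:
    names = list(prob.slices.keys())
    # search in units of the scale-invariant reference penalty
    grid = np.logspace(-5, 7, 13)
    rho_max = np.log(1e9)

    def lam_of(rho: np.ndarray) -> dict[str, float]:
        return {nm: float(np.exp(min(r, rho_max))) * prob.pen_scale[nm]
                for nm, r in zip(names, rho)}

    if len(names) == 1:
        nm = names[0]
        vals = [prob.gcv({nm: g * prob.pen_scale[nm]}, gamma) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            lambda r: prob.gcv({nm: np.exp(r) * prob.pen_scale[nm]}, gamma),
            bracket=None, bounds=(np.log(g0) - 3, np.log(g0) + 3), method="bounded")
        return _parsimony_pass(
            prob, {nm: float(np.exp(res.x)) * prob.pen_scale[nm]}, gamma)

    # coordinate-wise grid sweeps, then a joint Nelder-Mead polish
    rho = np.zeros(len(names))
    for _ in range(2):
        for i in range(len(names)):
            best_r, best_v = rho[i], np.inf
            for g in grid:
                trial = rho.copy()
                trial[i] = np.log(g)
                v = prob.gcv(lam_of(trial), gamma)
                if v < best_v:
                    best_v, best_r = v, np.log(g)
            rho[i] = best_r
    res = minimize(lambda r: prob.gcv(lam_of(r), gamma), rho,
                   method="Nelder-Mead",
                   options={"maxiter": 200 * len(names), "xatol": 1e-3,
                            "fatol": 1e-10})
    if np.isfinite(res.fun):
        rho = res.x
    return _parsimony_pass(prob, lam_of(rho), gamma)


def _parsimony_pass(prob: _PLSProblem, lams: dict[str, float],
                    gamma: float, rtol: float = 1e-6) -> dict[str, float]:
    """Push each smoothing parameter upward while GCV does not measurably
    worsen.  Resolves the GCV tie along flat regions (e.g. exactly linear
    data, where every lambda gives the same residuals) in favour of the
    smoother, lower-edf fit; genuinely nonlinear signal stops the walk."""
    lams = dict(lams)
    cur = prob.gcv(lams, gamma)
    for name in lams:
        cap = 1e9 * prob.pen_scale[name]
        while lams[name] < cap:
            trial = dict(lams)
            trial[name] = min(lams[name] * 10.0, cap)
            v = prob.gcv(trial, gamma)
            if v <= cur * (1.0 + rtol) + 1e-300:
                lams = trial
                cur = min(cur, v)
            else:
                break
    return lams


def fit_gam(response, predictors, lambdas: Mapping[str, float] | None = None,
            gamma: float = 1.0) -> GamFit:
    """Fit a Gaussian additive model with one penalized cubic regression
    spline per predictor (1 to 3 predictors).

    Parameters
    ----------
    response
        Per-plot response values.
    predictors
        Mapping name -> vector, or a DataFrame; one smooth per column.
    lambdas
        Optional frozen smoothing parameters per term.  When given, no GCV
        search is run -- used by the variance partitioning to hold model
        parameters fixed across subset models.
    gamma
        GCV degrees-of-freedom inflation (1 = plain GCV).
    """
    y = np.asarray(response, dtype=float)
    cols = _as_columns(predictors)
    if not 1 <= len(cols) <= 3:
        raise ValueError("fit_gam supports 1 to 3 predictors")
    if y.ndim != 1:
        raise ValueError("response must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    for name, x in cols.items():
        if x.shape != y.shape:
            raise ValueError(f"predictor {name!r} length mismatch")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in predictor {name!r}")

    prob = _PLSProblem(y, cols)
    if lambdas is None:
        lams = _optimize_lambdas(prob, gamma)
    else:
        missing = set(cols) - set(lambdas)
        if missing:
            raise ValueError(f"frozen lambdas missing for terms: {sorted(missing)}")
        lams = {name: float(lambdas[name]) for name in cols}

    beta, rss, edf, edf_total = prob.solve(lams)
    for name, term in prob.term_objs.items():
        term.lam = lams[name]
        term.edf = edf[name]
    rss_null = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    denom = n - gamma * edf_total
    gcv = np.inf if denom <= 0 else n * rss / denom ** 2
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)
    return GamFit(
        terms=prob.term_objs,
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        n=n,
        rss=rss,
        rss_null=rss_null,
        edf_total=edf_total,
        gcv=float(gcv),
        aic=float(aic),
        lambdas=lams,
        fitted=prob.X @ beta,
        _slices=prob.slices,
    )
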