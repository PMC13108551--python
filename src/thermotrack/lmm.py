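"""Linear mixed models with one or two crossed random-intercept factors.

The trend analyses need ``response ~ year + (1 | year_factor) + (1 | female)``
fitted by REML on cohorts of 10^4 attempts.  For random *intercepts* the
cross-product blocks Z_k' W Z_k are diagonal, so the mixed-model equations
collapse, via a Schur complement on the larger factor, to a dense system the
size of the smaller factor (the number of years).  Each REML evaluation is
therefore O(n) and full fits take milliseconds, which the simulation batteries
and cluster bootstraps rely on.

The variance ratios lambda_k = sigma_k^2 / sigma_e^2 are profiled out and the
REML criterion is minimised over log(lambda) by Nelder-Mead.  Denominator
degrees of freedom for fixed effects use the Satterthwaite approximation
(numeric gradient/Hessian on the variance scale), matching the fractional df
convention of lmerTest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

__all__ = ["LMMResult", "fit_lmm", "fit_attempt_level_trend", "MixedTrendFit"]

_SINGULAR_TOL = 1e-6  # lambda below this is reported as a zero variance component
_LOG_LAMBDA_BOUNDS = (-30.0, 15.0)


def _factorize(codes) -> tuple[np.ndarray, int]:
    arr, uniq = pd.factorize(np.asarray(codes), sort=True)
    return arr.astype(np.int64), len(uniq)


def _chol_safe(A: np.ndarray):
    """Cholesky with a tiny diagonal jitter retry for borderline matrices."""
    try:
        return sla.cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(float(np.trace(A)) / len(A), 1.0)
        return sla.cho_factor(A + jitter * np.eye(len(A)), lower=True)


class CrossedRandomIntercepts:
    """Workhorse: profiled REML pieces for fixed variance ratios.

    Parameters
    ----------
    y, X : response and fixed-effect design (column of ones included by caller).
    groups : mapping name -> length-n label array; one or two factors.
    weights : optional positive prior weights (Var e_i = sigma_e^2 / w_i),
        used by the PQL working model.
    """

    def __init__(self, y, X, groups: dict, weights=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n, self.p = self.X.shape
        if self.y.shape != (self.n,):
            raise ValueError("y/X shape mismatch")
        if not 1 <= len(groups) <= 2:
            raise ValueError("supports one or two random-intercept factors")
        self.w = np.ones(self.n) if weights is None else np.asarray(weights, dtype=float)
        if (self.w <= 0).any():
            raise ValueError("weights must be positive")

        self.group_names: list[str] = []
        codes_list: list[np.ndarray] = []
        sizes: list[int] = []
        for name, labels in groups.items():
            c, q = _factorize(labels)
            if len(c) != self.n:
                raise ValueError(f"group {name!r} length mismatch")
            if q < 2:
                raise ValueError(f"group {name!r} needs >= 2 levels")
            self.group_names.append(name)
            codes_list.append(c)
            sizes.append(q)

        # order so that factor 0 (the dense Schur block) is the smaller one
        order = np.argsort(sizes)
        self.group_names = [self.group_names[i] for i in order]
        self.codes = [codes_list[i] for i in order]
        self.q = [sizes[i] for i in order]
        self._precompute()

    def _precompute(self) -> None:
        w, X, y = self.w, self.X, self.y
        self.XtWX = X.T @ (w[:, None] * X)
        self.XtWy = X.T @ (w * y)
        self.yWy = float(np.dot(w * y, y))
        self.A = []      # per factor: diag of Z_k' W Z_k
        self.ZtWX = []   # per factor: q_k x p
        self.ZtWy = []   # per factor: q_k
        for c, q in zip(self.codes, self.q):
            self.A.append(np.bincount(c, weights=w, minlength=q))
            self.ZtWX.append(np.stack(
                [np.bincount(c, weights=w * X[:, j], minlength=q)
                 for j in range(self.p)], axis=1))
            self.ZtWy.append(np.bincount(c, weights=w * y, minlength=q))
        if len(self.codes) == 2:
            c0, c1 = self.codes
            self.B = sp.coo_matrix(
                (w, (c0, c1)), shape=(self.q[0], self.q[1])).tocsr()
        else:
            self.B = None

    # -- linear algebra for fixed lambda -----------------------------------

    def _system(self, lambdas: np.ndarray):
        """Return (solveM(b0, b1), logdet M) for M = D^-1 + Z'WZ."""
        if len(self.q) == 1:
            d = 1.0 / lambdas[0] + self.A[0]

            def solve(b0, b1=None):
                return b0 / (d if b0.ndim == 1 else d[:, None]), None

            return solve, float(np.log(d).sum())

        d1 = 1.0 / lambdas[1] + self.A[1]
        inv_d1 = 1.0 / d1
        Bw = self.B.multiply(inv_d1[None, :])  # q0 x q1
        S = np.diag(1.0 / lambdas[0] + self.A[0]) - (Bw @ self.B.T).toarray()
        cho = _chol_safe(S)
        logdet = float(np.log(d1).sum()) + 2.0 * float(
            np.log(np.diag(cho[0])).sum())
        B, BT = self.B, self.B.T.tocsr()

        def solve(b0, b1):
            rhs = b0 - Bw @ b1
            x0 = sla.cho_solve(cho, rhs)
            x1 = (b1 - BT @ x0) * (inv_d1 if b1.ndim == 1 else inv_d1[:, None])
            return x0, x1

        return solve, logdet

    def solve(self, lambdas) -> dict:
        """GLS quantities at fixed variance ratios lambda_k = sigma_k^2/sigma_e^2."""
        lambdas = np.asarray(lambdas, dtype=float)
        solveM, logdetM = self._system(lambdas)
        K = len(self.q)
        ZtWX0, ZtWy0 = self.ZtWX[0], self.ZtWy[0]
        if K == 2:
            mx = solveM(ZtWX0, self.ZtWX[1])
            my = solveM(ZtWy0, self.ZtWy[1])
            corrX = ZtWX0.T @ mx[0] + self.ZtWX[1].T @ mx[1]
            corry = ZtWX0.T @ my[0] + self.ZtWX[1].T @ my[1]
        else:
            mx = solveM(ZtWX0)
            my = solveM(ZtWy0)
            corrX = ZtWX0.T @ mx[0]
            corry = ZtWX0.T @ my[0]
        Phi = self.XtWX - corrX          # = X' V0^-1 X
        rhs = self.XtWy - corry          # = X' V0^-1 y
        cho_phi = _chol_safe(Phi)
        beta = sla.cho_solve(cho_phi, rhs)
        logdet_phi = 2.0 * float(np.log(np.diag(cho_phi[0])).sum())

        # residual quadratic form r' V0^-1 r with r = y - X beta
        ZtWr = [zy - zx @ beta for zy, zx in zip(self.ZtWy, self.ZtWX)]
        if K == 2:
            mr = solveM(ZtWr[0], ZtWr[1])
            corr_r = ZtWr[0] @ mr[0] + ZtWr[1] @ mr[1]
            u = list(mr)
        else:
            mr = solveM(ZtWr[0])
            corr_r = ZtWr[0] @ mr[0]
            u = [mr[0]]
        rWr = self.yWy - 2.0 * beta @ self.XtWy + beta @ (self.XtWX @ beta)
        qform = float(rWr - corr_r)
        logdetV0 = logdetM + float(np.dot(self.q, np.log(lambdas))) - float(
            np.log(self.w).sum())
        return {
            "beta": beta,
            "cov_unit": sla.cho_solve(cho_phi, np.eye(self.p)),  # (X'V0^-1 X)^-1
            "qform": qform,
            "logdetV0": logdetV0,
            "logdet_phi": logdet_phi,
            # BLUPs: u_k = lambda_k * (M^-1 Z'W r)_k  [M parametrised by D^-1]
            "u": [lambdas[k] * u[k] for k in range(K)],
        }

    # -- REML criteria -------------------------------------------------------

    def profiled_reml(self, log_lambdas) -> float:
        """-2 REML log-likelihood with sigma_e^2 profiled out (constants kept)."""
        lambdas = np.exp(np.clip(log_lambdas, *_LOG_LAMBDA_BOUNDS))
        s = self.solve(lambdas)
        npp = self.n - self.p
        sigma2 = max(s["qform"] / npp, 1e-300)
        return (npp * (1.0 + np.log(2.0 * np.pi * sigma2))
                + s["logdetV0"] + s["logdet_phi"])

    def reml_full(self, variances: np.ndarray) -> float:
        """-2 REML at explicit (sigma_1^2, [sigma_2^2,] sigma_e^2)."""
        *vk, ve = variances
        lambdas = np.asarray(vk) / ve
        s = self.solve(lambdas)
        return ((self.n - self.p) * np.log(ve) + s["logdetV0"] + s["logdet_phi"]
                + s["qform"] / ve + (self.n - self.p) * np.log(2.0 * np.pi))

    def fit_lambdas(self) -> tuple[np.ndarray, bool]:
        K = len(self.q)
        best = None
        for start in ([np.log(0.5)] * K, [np.log(1e-3)] * K):
            res = optimize.minimize(
                self.profiled_reml, x0=np.asarray(start), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400 * K})
            if best is None or res.fun < best.fun:
                best = res
        lam = np.exp(np.clip(best.x, *_LOG_LAMBDA_BOUNDS))
        return lam, bool(best.success or best.fun < np.inf)


@dataclass
class LMMResult:
    """REML fit of a random-intercepts linear mixed model."""

    fe_params: np.ndarray
    fe_se: np.ndarray
    cov_fe: np.ndarray
    fe_names: list[str]
    varcomps: dict[str, float]
    sigma2: float
    reml_criterion: float
    n_obs: int
    n_groups: dict[str, int]
    singular: dict[str, bool]
    converged: bool
    satterthwaite: dict[int, float] = field(default_factory=dict)
    _work: CrossedRandomIntercepts | None = field(default=None, repr=False)
    blups: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def satterthwaite_df(self, j: int = 1) -> float:
        """Approximate denominator df for fixed effect j (lmerTest convention)."""
        if j in self.satterthwaite:
            return self.satterthwaite[j]
        df = _satterthwaite_df(self, j)
        self.satterthwaite[j] = df
        return df

    def ci(self, j: int = 1, level: float = 0.95, use_t: bool = True) -> tuple[float, float]:
        """Wald interval for fixed effect j, with t quantiles on Satterthwaite df."""
        if use_t:
            crit = stats.t.ppf(0.5 + level / 2.0, self.satterthwaite_df(j))
        else:
            crit = stats.norm.ppf(0.5 + level / 2.0)
        b, se = self.fe_params[j], self.fe_se[j]
        return float(b - crit * se), float(b + crit * se)

    def p_value(self, j: int = 1) -> float:
        t = self.fe_params[j] / self.fe_se[j]
        return float(2.0 * stats.t.sf(abs(t), self.satterthwaite_df(j)))


def _satterthwaite_df(result: LMMResult, j: int) -> float:
    work = result._work
    n, p = work.n, work.p
    names = work.group_names
    theta_full = np.array([result.varcomps[nm] for nm in names] + [result.sigma2])
    active = [k for k in range(len(names)) if not result.singular[names[k]]]
    idx = active + [len(names)]  # active variance components + residual
    theta = theta_full[idx]

    def var_beta(th):
        full = theta_full.copy()
        full[idx] = th
        full = np.maximum(full, 1e-12)  # inactive (singular) components pinned near 0
        *vk, ve = full
        s = work.solve(np.asarray(vk) / ve)
        return ve * s["cov_unit"][j, j]

    def crit(th):
        full = theta_full.copy()
        full[idx] = th
        return work.reml_full(np.maximum(full, 1e-12))

    # central differences with steps small enough to stay interior
    h = np.maximum(1e-3 * np.abs(theta), 1e-10)
    h = np.minimum(h, theta / 4.0)
    m = len(theta)
    grad = np.zeros(m)
    for k in range(m):
        e = np.zeros(m)
        e[k] = h[k]
        grad[k] = (var_beta(theta + e) - var_beta(theta - e)) / (2 * h[k])
    H = np.zeros((m, m))
    f0 = crit(theta)
    for a in range(m):
        for b in range(a, m):
            ea = np.zeros(m); ea[a] = h[a]
            eb = np.zeros(m); eb[b] = h[b]
            if a == b:
                H[a, a] = (crit(theta + ea) - 2 * f0 + crit(theta - ea)) / h[a] ** 2
            else:
                fpp = crit(theta + ea + eb)
                fpm = crit(theta + ea - eb)
                fmp = crit(theta - ea + eb)
                fmm = crit(theta - ea - eb)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        cov_theta = 2.0 * np.linalg.inv(H)
        denom = float(grad @ cov_theta @ grad)
    except np.linalg.LinAlgError:
        denom = np.inf
    f = var_beta(theta)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    return float(np.clip(2.0 * f * f / denom, 1.0, n - p))


def fit_lmm(y, X, groups: dict, weights=None, fe_names: list[str] | None = None) -> LMMResult:
    """Fit a linear mixed model with one or two random-intercept factors by REML.

    Singular fits (a variance ratio driven to the boundary) are reported with a
    zero variance component and a flag, never as a failure.
    """
    work = CrossedRandomIntercepts(y, X, groups, weights=weights)
    lambdas, converged = work.fit_lambdas()
    s = work.solve(lambdas)
    sigma2 = s["qform"] / (work.n - work.p)
    cov_fe = sigma2 * s["cov_unit"]
    varcomps, singular, blups = {}, {}, {}
    for k, name in enumerate(work.group_names):
        is_singular = lambdas[k] < _SINGULAR_TOL
        varcomps[name] = 0.0 if is_singular else float(lambdas[k] * sigma2)
        singular[name] = bool(is_singular)
        blups[name] = s["u"][k]
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(work.p)]
    return LMMResult(
        fe_params=s["beta"],
        fe_se=np.sqrt(np.diag(cov_fe)),
        cov_fe=cov_fe,
        fe_names=list(fe_names),
        varcomps=varcomps,
        sigma2=float(sigma2),
        reml_criterion=float(work.profiled_reml(np.log(np.maximum(lambdas, 1e-300)))),
        n_obs=work.n,
        n_groups=dict(zip(work.group_names, work.q)),
        singular=singular,
        converged=converged,
        _work=work,
        blups=blups,
    )


@dataclass
class MixedTrendFit:
    """Attempt-level temporal trend: response ~ year + (1|year) + (1|female)."""

    fixed_slope: float
    fixed_slope_se: float
    satterthwaite_df: float
    p_value: float
    ci95: tuple[float, float]
    variance_components: dict[str, float]
    sigma2_residual: float
    n_obs: int
    n_groups: dict[str, int]
    singular: dict[str, bool]
    intercept: float


def fit_attempt_level_trend(values, years, females, center_year: float | None = None) -> MixedTrendFit:
    """Per-attempt trend LMM with year (categorical) and female random intercepts.

    ``values`` is the attempt-level response (e.g. laying April-day or a
    relative-interval temperature); the fixed effect is continuous year.
    The fixed-effect slope is invariant to ``center_year``.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    if center_year is None:
        center_year = float(np.mean(years.astype(float)))
    X = np.column_stack([np.ones(len(values)), years.astype(float) - center_year])
    res = fit_lmm(values, X, groups={"year": years, "female": np.asarray(females)},
                  fe_names=["intercept", "year"])
    return MixedTrendFit(
        fixed_slope=float(res.fe_params[1]),
        fixed_slope_se=float(res.fe_se[1]),
        satterthwaite_df=res.satterthwaite_df(1),
        p_value=res.p_value(1),
        ci95=res.ci(1),
        variance_components=res.varcomps,
        sigma2_residual=res.sigma2,
        n_obs=res.n_obs,
        n_groups=res.n_groups,
        singular=res.singular,
        intercept=float(res.fe_params[0]),
    )
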