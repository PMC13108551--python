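"""Generalized linear mixed models by penalized quasi-likelihood (PQL).

Families: Poisson (counts), binomial successes-out-of-trials, zero-inflated
Poisson (ZIP; intercept-only inflation, via EM around the Poisson fit) and
Gaussian.  Random structure: one or two crossed random-intercept factors,
delegated to :mod:`thermotrack.lmm`, so each working-model solve is O(n).

PQL iterates a weighted linear mixed model on the working response.  For
cluster bootstraps the variance ratios can be frozen at the full-fit
estimates (``fixed_lambdas``), reducing a refit to a handful of IRLS steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln

from .lmm import CrossedRandomIntercepts, fit_lmm

__all__ = ["GLMMResult", "fit_glmm"]

_ETA_CLIP = 30.0
_FAMILIES = ("poisson", "binomial", "zip", "gaussian")


@dataclass
class GLMMResult:
    """PQL fit of a GLMM with random intercepts."""

    family: str
    fe_params: np.ndarray
    fe_se: np.ndarray
    cov_fe: np.ndarray
    fe_names: list[str]
    varcomps: dict[str, float]
    lambdas: np.ndarray          # variance ratios of the final working model
    sigma2_working: float
    zip_pi: float                # 0.0 unless family == "zip"
    n_obs: int
    n_groups: dict[str, int]
    singular: dict[str, bool]
    converged: bool
    n_iter: int
    blups: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, Xnew) -> np.ndarray:
        return np.asarray(Xnew, float) @ self.fe_params

    def predict(self, Xnew) -> np.ndarray:
        """Population-level (random effects at zero) response-scale prediction."""
        eta = np.clip(self.linear_predictor(Xnew), -_ETA_CLIP, _ETA_CLIP)
        if self.family == "poisson":
            return np.exp(eta)
        if self.family == "zip":
            return (1.0 - self.zip_pi) * np.exp(eta)
        if self.family == "binomial":
            return expit(eta)
        return eta

    def wald_ci(self, j: int, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (float(self.fe_params[j] - z * self.fe_se[j]),
                float(self.fe_params[j] + z * self.fe_se[j]))


def _conditional_eta(X, beta, blups, codes):
    eta = X @ beta
    for u, c in zip(blups, codes):
        eta = eta + u[c]
    return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)


def conditional_log_likelihood(y, mu, family: str, pi: float = 0.0, trials=None) -> float:
    """Log-likelihood given the fitted conditional means (BLUPs plugged in).

    At pi = 0 the ZIP likelihood coincides with the Poisson likelihood at the
    same rates, which is the nested-family identity tests rely on.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if family == "poisson" or (family == "zip" and pi == 0.0):
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    if family == "zip":
        ll_pois = y * np.log(mu) - mu - gammaln(y + 1)
        out = np.where(
            y == 0,
            np.log(pi + (1.0 - pi) * np.exp(-mu)),
            np.log1p(-pi) + ll_pois)
        return float(np.sum(out))
    if family == "binomial":
        n = np.asarray(trials, float)
        p = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * np.log(p) + (n - y) * np.log1p(-p)))
    raise ValueError(f"no likelihood for family {family!r}")


def fit_glmm(
    y,
    X,
    groups: dict,
    family: str = "poisson",
    trials=None,
    fe_names: list[str] | None = None,
    fixed_lambdas=None,
    case_weights=None,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> GLMMResult:
    """Fit a GLMM with random intercepts by PQL (EM-wrapped for ZIP).

    Parameters
    ----------
    y : response; counts (poisson/zip) or successes (binomial).
    trials : binomial trial counts, required for that family.
    fixed_lambdas : freeze the variance ratios (bootstrap refits).
    case_weights : optional per-row frequency weights.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    cw = np.ones(n) if case_weights is None else np.asarray(case_weights, float)

    if family == "gaussian":
        if fixed_lambdas is not None:
            work = CrossedRandomIntercepts(
                y, X, groups, weights=cw if case_weights is not None else None)
            lam = np.asarray(fixed_lambdas, float)
            s = work.solve(lam)
            sigma2 = s["qform"] / (work.n - work.p)
            cov_fe = sigma2 * s["cov_unit"]
            names = fe_names or [f"x{j}" for j in range(p)]
            return GLMMResult(
                family="gaussian", fe_params=s["beta"], fe_se=np.sqrt(np.diag(cov_fe)),
                cov_fe=cov_fe, fe_names=list(names),
                varcomps={g: float(l * sigma2) for g, l in zip(work.group_names, lam)},
                lambdas=lam, sigma2_working=float(sigma2), zip_pi=0.0, n_obs=n,
                n_groups=dict(zip(work.group_names, work.q)),
                singular={g: bool(l < 1e-6) for g, l in zip(work.group_names, lam)},
                converged=True, n_iter=1,
                blups=dict(zip(work.group_names, s["u"])))
        res = fit_lmm(y, X, groups, weights=cw if case_weights is not None else None,
                      fe_names=fe_names)
        return GLMMResult(
            family="gaussian", fe_params=res.fe_params, fe_se=res.fe_se,
            cov_fe=res.cov_fe, fe_names=res.fe_names, varcomps=res.varcomps,
            lambdas=np.array([res.varcomps[g] / res.sigma2 if res.sigma2 > 0 else 0.0
                              for g in res.n_groups]),
            sigma2_working=res.sigma2, zip_pi=0.0, n_obs=res.n_obs,
            n_groups=res.n_groups, singular=res.singular, converged=res.converged,
            n_iter=1, blups=res.blups)

    if family == "binomial":
        if trials is None:
            raise ValueError("binomial family requires trials")
        trials = np.asarray(trials, dtype=float)
        if (y > trials).any():
            raise ValueError("successes exceed trials")

    # initial linear predictor
    if family == "binomial":
        eta = np.log((y + 0.5) / (trials - y + 0.5))
    else:
        eta = np.log(y + 0.5)
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)

    pi = 0.0
    if family == "zip":
        frac0 = float(np.mean(y == 0))
        pi = min(0.5, max(1e-4, 0.5 * frac0))

    beta = np.zeros(p)
    lambdas = None if fixed_lambdas is None else np.asarray(fixed_lambdas, float)
    work = None
    zeta = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # linearize at a clipped eta: keeps working weights bounded away from
        # zero so quasi-separated fits stay finite instead of diverging
        if family == "binomial":
            eta_w = np.clip(eta, -8.0, 8.0)
            mu_p = expit(eta_w)                     # probability scale
            wld = trials * mu_p * (1 - mu_p)
            z = eta_w + (y / trials - mu_p) / (mu_p * (1 - mu_p))
        else:
            eta_w = np.clip(eta, -15.0, 15.0)
            mu = np.exp(eta_w)
            if family == "zip":
                # E-step: posterior probability that a zero is structural
                zeta = np.where(y == 0, pi / np.clip(pi + (1 - pi) * np.exp(-mu), 1e-300, None), 0.0)
                pi = float(np.sum(cw * zeta) / np.sum(cw))
            wld = np.clip(mu, 1e-10, None)
            z = eta_w + (y - mu) / mu
        w = wld * cw
        if family == "zip":
            w = w * (1.0 - zeta)
        w = np.clip(w, 1e-10, None)

        work = CrossedRandomIntercepts(z, X, groups, weights=w)
        if fixed_lambdas is None:
            lam_start = lambdas
            if lam_start is None:
                lambdas, _ = work.fit_lambdas()
            else:
                from scipy import optimize
                res_opt = optimize.minimize(
                    work.profiled_reml, x0=np.log(np.maximum(lam_start, 1e-12)),
                    method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 250})
                lambdas = np.exp(np.clip(res_opt.x, -30, 15))
        s = work.solve(lambdas)
        beta_new = s["beta"]
        blup_list = s["u"]
        eta_new = _conditional_eta(X, beta_new, blup_list, work.codes)
        step = float(np.max(np.abs(beta_new - beta))) if it > 1 else np.inf
        beta, eta = beta_new, eta_new
        if step < tol:
            converged = True
            break

    sigma2 = s["qform"] / (work.n - work.p)
    cov_fe = sigma2 * s["cov_unit"]
    varcomps, singular, blups = {}, {}, {}
    for k, name in enumerate(work.group_names):
        bad = lambdas[k] < 1e-6
        varcomps[name] = 0.0 if bad else float(lambdas[k] * sigma2)
        singular[name] = bool(bad)
        blups[name] = blup_list[k]
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]
    return GLMMResult(
        family=family, fe_params=beta, fe_se=np.sqrt(np.diag(cov_fe)),
        cov_fe=cov_fe, fe_names=list(fe_names), varcomps=varcomps,
        lambdas=np.asarray(lambdas, float), sigma2_working=float(sigma2),
        zip_pi=float(pi), n_obs=n, n_groups=dict(zip(work.group_names, work.q)),
        singular=singular, converged=converged, n_iter=it, blups=blups)
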