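"""Temperature–fitness response surfaces and peak analysis.

For each reproductive-success measure the period temperature enters a GLMM
through a natural cubic spline (df = 7 by default) alongside standardized
laying date and neighbor count (plus clutch size for fledging success), with
year and female random intercepts.  Families: clutch size Poisson; fledgling
and recruit counts zero-inflated Poisson; fledging success binomial
(fledglings out of clutch size).

The thermal optimum is the argmax of the population-level predicted curve on
a 0.1 degC grid; its 95% interval comes from a cluster bootstrap over years
(variance ratios frozen at the full-fit estimates inside the bootstrap).
Pre- and post-peak linear trends are refitted on each side of the peak with
temperature standardized within subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import GLMMResult, fit_glmm
from .intervals import Period
from .io import BreedingAttempt
from .splines import NaturalCubicSpline, SplineSpec

__all__ = [
    "RESPONSE_FAMILIES", "FitnessModelResult", "PeakEstimate", "PiecewiseTrend",
    "MediationComparison", "assemble_model_frame", "fit_fitness_spline_model",
    "locate_peak_with_interval", "fit_prepost_peak_trends",
    "compare_with_mismatch_covariate",
]

RESPONSE_FAMILIES = {
    "clutch_size": "poisson",
    "n_fledged": "zip",
    "n_recruits": "zip",
    "fledging_success": "binomial",
}

#: responses analysed for every period; clutch size only at laying
#: (the other periods fall after clutch completion)
_LAYING_ONLY = ("clutch_size",)

PEAK_GRID_STEP = 0.1


class _Scaler:
    """Column standardizer (mean 0, SD 1) reusable on new data."""

    def __init__(self, x):
        x = np.asarray(x, dtype=float)
        self.mean = float(np.mean(x))
        sd = float(np.std(x, ddof=0))
        self.sd = sd if sd > 0 else 1.0

    def __call__(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


@dataclass
class FitnessModelResult:
    """Fitted spline response model for one (response, period) pair."""

    response: str
    family: str
    period: Period
    model: GLMMResult
    spline: NaturalCubicSpline
    grid: np.ndarray                 # temperature grid (0.1 degC)
    curve: np.ndarray                # population-level prediction on grid
    n_obs: int
    covariates: list[str]
    flags: list[str] = field(default_factory=list)
    data: pd.DataFrame = field(default=None, repr=False)
    _design: dict = field(default=None, repr=False)

    def predict_curve(self, params=None, zip_pi=None) -> np.ndarray:
        """Population-level response curve on the grid for given coefficients."""
        Xg = self._grid_design()
        model = self.model
        beta = model.fe_params if params is None else params
        eta = np.clip(Xg @ beta, -30, 30)
        if self.family in ("poisson", "zip"):
            scale = 1.0
            if self.family == "zip":
                scale = 1.0 - (model.zip_pi if zip_pi is None else zip_pi)
            return scale * np.exp(eta)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def _grid_design(self) -> np.ndarray:
        d = self._design
        basis = self.spline.design(self.grid)
        basis_z = (basis - d["basis_mean"]) / d["basis_sd"]
        basis_o = basis_z @ d["basis_transform"]
        n = len(self.grid)
        cols = [np.ones(n), *basis_o.T]
        cols += [np.zeros(n)] * (len(self.covariates))
        return np.column_stack(cols)


@dataclass(frozen=True)
class PeakEstimate:
    """Location of the response optimum with a bootstrap 95% interval."""

    peak_temp: float
    interval: tuple[float, float]
    at_boundary: bool
    identifiable: bool = True
    boot_peaks: np.ndarray | None = None
    kind: str = "max"


@dataclass(frozen=True)
class PiecewiseTrend:
    """Link-scale linear temperature slopes on each side of the peak."""

    prepeak_slope: float | None
    prepeak_ci: tuple[float, float] | None
    postpeak_slope: float | None
    postpeak_ci: tuple[float, float] | None
    n_pre: int
    n_post: int
    flags: list[str]


@dataclass(frozen=True)
class MediationComparison:
    """Paired fits with/without absolute mismatch as covariate."""

    response: str
    curve_without: np.ndarray
    curve_with: np.ndarray
    grid: np.ndarray
    postpeak_without: float
    postpeak_with: float
    attenuation: float        # |post-peak slope with| / |without|
    n_obs: int


def assemble_model_frame(
    attempts: list[BreedingAttempt],
    interval_temps: pd.DataFrame,
    period: Period,
    mismatch: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join attempts with their period temperature (and optionally mismatch)."""
    rows = {a.attempt_id: a for a in attempts}
    sub = interval_temps[interval_temps["period"] == period.value]
    df = pd.DataFrame({
        "attempt_id": sub["attempt_id"].to_numpy(),
        "temp": sub["mean_temp"].to_numpy(),
    })
    meta = pd.DataFrame([
        (a.attempt_id, a.year, a.female_id, a.laying_date, a.clutch_size,
         a.n_fledged, a.n_recruits, a.n_neighbors)
        for a in rows.values()], columns=[
        "attempt_id", "year", "female_id", "laying_date", "clutch_size",
        "n_fledged", "n_recruits", "n_neighbors"])
    df = df.merge(meta, on="attempt_id", how="inner")
    if mismatch is not None:
        df = df.merge(mismatch[["attempt_id", "abs_mismatch"]], on="attempt_id",
                      how="inner")
    return df.reset_index(drop=True)


def _build_design(df: pd.DataFrame, response: str, spline: NaturalCubicSpline,
                  extra: list[str]) -> tuple[np.ndarray, dict, list[str]]:
    basis = spline.design(df["temp"].to_numpy())
    basis_mean = basis.mean(axis=0)
    basis_sd = np.where(basis.std(axis=0) > 0, basis.std(axis=0), 1.0)
    basis_z = (basis - basis_mean) / basis_sd
    # the truncated-power natural basis is badly conditioned; re-express the
    # spline block in an orthonormal basis of the same span (scaled to SD 1)
    q, r = np.linalg.qr(basis_z)
    transform = np.linalg.solve(r, np.eye(r.shape[0])) * np.sqrt(len(df))
    basis_o = basis_z @ transform
    cols = [np.ones(len(df)), *basis_o.T]
    names = ["intercept"] + [f"ns{j + 1}" for j in range(basis.shape[1])]
    scalers = {}
    for cov in extra:
        sc = _Scaler(df[cov].to_numpy())
        scalers[cov] = sc
        cols.append(sc(df[cov].to_numpy()))
        names.append(cov)
    X = np.column_stack(cols)
    design = {"basis_mean": basis_mean, "basis_sd": basis_sd,
              "basis_transform": transform, "scalers": scalers}
    return X, design, names


def _response_arrays(df: pd.DataFrame, response: str):
    if response == "fledging_success":
        return df["n_fledged"].to_numpy(float), df["clutch_size"].to_numpy(float)
    return df[response].to_numpy(float), None


def _covariate_list(response: str) -> list[str]:
    if response == "abs_mismatch":
        return []  # mismatch models carry only the temperature spline
    extra = ["laying_date", "n_neighbors"]
    if response == "fledging_success":
        extra.append("clutch_size")
    return extra


def fit_fitness_spline_model(
    attempts: list[BreedingAttempt],
    interval_temps: pd.DataFrame,
    response: str,
    period: Period | str,
    df_spline: int = 7,
    mismatch: pd.DataFrame | None = None,
    include_mismatch: bool = False,
    family: str | None = None,
) -> FitnessModelResult:
    """Spline GLMM of one reproductive-success measure on period temperature."""
    period = Period(period)
    if response not in RESPONSE_FAMILIES and family is None:
        raise ValueError(f"unknown response {response!r}")
    if response in _LAYING_ONLY and period is not Period.LAYING:
        raise ValueError(f"{response} is analysed only for the laying period")
    family = family or RESPONSE_FAMILIES[response]
    needs_mismatch = include_mismatch or response == "abs_mismatch"
    if needs_mismatch and mismatch is None:
        raise ValueError("a mismatch table is required for this model")
    frame = assemble_model_frame(attempts, interval_temps, period,
                                 mismatch=mismatch if needs_mismatch else None)
    spline = NaturalCubicSpline.from_data(frame["temp"].to_numpy(), df=df_spline)
    extra = _covariate_list(response)
    if include_mismatch:
        extra = extra + ["abs_mismatch"]
    # constant covariates carry no information and would make the design singular
    extra = [cov for cov in extra if frame[cov].nunique() > 1]
    X, design, names = _build_design(frame, response, spline, extra)
    y, trials = _response_arrays(frame, response)
    model = fit_glmm(
        y, X, {"year": frame["year"].to_numpy(), "female": frame["female_id"].to_numpy()},
        family=family, trials=trials, fe_names=names)
    flags = []
    if not model.converged:
        flags.append("non-convergence")
    if family == "binomial":
        eta = X @ model.fe_params
        if np.max(np.abs(eta)) > 15:
            flags.append("possible separation")
    tmin, tmax = frame["temp"].min(), frame["temp"].max()
    grid = np.round(np.arange(np.floor(tmin * 10) / 10, tmax + PEAK_GRID_STEP / 2,
                              PEAK_GRID_STEP), 10)
    res = FitnessModelResult(
        response=response, family=family, period=period, model=model,
        spline=spline, grid=grid, curve=np.empty(0), n_obs=len(frame),
        covariates=extra, flags=flags, data=frame, _design=design)
    res.curve = res.predict_curve()
    return res


def _argopt(grid: np.ndarray, curve: np.ndarray, kind: str) -> float:
    """Grid arg-optimum with ties broken toward the lower temperature."""
    vals = curve if kind == "max" else -curve
    return float(grid[int(np.argmax(vals))])


def locate_peak_with_interval(
    fit: FitnessModelResult,
    n_boot: int = 500,
    seed: int = 0,
    kind: str = "max",
) -> PeakEstimate:
    """Grid arg-optimum of the fitted curve + cluster-bootstrap 95% interval.

    Years are resampled with replacement (each draw relabelled as its own
    cluster), the model is refitted with variance ratios frozen at the
    full-fit estimates, and the optimum re-located; the interval is the
    percentile interval of the bootstrap optima.
    """
    grid, curve = fit.grid, fit.curve
    peak = _argopt(grid, curve, kind)
    spread = float(np.ptp(curve))
    scale = max(abs(float(np.max(np.abs(curve)))), 1e-12)
    identifiable = spread > 1e-6 * scale
    at_boundary = peak <= grid[0] + 1e-9 or peak >= grid[-1] - 1e-9

    boot_peaks = None
    interval = (float("nan"), float("nan"))
    if n_boot > 0 and identifiable:
        rng = np.random.default_rng(seed)
        frame = fit.data
        years = frame["year"].to_numpy()
        uniq = np.unique(years)
        idx_by_year = {y: np.flatnonzero(years == y) for y in uniq}
        spline, design = fit.spline, fit._design
        peaks = np.empty(n_boot)
        y_all, trials_all = _response_arrays(frame, fit.response)
        basis = spline.design(frame["temp"].to_numpy())
        basis_z = (basis - design["basis_mean"]) / design["basis_sd"]
        basis_z = basis_z @ design["basis_transform"]
        cols = [np.ones(len(frame)), *basis_z.T]
        for cov in fit.covariates:
            cols.append(design["scalers"][cov](frame[cov].to_numpy()))
        X_all = np.column_stack(cols)
        fem_all = frame["female_id"].to_numpy()
        for b in range(n_boot):
            draw = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([idx_by_year[y] for y in draw])
            cluster = np.repeat(np.arange(len(draw)), [len(idx_by_year[y]) for y in draw])
            sub_model = fit_glmm(
                y_all[idx], X_all[idx],
                {"year": cluster, "female": fem_all[idx]},
                family=fit.family,
                trials=None if trials_all is None else trials_all[idx],
                fixed_lambdas=fit.model.lambdas)
            curve_b = fit.predict_curve(params=sub_model.fe_params,
                                        zip_pi=sub_model.zip_pi)
            peaks[b] = _argopt(grid, curve_b, kind)
        boot_peaks = peaks
        interval = (float(np.percentile(peaks, 2.5)), float(np.percentile(peaks, 97.5)))
    return PeakEstimate(peak_temp=peak, interval=interval, at_boundary=at_boundary,
                        identifiable=identifiable, boot_peaks=boot_peaks, kind=kind)


def fit_prepost_peak_trends(
    fit: FitnessModelResult,
    peak: PeakEstimate,
    min_side_n: int = 30,
) -> PiecewiseTrend:
    """Linear (link-scale) temperature slopes below and above the peak.

    Observations exactly at the peak join the pre side; temperature is
    standardized to mean 0, SD 1 within each subset.
    """
    frame = fit.data
    temps = frame["temp"].to_numpy()
    sides = {"pre": temps <= peak.peak_temp, "post": temps > peak.peak_temp}
    out = {}
    flags = []
    for name, mask in sides.items():
        n = int(mask.sum())
        if n == 0:
            out[name] = (None, None, 0)
            flags.append(f"empty {name}-peak side")
            continue
        if n < min_side_n:
            flags.append(f"{name}-peak side has n={n} < {min_side_n}")
        sub = frame[mask].reset_index(drop=True)
        if sub["temp"].nunique() < 2 or sub["year"].nunique() < 2 or \
                sub["female_id"].nunique() < 2:
            out[name] = (None, None, n)
            flags.append(f"{name}-peak side degenerate")
            continue
        cols = [np.ones(n), _Scaler(sub["temp"].to_numpy())(sub["temp"].to_numpy())]
        names = ["intercept", "temp"]
        for cov in fit.covariates:
            if sub[cov].nunique() < 2:
                continue
            cols.append(_Scaler(sub[cov].to_numpy())(sub[cov].to_numpy()))
            names.append(cov)
        y, trials = _response_arrays(sub, fit.response)
        m = fit_glmm(y, np.column_stack(cols),
                     {"year": sub["year"].to_numpy(), "female": sub["female_id"].to_numpy()},
                     family=fit.family, trials=trials, fe_names=names)
        out[name] = (float(m.fe_params[1]), m.wald_ci(1), n)
    pre, post = out["pre"], out["post"]
    if peak.at_boundary:
        flags.append("peak at grid boundary; one-sided result")
    return PiecewiseTrend(
        prepeak_slope=pre[0], prepeak_ci=pre[1],
        postpeak_slope=post[0], postpeak_ci=post[1],
        n_pre=pre[2], n_post=post[2], flags=flags)


def compare_with_mismatch_covariate(
    attempts: list[BreedingAttempt],
    interval_temps: pd.DataFrame,
    mismatch: pd.DataFrame,
    response: str,
    period: Period | str = Period.LAYING,
    df_spline: int = 7,
    n_boot_peak: int = 0,
    seed: int = 0,
) -> MediationComparison:
    """How much does controlling for absolute mismatch attenuate the
    post-peak temperature slope?

    Both models are fitted on the attempts that have mismatch records (years
    with half-fall data); the attenuation factor is the ratio of post-peak
    slope magnitudes (with / without the mismatch covariate).
    """
    if response not in ("n_fledged", "fledging_success"):
        raise ValueError("mediation comparison applies to n_fledged or fledging_success")
    ids = set(mismatch["attempt_id"])
    restricted = [a for a in attempts if a.attempt_id in ids]
    base = fit_fitness_spline_model(restricted, interval_temps, response, period,
                                    df_spline=df_spline)
    with_m = fit_fitness_spline_model(restricted, interval_temps, response, period,
                                      df_spline=df_spline, mismatch=mismatch,
                                      include_mismatch=True)
    peak = locate_peak_with_interval(base, n_boot=n_boot_peak, seed=seed)
    trend_base = fit_prepost_peak_trends(base, peak)
    trend_with = fit_prepost_peak_trends(with_m, peak)
    s0 = trend_base.postpeak_slope
    s1 = trend_with.postpeak_slope
    atten = float("nan")
    if s0 is not None and s1 is not None and abs(s0) > 0:
        atten = abs(s1) / abs(s0)
    grid = base.grid
    curve_with = np.interp(grid, with_m.grid, with_m.curve)
    return MediationComparison(
        response=response, curve_without=base.curve, curve_with=curve_with,
        grid=grid, postpeak_without=s0 if s0 is not None else float("nan"),
        postpeak_with=s1 if s1 is not None else float("nan"),
        attenuation=atten, n_obs=base.n_obs)
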