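"""Natural cubic spline bases for nonlinear temperature effects.

The convention follows R's ``splines::ns``: ``df`` basis columns excluding
the intercept, interior knots at equally spaced quantiles of the data,
boundary knots at the data range, and natural (linear) extrapolation beyond
the boundary knots.  The basis is the truncated-power natural form, which
spans the same function space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "NaturalCubicSpline", "natural_cubic_spline_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Degrees of freedom and knot layout of a natural cubic spline basis."""

    df: int = 7
    knots: tuple[float, ...] = ()       # interior knots
    boundary: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.df < 3:
            raise ValueError("natural cubic spline needs df >= 3")
        ks = np.asarray(self.knots, dtype=float)
        lo, hi = self.boundary
        if ks.size and (np.diff(ks) <= 0).any():
            raise ValueError("interior knots must be strictly increasing")
        if ks.size and ((ks <= lo) | (ks >= hi)).any():
            raise ValueError("interior knots must lie strictly inside the boundary")


class NaturalCubicSpline:
    """ns()-style basis fitted to data, reusable on any evaluation grid."""

    def __init__(self, spec: SplineSpec):
        self.spec = spec
        lo, hi = spec.boundary
        self.all_knots = np.concatenate([[lo], np.asarray(spec.knots, float), [hi]])
        if len(self.all_knots) != spec.df + 1:
            raise ValueError(
                f"df={spec.df} requires {spec.df - 1} interior knots, "
                f"got {len(spec.knots)}")

    @classmethod
    def from_data(cls, x, df: int = 7) -> "NaturalCubicSpline":
        """Interior knots at equally spaced quantiles, boundary at the range."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if np.unique(x).size < df + 1:
            raise ValueError(f"need at least {df + 1} distinct values for df={df}")
        n_interior = df - 1
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(x, probs)
        lo, hi = float(x.min()), float(x.max())
        # collapse ties in heavily discrete data by nudging
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        if (np.diff(interior) <= 0).any():
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return cls(SplineSpec(df=df, knots=tuple(interior), boundary=(lo, hi)))

    def design(self, x) -> np.ndarray:
        """Evaluate the df basis columns (intercept excluded) at x."""
        x = np.asarray(x, dtype=float)
        knots = self.all_knots
        K = len(knots)
        xi_K = knots[-1]
        scale = (xi_K - knots[0]) ** 2  # conditioning only; span unchanged

        def d(k):
            num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - xi_K, 0.0, None) ** 3
            return num / (xi_K - knots[k]) / scale

        cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
        return np.column_stack(cols)


def natural_cubic_spline_basis(x, spec: SplineSpec | int = 7) -> tuple[np.ndarray, "NaturalCubicSpline"]:
    """Basis matrix for x; an int spec means df with data-driven knots."""
    if isinstance(spec, int):
        tr = NaturalCubicSpline.from_data(x, df=spec)
    else:
        tr = NaturalCubicSpline(spec)
    return tr.design(x), tr
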