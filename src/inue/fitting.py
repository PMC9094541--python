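"""Quadratic-plateau yield-response fitting and inclusion screening.

Maize grain yield as a function of fertilizer N rate is modelled with a
segmented quadratic-plateau (QP) curve:

    yield(N) = c + b*N + a*N^2      for N <= x0
    yield(N) = c - b^2 / (4*a)      for N >  x0

with ``a < 0`` and the join point at the vertex ``x0 = -b / (2*a)``, which
makes the curve continuously differentiable (C1). Fitting profiles the join
point on a grid: for a candidate x0 the C1 constraint ``b = -2*a*x0`` makes
the model linear in ``(c, a)``, so each candidate is an ordinary
least-squares solve; the best candidate is then polished with a bounded
derivative-free search. This keeps the optimisation globally robust and
easy to audit against a brute-force grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitError",
    "NRateTrial",
    "QPFit",
    "ScreenResult",
    "fit_quadratic_plateau",
    "screen_fit",
]

#: default significance level for the overall-regression F screen
DEFAULT_ALPHA = 0.10
#: default minimum coefficient of determination for inclusion
DEFAULT_R2_MIN = 0.30


class FitError(ValueError):
    """Raised when a yield-response trial cannot be fitted."""


@dataclass
class NRateTrial:
    """One site-year of an N-rate trial.

    Parameters
    ----------
    site_id : str
        Site identifier.
    year : int
        Trial year.
    n_rates : array-like
        Fertilizer N rates, kg N/ha. Must include a zero-N control.
    yields : array-like
        Dry-basis grain yields, kg/ha, one per rate.
    dataset : str
        Optional dataset/group label (e.g. a regional study name).
    attrs : dict
        Optional soil / management attributes.
    """

    site_id: str
    year: int
    n_rates: np.ndarray
    yields: np.ndarray
    dataset: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_rates = np.asarray(self.n_rates, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.n_rates.shape != self.yields.shape:
            raise ValueError("n_rates and yields must have the same length")

    def validate(self) -> None:
        """Check the design-point invariants needed for QP fitting."""
        if self.n_rates.size < 5:
            raise ValueError(
                f"trial {self.site_id}/{self.year}: needs >= 5 design points, "
                f"got {self.n_rates.size}"
            )
        if np.unique(self.n_rates).size < 4:
            raise ValueError(
                f"trial {self.site_id}/{self.year}: needs >= 4 distinct N rates"
            )
        if not np.any(self.n_rates == 0):
            raise ValueError(
                f"trial {self.site_id}/{self.year}: must include a zero-N control"
            )
        if np.any(self.n_rates < 0):
            raise ValueError(f"trial {self.site_id}/{self.year}: negative N rate")
        if np.any(self.yields < 0):
            raise ValueError(f"trial {self.site_id}/{self.year}: negative yield")

    @property
    def key(self) -> tuple:
        return (self.site_id, self.year)


@dataclass
class ScreenResult:
    """Per-screen inclusion flags for a fitted site-year."""

    f_significant: bool
    r2_ok: bool
    join_below_max: bool

    @property
    def passed(self) -> bool:
        return self.f_significant and self.r2_ok and self.join_below_max


@dataclass
class QPFit:
    """Fitted quadratic-plateau coefficients and diagnostics.

    ``a`` is in (kg grain * ha)/(kg N)^2, ``b`` in kg grain/kg N and ``c``
    (the zero-N yield) in kg grain/ha. ``x0`` is the join point in kg N/ha.
    """

    site_id: str
    year: int
    a: float
    b: float
    c: float
    x0: float
    plateau_yield: float
    r2: float
    f_pvalue: float
    sse: float
    sst: float
    n_obs: int
    max_rate_applied: float
    dataset: str = ""
    attrs: dict = field(default_factory=dict)
    screens: Optional[ScreenResult] = None

    def predict(self, n_rate):
        """Predicted dry-grain yield (kg/ha) at ``n_rate`` (kg N/ha)."""
        n = np.asarray(n_rate, dtype=float)
        out = np.where(
            n <= self.x0,
            self.c + self.b * n + self.a * n * n,
            self.plateau_yield,
        )
        return float(out) if np.isscalar(n_rate) else out

    @property
    def passed_screens(self) -> bool:
        if self.screens is None:
            raise ValueError("fit has not been screened yet")
        return self.screens.passed


def _sse_at_x0(n: np.ndarray, y: np.ndarray, x0: float):
    """Least-squares (c, a) for a fixed join point; b = -2*a*x0 is implied.

    With the C1 constraint the model is ``y = c + a * z(N)`` where
    ``z = N^2 - 2*x0*N`` below the join and ``z = -x0^2`` on the plateau.
    """
    z = np.where(n <= x0, n * (n - 2.0 * x0), -x0 * x0)
    X = np.column_stack([np.ones_like(n), z])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_quadratic_plateau(trial: NRateTrial, grid_step: float = 1.0) -> QPFit:
    """Fit the C1 quadratic-plateau model to one site-year.

    The join point is profiled on a grid over ``(0, 1.5 * max rate]`` at
    ``grid_step`` kg N/ha (ties broken toward the smallest x0), then the
    best candidate is polished with a bounded scalar minimisation.

    Raises
    ------
    FitError
        If the trial has fewer points than parameters or all yields are
        identical (r^2 undefined).
    """
    trial.validate()
    n = trial.n_rates
    y = trial.yields
    if n.size <= 3:
        raise FitError("fewer design points than model parameters")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        raise FitError(
            f"trial {trial.site_id}/{trial.year}: all yields identical, "
            "degenerate fit (r2 undefined)"
        )

    max_rate = float(n.max())
    hi = 1.5 * max_rate
    grid = np.arange(grid_step, hi + 0.5 * grid_step, grid_step)
    sses = np.array([_sse_at_x0(n, y, x0)[1] for x0 in grid])
    best = int(np.argmin(sses))  # first minimum -> smallest x0 on ties
    best_x0 = float(grid[best])
    best_sse = float(sses[best])

    # local polish around the winning grid candidate
    lo_b = max(grid_step * 1e-3, best_x0 - grid_step)
    hi_b = min(hi, best_x0 + grid_step)
    res = optimize.minimize_scalar(
        lambda x0: _sse_at_x0(n, y, x0)[1],
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if res.success and res.fun <= best_sse:
        best_x0 = float(res.x)
        best_sse = float(res.fun)

    (c, a), sse = _sse_at_x0(n, y, best_x0)
    b = -2.0 * a * best_x0
    plateau = c - b * b / (4.0 * a) if a != 0.0 else c

    r2 = 1.0 - sse / sst
    df_den = n.size - 3
    if sse <= 1e-12 * sst:
        f_pvalue = 0.0
    else:
        f_stat = ((sst - sse) / 2.0) / (sse / df_den)
        f_pvalue = float(stats.f.sf(f_stat, 2, df_den))

    return QPFit(
        site_id=trial.site_id,
        year=trial.year,
        a=float(a),
        b=float(b),
        c=float(c),
        x0=best_x0,
        plateau_yield=float(plateau),
        r2=float(r2),
        f_pvalue=f_pvalue,
        sse=sse,
        sst=sst,
        n_obs=int(n.size),
        max_rate_applied=max_rate,
        dataset=trial.dataset,
        attrs=dict(trial.attrs),
    )


def screen_fit(
    fit: QPFit,
    alpha: float = DEFAULT_ALPHA,
    r2_min: float = DEFAULT_R2_MIN,
) -> ScreenResult:
    """Apply the three inclusion screens to a fitted site-year.

    A site-year is retained when (i) the overall-regression F test is
    significant at ``alpha``, (ii) r^2 >= ``r2_min`` and (iii) the plateau
    join point lies below the highest N rate applied in that trial.
    The result is stored on ``fit.screens`` and returned.
    """
    result = ScreenResult(
        f_significant=bool(fit.f_pvalue < alpha),
        r2_ok=bool(fit.r2 >= r2_min),
        join_below_max=bool(fit.x0 < fit.max_rate_applied),
    )
    fit.screens = result
    return result


def brute_force_sse(trial: NRateTrial, step: float = 0.5) -> float:
    """Dense grid-search SSE oracle over x0 in (0, 1.5 * max rate].

    Independent cross-check for the profiled fit; not used by it.
    """
    n, y = trial.n_rates, trial.yields
    hi = 1.5 * float(n.max())
    grid = np.arange(step, hi + 0.5 * step, step)
    return min(_sse_at_x0(n, y, x0)[1] for x0 in grid)
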