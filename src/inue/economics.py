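"""Economic-optimum N rate, incremental/average NUE and forgone profit.

Core quantities, all derived from a fitted quadratic-plateau response
``yield(N) = c + b*N + a*N^2`` (N <= x0, a < 0):

* EONR — the economically optimal N rate, where the marginal yield gain
  equals the grain-equivalent cost of N:  ``EONR = (ratio - b) / (2a)``
  with ``ratio`` the N:grain price ratio in kg grain per kg N.
* iNUE — incremental N use efficiency, the grain-N captured by the next
  kg of fertilizer N: ``iNUE(N) = (b + 2*a*N) * k`` where ``k`` is the
  grain N content (kg grain-N per kg grain, default 0.0115).
* average NUE — grain-N gained over the zero-N control per kg applied:
  ``(b + a*N) * k`` under the QP model.
* partial profit — grain revenue minus fertilizer cost, $/ha; forgone
  (unrealized) profit is the profit deficit of a sub-EONR rate relative
  to fertilizing exactly at EONR.

iNUE at EONR equals ``ratio * k`` at every site: the terminal efficiency
is set entirely by prices, not by the response curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import QPFit

__all__ = [
    "GRAIN_N_COEF",
    "PriceSet",
    "NUEProfile",
    "EconomicsError",
    "PlateauWarning",
    "eonr",
    "inue",
    "terminal_inue",
    "initial_inue",
    "avg_nue",
    "grain_n_sensitivity",
    "partial_profit",
    "forgone_profit",
    "forgone_profit_ratio",
    "invert_forgone",
    "rate_of_decrease",
    "weighted_mean",
    "nue_profile",
    "step_summary",
    "dataset_summary",
]

log = logging.getLogger(__name__)

#: baseline grain N content, kg grain-N per kg dry grain
GRAIN_N_COEF = 0.0115


class EconomicsError(ValueError):
    """Raised for economically invalid inputs (e.g. a >= 0, rate beyond EONR)."""


class PlateauWarning(UserWarning):
    """Marginal quantities requested beyond the yield plateau."""


@dataclass(frozen=True)
class PriceSet:
    """Grain and N fertilizer prices and the price ratio used for EONR.

    The default ratio is the fixed 5.6 kg grain per kg N; when ``ratio``
    is ``None`` it is derived from the raw prices as
    ``price_n / price_grain``. Profit calculations always use the raw
    prices; EONR uses the (possibly fixed) ratio.
    """

    price_grain: float = 0.158  # $/kg grain
    price_n: float = 0.88  # $/kg N
    ratio: Optional[float] = 5.6  # kg grain per kg N

    def __post_init__(self) -> None:
        if self.price_grain <= 0 or self.price_n <= 0:
            raise ValueError("prices must be positive")
        if self.ratio is not None and self.ratio <= 0:
            raise ValueError("price ratio must be positive")

    @property
    def effective_ratio(self) -> float:
        if self.ratio is not None:
            return self.ratio
        return self.price_n / self.price_grain

    @classmethod
    def from_prices(cls, price_grain: float, price_n: float) -> "PriceSet":
        """Price set whose ratio is derived from the raw prices."""
        return cls(price_grain=price_grain, price_n=price_n, ratio=None)


DEFAULT_PRICES = PriceSet()


def eonr(fit: QPFit, prices: PriceSet = DEFAULT_PRICES) -> float:
    """Economic optimal N rate, kg N/ha: ``(ratio - b) / (2a)``.

    Always strictly below the join point x0 when ``b > ratio``. If the
    initial marginal product never exceeds the price ratio the optimum is
    zero (fertilization is never profitable) and a warning is emitted.
    """
    if fit.a >= 0:
        raise EconomicsError("EONR requires a concave response (a < 0)")
    ratio = prices.effective_ratio
    if fit.b <= ratio:
        warnings.warn(
            f"site {fit.site_id}/{fit.year}: b = {fit.b:.3g} <= price ratio "
            f"{ratio:.3g}; fertilization never profitable, EONR = 0",
            PlateauWarning,
            stacklevel=2,
        )
        return 0.0
    return (ratio - fit.b) / (2.0 * fit.a)


def inue(fit: QPFit, n_rate: float, grain_n_coef: float = GRAIN_N_COEF) -> float:
    """Incremental NUE at ``n_rate``: ``(b + 2*a*N) * k`` (fraction).

    Beyond the join point the marginal yield is zero, so 0 is returned
    (with a :class:`PlateauWarning`).
    """
    if n_rate < 0:
        raise EconomicsError("n_rate must be non-negative")
    if n_rate > fit.x0:
        warnings.warn(
            f"n_rate {n_rate:.1f} beyond join point {fit.x0:.1f}: "
            "no marginal grain on the plateau",
            PlateauWarning,
            stacklevel=2,
        )
        return 0.0
    return (fit.b + 2.0 * fit.a * n_rate) * grain_n_coef


def terminal_inue(
    prices: PriceSet = DEFAULT_PRICES, grain_n_coef: float = GRAIN_N_COEF
) -> float:
    """iNUE at EONR (fraction): ``ratio * k``, independent of the site."""
    return prices.effective_ratio * grain_n_coef


def initial_inue(fit: QPFit, grain_n_coef: float = GRAIN_N_COEF) -> float:
    """iNUE of the first kg of fertilizer (evaluated at N = 1 kg/ha)."""
    return inue(fit, 1.0, grain_n_coef)


def avg_nue(fit: QPFit, n_rate: float, grain_n_coef: float = GRAIN_N_COEF) -> float:
    """Average NUE at ``n_rate`` (fraction).

    Grain-N gained over the zero-N control per kg N applied:
    ``(GrainN(N) - GrainN(0)) / N`` with ``GrainN = yield * k``; equals
    ``(b + a*N) * k`` on the quadratic branch. Undefined at N = 0 — use
    :func:`inue` at ~1 kg/ha there.
    """
    if n_rate == 0:
        raise EconomicsError(
            "average NUE is undefined at N = 0; use inue at ~1 kg/ha instead"
        )
    if n_rate < 0:
        raise EconomicsError("n_rate must be non-negative")
    return (fit.predict(n_rate) - fit.c) * grain_n_coef / n_rate


def grain_n_sensitivity(
    avg_nue_base: float, coef_base: float, coef_new: float
) -> float:
    """Rescale an average-NUE value to a different grain N content.

    Average NUE is proportional to the grain N coefficient, so the
    rescaled value is ``avg_nue_base * coef_new / coef_base``.
    """
    for name, val in (("coef_base", coef_base), ("coef_new", coef_new)):
        if not (0.0 < val < 0.05):
            raise ValueError(f"{name} = {val} outside plausible range (0, 0.05)")
    return avg_nue_base * coef_new / coef_base


def partial_profit(
    fit: QPFit, n_rate: float, prices: PriceSet = DEFAULT_PRICES
) -> float:
    """Partial profit, $/ha: grain revenue minus fertilizer cost."""
    if n_rate < 0:
        raise EconomicsError("n_rate must be non-negative")
    return prices.price_grain * fit.predict(n_rate) - prices.price_n * n_rate


def forgone_profit(
    fit: QPFit, n_rate: float, prices: PriceSet = DEFAULT_PRICES
) -> float:
    """Forgone (unrealized) profit of a sub-EONR rate, $/ha.

    ``partial_profit(EONR) - partial_profit(N)``; non-negative on
    [0, EONR], exactly zero at EONR.
    """
    opt = eonr(fit, prices)
    if n_rate > opt + 1e-9:
        raise EconomicsError(
            f"n_rate {n_rate:.2f} exceeds EONR {opt:.2f}; the forgone-profit "
            "curve is defined for sub-optimal rates only"
        )
    return partial_profit(fit, opt, prices) - partial_profit(fit, n_rate, prices)


def forgone_profit_ratio(
    fit: QPFit, n_rate: float, prices: PriceSet = DEFAULT_PRICES
) -> float:
    """Quotient variant: partial profit at N divided by partial profit at EONR.

    Exposed for auditability alongside the primary difference form
    (:func:`forgone_profit`), whose $/ha units match the reported curves.
    """
    opt = eonr(fit, prices)
    denom = partial_profit(fit, opt, prices)
    if denom == 0:
        raise EconomicsError("partial profit at EONR is zero; ratio undefined")
    return partial_profit(fit, n_rate, prices) / denom


def invert_forgone(
    fit: QPFit, prices: PriceSet = DEFAULT_PRICES, step_value: float = 0.0
) -> float:
    """N rate (kg/ha) at which forgone profit equals ``step_value`` $/ha.

    Solved from the closed-form quadratic; of the two roots the one
    nearest EONR is taken, so larger steps map to smaller rates.
    """
    if step_value < 0:
        raise EconomicsError("step_value must be non-negative")
    opt = eonr(fit, prices)
    fmax = forgone_profit(fit, 0.0, prices)
    if step_value > fmax + 1e-9:
        raise EconomicsError(
            f"step_value {step_value:.2f} exceeds the maximum attainable "
            f"forgone profit {fmax:.2f} $/ha (at N = 0)"
        )
    pg, pn = prices.price_grain, prices.price_n
    # g(N) = pg*a*N^2 + (pg*b - pn)*N ; solve g(N) = g(EONR) - step
    alpha = pg * fit.a
    beta = pg * fit.b - pn
    target = alpha * opt * opt + beta * opt - step_value
    disc = beta * beta + 4.0 * alpha * target
    if disc < 0:
        disc = 0.0  # guard against round-off at step ~ fmax
    root = (-beta + np.sqrt(disc)) / (2.0 * alpha)
    other = (-beta - np.sqrt(disc)) / (2.0 * alpha)
    # pick the admissible root nearest EONR
    candidates = [r for r in (root, other) if -1e-9 <= r <= opt + 1e-9]
    if not candidates:
        raise EconomicsError("no admissible root for forgone-profit inversion")
    n_star = min(candidates, key=lambda r: abs(r - opt))
    return float(np.clip(n_star, 0.0, opt))


def rate_of_decrease(
    initial_inue_frac: float, terminal_inue_frac: float, eonr_kg: float
) -> float:
    """Average decrease in iNUE per kg N, percentage points per kg.

    ``100 * (initial - terminal) / EONR`` with both efficiencies as
    fractions; the endpoint (chord) form of the decline.
    """
    if eonr_kg <= 0:
        raise EconomicsError("EONR must be positive for a rate of decrease")
    return 100.0 * (initial_inue_frac - terminal_inue_frac) / eonr_kg


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Site-year-count-weighted mean across dataset groups."""
    return float(np.average(np.asarray(values, float), weights=np.asarray(weights, float)))


@dataclass
class NUEProfile:
    """Per-kg NUE and profit curves for one screened site-year."""

    fit: QPFit
    prices: PriceSet
    grain_n_coef: float
    eonr: float
    n_grid: np.ndarray  # 1..round(EONR), kg N/ha
    inue: np.ndarray  # fraction
    avg_nue: np.ndarray  # fraction
    partial_profit: np.ndarray  # $/ha
    forgone_profit: np.ndarray  # $/ha
    n_saved: np.ndarray  # kg N/ha, EONR - N
    yield_reduction: np.ndarray  # kg/ha, yield(EONR) - yield(N)
    initial_inue: float
    terminal_inue: float
    slope_grain_n: float  # 2*a*k, fraction per kg N
    slope_grain_n_pct: float  # percentage points per kg N


def nue_profile(
    fit: QPFit,
    prices: PriceSet = DEFAULT_PRICES,
    grain_n_coef: float = GRAIN_N_COEF,
) -> NUEProfile:
    """Evaluate the per-kg iNUE/NUE/profit curves from N = 1 to EONR."""
    opt = eonr(fit, prices)
    if opt < 1.0:
        raise EconomicsError(
            f"EONR {opt:.2f} kg N/ha is below 1 kg/ha; no per-kg profile"
        )
    n_grid = np.arange(1.0, round(opt) + 1.0)
    inue_arr = (fit.b + 2.0 * fit.a * n_grid) * grain_n_coef
    avg_arr = (fit.predict(n_grid) - fit.c) * grain_n_coef / n_grid
    pp = prices.price_grain * fit.predict(n_grid) - prices.price_n * n_grid
    pp_opt = partial_profit(fit, opt, prices)
    return NUEProfile(
        fit=fit,
        prices=prices,
        grain_n_coef=grain_n_coef,
        eonr=opt,
        n_grid=n_grid,
        inue=inue_arr,
        avg_nue=avg_arr,
        partial_profit=pp,
        forgone_profit=pp_opt - pp,
        n_saved=opt - n_grid,
        yield_reduction=fit.predict(opt) - fit.predict(n_grid),
        initial_inue=initial_inue(fit, grain_n_coef),
        terminal_inue=(fit.b + 2.0 * fit.a * opt) * grain_n_coef,
        slope_grain_n=2.0 * fit.a * grain_n_coef,
        slope_grain_n_pct=200.0 * fit.a * grain_n_coef,
    )


def _tukey_whiskers(x: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return float(lo), float(hi)


def step_summary(
    fits: Iterable[QPFit],
    prices: PriceSet = DEFAULT_PRICES,
    steps: Sequence[float] = tuple(range(0, 260, 20)),
    grain_n_coef: float = GRAIN_N_COEF,
    weights: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of iNUE/NUE/N-saved/yield-loss at forgone-profit steps.

    For each step value s ($/ha) and each screened site-year, the N rate
    with forgone profit exactly s is found by inversion; iNUE, average
    NUE, N saved (EONR - N) and yield reduction are evaluated there.
    Sites whose forgone-profit range cannot reach a step are excluded
    from that step (counted in the summary).

    Returns
    -------
    (per_site, summary) : DataFrames
        ``per_site`` has one row per site-year per reachable step;
        ``summary`` has distribution statistics (mean, median, quartiles,
        Tukey 1.5*IQR whisker bounds) per step and variable, plus an
        across-dataset weighted mean (weights = site-year counts unless
        supplied).
    """
    fits = [f for f in fits if f.screens is None or f.passed_screens]
    rows = []
    excluded: dict[float, int] = {s: 0 for s in steps}
    for fit in fits:
        opt = eonr(fit, prices)
        if opt <= 0:
            continue
        fmax = forgone_profit(fit, 0.0, prices)
        for s in steps:
            if s > fmax:
                excluded[s] += 1
                continue
            n_s = invert_forgone(fit, prices, s)
            rows.append(
                {
                    "dataset": fit.dataset,
                    "site_id": fit.site_id,
                    "year": fit.year,
                    "step_usd_ha": s,
                    "n_rate_kg_ha": n_s,
                    "inue_pct": 100.0 * inue(fit, n_s, grain_n_coef),
                    "avg_nue_pct": 100.0 * avg_nue(fit, max(n_s, 1.0), grain_n_coef),
                    "n_saved_kg_ha": opt - n_s,
                    "yield_reduction_kg_ha": fit.predict(opt) - fit.predict(n_s),
                }
            )
    per_site = pd.DataFrame(rows)
    if per_site.empty:
        return per_site, pd.DataFrame()

    variables = ["inue_pct", "avg_nue_pct", "n_saved_kg_ha", "yield_reduction_kg_ha"]
    summary_rows = []
    for s in steps:
        grp = per_site[per_site["step_usd_ha"] == s]
        if grp.empty:
            # step out of range for every site: reported, not silently dropped
            for var in variables:
                summary_rows.append(
                    {
                        "step_usd_ha": s,
                        "variable": var,
                        "n_sites": 0,
                        "n_excluded": excluded[s],
                        "mean": np.nan,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "whisker_lo": np.nan,
                        "whisker_hi": np.nan,
                        "weighted_mean": np.nan,
                    }
                )
            log.info("step %s $/ha: out of range for all site-years", s)
            continue
        if weights is not None:
            w = weights
        else:
            w = grp.groupby("dataset").size().to_dict()
        for var in variables:
            x = grp[var].to_numpy()
            q1, q3 = np.percentile(x, [25, 75])
            lo, hi = _tukey_whiskers(x)
            by_ds = grp.groupby("dataset")[var].mean()
            wmean = weighted_mean(
                [by_ds[d] for d in by_ds.index], [w.get(d, 1) for d in by_ds.index]
            )
            summary_rows.append(
                {
                    "step_usd_ha": s,
                    "variable": var,
                    "n_sites": len(x),
                    "n_excluded": excluded[s],
                    "mean": float(x.mean()),
                    "median": float(np.median(x)),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_lo": lo,
                    "whisker_hi": hi,
                    "weighted_mean": wmean,
                }
            )
        if excluded[s]:
            log.info("step %s $/ha: %d site-years out of range", s, excluded[s])
    return per_site, pd.DataFrame(summary_rows)


def dataset_summary(
    fits: Iterable[QPFit],
    prices: PriceSet = DEFAULT_PRICES,
    weights: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-dataset EONR and yield summaries, plus a weighted-mean row.

    Reports, per dataset group: mean/min/max/span of EONR, percent yield
    increase at EONR over the zero-N control, zero-N yield, and the gap
    between the agronomic optimum (join point) and EONR. The weighted
    mean uses site-year counts as weights unless supplied.
    """
    rows = {}
    for fit in fits:
        if fit.screens is not None and not fit.passed_screens:
            continue
        opt = eonr(fit, prices)
        rows.setdefault(fit.dataset, []).append(
            {
                "eonr": opt,
                "yield0": fit.c,
                "pct_yield_increase": 100.0 * (fit.predict(opt) - fit.c) / fit.c,
                "opt_minus_eonr": fit.x0 - opt,
            }
        )
    out = []
    for ds, recs in rows.items():
        if not recs:
            warnings.warn(f"dataset {ds!r}: empty group omitted", stacklevel=2)
            continue
        df = pd.DataFrame(recs)
        out.append(
            {
                "dataset": ds,
                "n_site_years": len(df),
                "eonr_mean": df["eonr"].mean(),
                "eonr_min": df["eonr"].min(),
                "eonr_max": df["eonr"].max(),
                "eonr_span": df["eonr"].max() - df["eonr"].min(),
                "yield0_mean": df["yield0"].mean(),
                "pct_yield_increase_mean": df["pct_yield_increase"].mean(),
                "opt_minus_eonr_mean": df["opt_minus_eonr"].mean(),
            }
        )
    table = pd.DataFrame(out)
    if table.empty:
        return table
    w = (
        [weights.get(d, 1) for d in table["dataset"]]
        if weights is not None
        else table["n_site_years"].tolist()
    )
    wrow = {"dataset": "weighted_mean", "n_site_years": int(np.sum(w))}
    for col in table.columns[2:]:
        wrow[col] = weighted_mean(table[col].tolist(), w)
    return pd.concat([table, pd.DataFrame([wrow])], ignore_index=True)
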