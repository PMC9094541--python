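"""Synthetic N-rate trials, daily weather and soil/management attributes.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external data:

* yields follow a true quadratic-plateau curve per site-year with
  additive homoscedastic Gaussian noise;
* daily precipitation is an occurrence (Bernoulli) x amount (Gamma)
  mixture whose parameters shift with a weather profile controlling
  evenness and seasonal totals; temperatures follow a seasonal sinusoid
  with a positive diurnal range by construction;
* soil texture, drainage and management attributes are drawn per site,
  and an optional covariate link tilts the true response curvature |a|
  log-linearly with rainfall evenness (more even rain -> faster iNUE
  decline) and clay content (heavier soils -> slower decline, higher
  EONR), giving a tunable, recoverable signal for the classifier.

All draws descend from a single seed through per-site seed sequences, so
identical configurations reproduce identical tables byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import NRateTrial
from .weather import WINDOWS

__all__ = [
    "WEATHER_PROFILES",
    "SyntheticSiteConfig",
    "generate_trials",
    "generate_weather",
    "generate_soil_attrs",
]

#: price ratio implied by the default prices; b must exceed it for EONR > 0
_MIN_B = 5.6

#: precipitation mixture per profile: daily wet-day probability, Gamma
#: shape and scale (mm). "even"/"uneven" steer evenness (SDI), "wet"/"dry"
#: steer seasonal totals.
WEATHER_PROFILES: dict[str, dict[str, float]] = {
    "even": {"p_wet": 0.62, "shape": 2.0, "scale": 3.0},
    "uneven": {"p_wet": 0.08, "shape": 0.7, "scale": 45.0},
    "wet": {"p_wet": 0.55, "shape": 2.0, "scale": 8.0},
    "dry": {"p_wet": 0.22, "shape": 1.2, "scale": 4.0},
}

DRAINAGE_CLASSES = [
    "very poorly drained",
    "poorly drained",
    "somewhat poorly drained",
    "moderately well drained",
    "well drained",
    "excessively drained",
]

TAXONOMIC_ORDERS = ["Mollisols", "Alfisols", "Entisols", "Vertisols"]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


@dataclass
class SyntheticSiteConfig:
    """Study conditions for the synthetic ensemble.

    Default coefficient ranges are centred on the scale implied by
    published maize responses (initial marginal product b around 75 kg
    grain per kg N, curvature |a| around 0.25, hence join points near 150
    kg N/ha and economic optima of roughly 80-200 kg N/ha), with the
    standard six-rate design reaching beyond most join points so the
    plateau screen is exercisable. ``n_reps`` replicates each rate (a randomized
    complete block layout without block effects): plot trials are
    replicated in practice, and single observations per rate leave the
    curvature poorly identified at realistic yield noise.
    """

    n_sites: int = 60
    n_rates: Sequence[float] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0)
    n_reps: int = 4
    a_range: tuple[float, float] = (-0.35, -0.15)
    b_range: tuple[float, float] = (55.0, 95.0)
    c_range: tuple[float, float] = (4000.0, 9000.0)
    noise_sd: float = 300.0
    seed: int = 0
    weather_profile: str = "even"
    covariate_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites: must be >= 1")
        rates = np.asarray(self.n_rates, dtype=float)
        if 0.0 not in rates:
            raise ConfigError("n_rates: must include a zero-N control")
        if np.unique(rates[rates > 0]).size < 4:
            raise ConfigError("n_rates: needs >= 4 distinct positive rates")
        if self.n_reps < 1:
            raise ConfigError("n_reps: must be >= 1")
        if not self.a_range[0] < self.a_range[1] < 0:
            raise ConfigError("a_range: upper bound must be < 0 and > lower")
        if not self.b_range[0] < self.b_range[1]:
            raise ConfigError("b_range: lower bound must be below upper")
        if self.b_range[0] <= _MIN_B:
            raise ConfigError(
                f"b_range: lower bound must exceed the price ratio {_MIN_B} "
                "so that EONR > 0"
            )
        if not self.c_range[0] < self.c_range[1]:
            raise ConfigError("c_range: lower bound must be below upper")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if self.weather_profile not in WEATHER_PROFILES:
            raise ConfigError(
                f"weather_profile: unknown profile {self.weather_profile!r}; "
                f"allowed: {sorted(WEATHER_PROFILES)}"
            )


def _site_index(site_id: str) -> int:
    digits = "".join(ch for ch in site_id if ch.isdigit())
    if digits:
        return int(digits)
    return zlib.crc32(site_id.encode()) % (2**31)


def _site_rng(config: SyntheticSiteConfig, idx: int, stream: int) -> np.random.Generator:
    # streams: 0 latents/truth, 1 yield noise, 2 weather, 3 soil extras
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(idx, stream))
    return np.random.default_rng(ss)


def _site_id(idx: int) -> str:
    return f"S{idx:03d}"


def _site_year(idx: int) -> int:
    return 2001 + idx % 10


def _site_latents(config: SyntheticSiteConfig, idx: int) -> dict:
    """Shared per-site latents: true QP coefficients and covariates.

    The covariate link is log-linear on |a|:
    ``log|a| = log|a0| + ce * (0.4 * evenness_z - 0.3 * clay_z)`` with
    standardized latents, so covariate_effect = 0 severs the association.
    The moderate coefficients keep the curvature spread (and hence the
    EONR and join-point distributions) within the range of real trials
    at ce around 1.
    """
    rng = _site_rng(config, idx, stream=0)
    evenness = rng.beta(2.0, 2.0)  # drives rainy-day frequency and SDI
    clay = rng.uniform(8.0, 48.0)
    sand = rng.uniform(5.0, min(85.0, 97.0 - clay))
    a0 = rng.uniform(*config.a_range)
    b = rng.uniform(*config.b_range)
    c = rng.uniform(*config.c_range)
    evenness_z = (evenness - 0.5) / 0.2236  # sd of Beta(2,2)
    clay_z = (clay - 28.0) / 11.547  # sd of U(8,48)
    ce = config.covariate_effect
    log_abs_a = np.log(abs(a0)) + ce * (0.4 * evenness_z - 0.3 * clay_z)
    a = -float(np.exp(log_abs_a))
    if clay >= 35.0:
        texture = "fine"
    elif clay >= 18.0:
        texture = "medium"
    else:
        texture = "coarse"
    return {
        "site_id": _site_id(idx),
        "year": _site_year(idx),
        "a": a,
        "b": float(b),
        "c": float(c),
        "x0": -float(b) / (2.0 * a),
        "evenness": float(evenness),
        "clay_pct": float(clay),
        "sand_pct": float(sand),
        "texture_class": texture,
    }


def generate_trials(
    config: SyntheticSiteConfig,
) -> tuple[list[NRateTrial], pd.DataFrame]:
    """Generate one trial per site plus the true-parameter record.

    Yields are the true QP curve evaluated at the design rates (each
    replicated ``n_reps`` times) plus i.i.d. Gaussian noise of
    ``noise_sd``; the returned truth table carries the generating
    coefficients for recovery experiments.
    """
    rates = np.tile(np.asarray(config.n_rates, dtype=float), config.n_reps)
    trials: list[NRateTrial] = []
    truths = []
    for idx in range(config.n_sites):
        lat = _site_latents(config, idx)
        a, b, c, x0 = lat["a"], lat["b"], lat["c"], lat["x0"]
        clean = np.where(rates <= x0, c + b * rates + a * rates**2, c + b * x0 + a * x0**2)
        noise_rng = _site_rng(config, idx, stream=1)
        noise = noise_rng.normal(0.0, config.noise_sd, size=rates.size) if config.noise_sd > 0 else 0.0
        yields = np.maximum(0.0, clean + noise)
        trials.append(
            NRateTrial(
                site_id=lat["site_id"],
                year=lat["year"],
                n_rates=rates.copy(),
                yields=yields,
                dataset="synthetic",
            )
        )
        truths.append(lat)
    return trials, pd.DataFrame(truths)


def generate_weather(config: SyntheticSiteConfig, site_id: str) -> pd.DataFrame:
    """Daily weather (Apr 15 - Sep 15, 154 rows) for one site-year.

    Precipitation occurrence/amount parameters come from the config's
    profile, modulated by the site's evenness latent (the same latent
    that tilts the response curvature when covariate_effect > 0).
    Temperatures ride a seasonal sinusoid with a strictly positive
    diurnal range, so tmax > tmin on every day.
    """
    idx = _site_index(site_id)
    lat = _site_latents(config, idx)
    prof = WEATHER_PROFILES[config.weather_profile]
    rng = _site_rng(config, idx, stream=2)

    year = lat["year"]
    start = pd.Timestamp(year, *WINDOWS["season"][0])
    end = pd.Timestamp(year, *WINDOWS["season"][1])
    dates = pd.date_range(start, end, freq="D")
    ndays = len(dates)

    p_wet = float(np.clip(prof["p_wet"] + 0.35 * (lat["evenness"] - 0.5), 0.03, 0.95))
    wet = rng.random(ndays) < p_wet
    amounts = rng.gamma(prof["shape"], prof["scale"], size=ndays)
    prcp = np.where(wet, amounts, 0.0)

    t = np.arange(ndays)
    tmean = 13.0 + 10.0 * np.sin(np.pi * t / (ndays - 1)) + rng.normal(0.0, 2.0, ndays)
    diurnal = np.clip(10.0 + rng.normal(0.0, 1.5, ndays), 2.0, None)
    return pd.DataFrame(
        {
            "site_id": site_id,
            "date": dates.strftime("%Y-%m-%d"),
            "tmin_c": np.round(tmean - diurnal / 2.0, 2),
            "tmax_c": np.round(tmean + diurnal / 2.0, 2),
            "prcp_mm": np.round(prcp, 2),
        }
    )


def generate_soil_attrs(config: SyntheticSiteConfig, site_id: str) -> dict:
    """Soil texture, drainage and management record for one site.

    Sand + clay never exceed 100% (silt is the implied remainder);
    drainage has six ordered classes and management flags are simple
    Bernoulli draws.
    """
    idx = _site_index(site_id)
    lat = _site_latents(config, idx)
    rng = _site_rng(config, idx, stream=3)
    sand, clay = lat["sand_pct"], lat["clay_pct"]
    return {
        "site_id": site_id,
        "year": lat["year"],
        "sand_pct": round(sand, 1),
        "clay_pct": round(clay, 1),
        "silt_pct": round(100.0 - sand - clay, 1),
        "texture_class": lat["texture_class"],
        "drainage_class": DRAINAGE_CLASSES[rng.integers(0, len(DRAINAGE_CLASSES))],
        "taxonomic_order": TAXONOMIC_ORDERS[rng.integers(0, len(TAXONOMIC_ORDERS))],
        "irrigation": bool(rng.random() < 0.4),
        "tillage": bool(rng.random() < 0.6),
        "rotation": "corn-soybean" if rng.random() < 0.6 else "continuous corn",
    }
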