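"""Season and phase weather features from daily temperature/precipitation.

Features are computed over four phenological windows of the maize season
(all dates inclusive):

* season        — April 15 to September 15 (154 days)
* establishment — April 15 to June 1 (48 days)
* growth        — June 2 to July 15 (44 days)
* grain_fill    — July 16 to September 15 (62 days)

Per window: total precipitation (PPT, mm), the Shannon Diversity Index of
daily rainfall shares (SDI, an evenness measure in [0, 1]), abundant and
well-distributed rainfall (AWDR = PPT * SDI, mm), growing degree days
(GDD, base 10 C) and Ontario-style corn heat units (CHU).
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "WINDOWS",
    "sdi",
    "awdr",
    "gdd",
    "chu",
    "build_features",
    "features_table",
]

#: (start month-day, end month-day) per window, both inclusive
WINDOWS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "season": ((4, 15), (9, 15)),
    "establishment": ((4, 15), (6, 1)),
    "growth": ((6, 2), (7, 15)),
    "grain_fill": ((7, 16), (9, 15)),
}

GDD_BASE_C = 10.0


def sdi(daily_prcp) -> float:
    """Shannon Diversity Index of daily precipitation shares.

    With p_i the share of window-total rainfall falling on day i,
    ``SDI = -sum(p_i * ln p_i) / ln(n)`` where n is the window length in
    days (the 0*ln 0 terms of dry days vanish). 1 means perfectly even
    rain, 0 a single-day event; a fully dry window is 0 by convention.
    """
    p = np.asarray(daily_prcp, dtype=float)
    if p.size < 2:
        raise ValueError("SDI needs at least 2 days")
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    total = p.sum()
    if total == 0:
        return 0.0
    shares = p[p > 0] / total
    entropy = -np.sum(shares * np.log(shares))
    return float(entropy / np.log(p.size))


def awdr(ppt: float, sdi_value: float) -> float:
    """Abundant and well-distributed rainfall: total PPT times SDI (mm)."""
    if ppt < 0 or not (0.0 <= sdi_value <= 1.0 + 1e-12):
        raise ValueError("need ppt >= 0 and sdi in [0, 1]")
    return ppt * sdi_value


def gdd(tmin, tmax, base: float = GDD_BASE_C) -> float:
    """Growing degree days: daily mean above ``base``, floored at 0, summed."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    return float(np.maximum(0.0, (tmin + tmax) / 2.0 - base).sum())


def chu(tmin, tmax) -> float:
    """Corn heat units, Ontario daily form, summed over the window.

    Daily CHU = (Ymax + Ymin) / 2 with the day term
    ``Ymax = 3.33*(tmax - 10) - 0.084*(tmax - 10)^2`` and the night term
    ``Ymin = 1.8*(tmin - 4.44)``, each floored at zero.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    ymax = np.maximum(0.0, 3.33 * (tmax - 10.0) - 0.084 * (tmax - 10.0) ** 2)
    ymin = np.maximum(0.0, 1.8 * (tmin - 4.44))
    return float(((ymax + ymin) / 2.0).sum())


def _window_mask(dates: pd.Series, window: str) -> pd.Series:
    (m1, d1), (m2, d2) = WINDOWS[window]
    md = dates.dt.month * 100 + dates.dt.day
    return (md >= m1 * 100 + d1) & (md <= m2 * 100 + d2)


def _validate_series(weather: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "tmin_c", "tmax_c", "prcp_mm"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    years = df["date"].dt.year.unique()
    if len(years) != 1:
        raise ValueError("weather series must cover a single year")
    year = int(years[0])
    start = pd.Timestamp(year, *WINDOWS["season"][0])
    end = pd.Timestamp(year, *WINDOWS["season"][1])
    expected = pd.date_range(start, end, freq="D")
    present = pd.DatetimeIndex(df["date"])
    gaps = expected.difference(present)
    if len(gaps) > 0:
        raise ValueError(
            "missing days in Apr 15 - Sep 15 window (no imputation): "
            + ", ".join(g.strftime("%Y-%m-%d") for g in gaps[:10])
            + (" ..." if len(gaps) > 10 else "")
        )
    if present.has_duplicates:
        raise ValueError("duplicated dates in weather series")
    df = df[df["date"].isin(expected)]
    if (df["tmax_c"] < df["tmin_c"]).any():
        raise ValueError("tmax < tmin in weather series")
    if (df["prcp_mm"] < 0).any():
        raise ValueError("negative precipitation in weather series")
    return df


def build_features(
    weather: pd.DataFrame, soil: Optional[Mapping] = None
) -> dict[str, float]:
    """All 20 weather features (5 features x 4 windows) for one site-year.

    ``weather`` needs columns ``date, tmin_c, tmax_c, prcp_mm`` covering
    the full Apr 15 - Sep 15 season with no gaps. Soil/management
    covariates, if given, are passed through into the feature record.
    """
    df = _validate_series(weather)
    feats: dict[str, float] = {}
    for window in WINDOWS:
        sub = df[_window_mask(df["date"], window)]
        ppt = float(sub["prcp_mm"].sum())
        s = sdi(sub["prcp_mm"].to_numpy())
        feats[f"ppt_{window}"] = ppt
        feats[f"sdi_{window}"] = s
        feats[f"awdr_{window}"] = awdr(ppt, s)
        feats[f"gdd_{window}"] = gdd(sub["tmin_c"], sub["tmax_c"])
        feats[f"chu_{window}"] = chu(sub["tmin_c"], sub["tmax_c"])
    if soil is not None:
        for key, val in dict(soil).items():
            if key not in ("site_id", "year"):
                feats[key] = val
    return feats


def features_table(
    weather_by_site: Mapping[tuple, pd.DataFrame],
    soil_by_site: Optional[Mapping[tuple, Mapping]] = None,
) -> pd.DataFrame:
    """Stack per-site-year feature records into one table.

    Keys are ``(site_id, year)`` tuples; the result has one row per key.
    """
    rows = []
    for key, weather in weather_by_site.items():
        soil = soil_by_site.get(key) if soil_by_site else None
        rec = build_features(weather, soil)
        rec["site_id"], rec["year"] = key
        rows.append(rec)
    df = pd.DataFrame(rows)
    lead = ["site_id", "year"]
    return df[lead + [c for c in df.columns if c not in lead]]
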