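"""Delimited-text readers/writers for trials, weather, soil and fit tables.

All tabular I/O is comma-separated UTF-8 with a header row; units are
embedded in column names (``n_rate_kg_ha``, ``yield_kg_ha``, ...). An
optional reader ingests the published three-dataset spreadsheet when a
local copy is available, mapping sheets/columns by name pattern.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fitting import NRateTrial, QPFit

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "fits_to_frame",
    "read_s1_dataset",
]

REQUIRED_TRIAL_COLUMNS = ("site_id", "year", "n_rate_kg_ha", "yield_kg_ha")


class SchemaError(ValueError):
    """A table is missing a required column or violates row constraints."""


def _frame_to_trials(df: pd.DataFrame, source: str = "") -> list[NRateTrial]:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{source or 'trial table'}: missing required column(s) {missing}"
        )
    bad = df.index[(df["n_rate_kg_ha"] < 0) | (df["yield_kg_ha"] < 0)]
    if len(bad) > 0:
        lines = [int(i) + 2 for i in bad]  # +2: header row + 1-based lines
        raise SchemaError(
            f"{source or 'trial table'}: negative rate/yield on line(s) {lines}"
        )
    extra = [c for c in df.columns if c not in REQUIRED_TRIAL_COLUMNS + ("dataset",)]
    key_cols = ["site_id", "year", "n_rate_kg_ha"]
    dup_mask = df.duplicated(key_cols, keep=False)
    if dup_mask.any():
        n_rep = int(dup_mask.sum())
        warnings.warn(
            f"{source or 'trial table'}: {n_rep} replicate rows for duplicated "
            "(site, year, rate); averaging yields per design point",
            stacklevel=2,
        )
    agg = {"yield_kg_ha": "mean"}
    for c in extra:
        agg[c] = "first"
    if "dataset" in df.columns:
        agg["dataset"] = "first"
    collapsed = df.groupby(key_cols, as_index=False, sort=True).agg(agg)
    trials = []
    for (site, year), grp in collapsed.groupby(["site_id", "year"], sort=True):
        attrs = {c: grp[c].iloc[0] for c in extra}
        trials.append(
            NRateTrial(
                site_id=str(site),
                year=int(year),
                n_rates=grp["n_rate_kg_ha"].to_numpy(dtype=float),
                yields=grp["yield_kg_ha"].to_numpy(dtype=float),
                dataset=str(grp["dataset"].iloc[0]) if "dataset" in grp else "",
                attrs=attrs,
            )
        )
    return trials


def read_trials(path) -> list[NRateTrial]:
    """Read N-rate trials from a CSV with the documented header contract.

    Rows with negative rates or yields are rejected with their line
    numbers; duplicated (site, year, rate) rows are treated as replicates
    and averaged into one design point with a warning. Extra columns are
    preserved as per-trial attributes.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _frame_to_trials(df, source=str(path))


def trials_to_frame(trials: Iterable[NRateTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for n, y in zip(t.n_rates, t.yields):
            rows.append(
                {
                    "site_id": t.site_id,
                    "year": t.year,
                    "n_rate_kg_ha": n,
                    "yield_kg_ha": y,
                    "dataset": t.dataset,
                }
            )
    return pd.DataFrame(rows)


def write_trials(trials: Iterable[NRateTrial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def fits_to_frame(fits: Iterable[QPFit]) -> pd.DataFrame:
    """One row per fitted site-year: coefficients, diagnostics, screens."""
    rows = []
    for f in fits:
        row = {
            "site_id": f.site_id,
            "year": f.year,
            "dataset": f.dataset,
            "a": f.a,
            "b": f.b,
            "c": f.c,
            "x0": f.x0,
            "plateau_yield": f.plateau_yield,
            "r2": f.r2,
            "f_pvalue": f.f_pvalue,
            "max_rate_applied": f.max_rate_applied,
        }
        if f.screens is not None:
            row.update(
                {
                    "screen_f": f.screens.f_significant,
                    "screen_r2": f.screens.r2_ok,
                    "screen_join": f.screens.join_below_max,
                    "passed_screens": f.screens.passed,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


_S1_PATTERNS = {
    "site_id": re.compile(r"site|location|field|id", re.I),
    "year": re.compile(r"year", re.I),
    "n_rate_kg_ha": re.compile(r"n[_ ]?rate|nrate|nitrogen|n[_ ]?kg|fert", re.I),
    "yield_kg_ha": re.compile(r"yield|grain", re.I),
}

_DATASET_LABELS = ("NA", "NE", "MO")


def _map_columns(df: pd.DataFrame, sheet: str) -> pd.DataFrame:
    mapping = {}
    for target, pat in _S1_PATTERNS.items():
        matches = [c for c in df.columns if pat.search(str(c))]
        if not matches:
            raise SchemaError(
                f"sheet {sheet!r}: no column matching pattern for {target!r}; "
                f"columns present: {list(df.columns)}"
            )
        mapping[matches[0]] = target
    out = df.rename(columns=mapping)[list(_S1_PATTERNS)]
    return out


def read_s1_dataset(path) -> dict[str, list[NRateTrial]]:
    """Read the published three-dataset spreadsheet, grouped by label.

    The sheet layout is mapped by column-name patterns (site, year, N
    rate, yield); a sheet or column that cannot be mapped raises a
    loud :class:`SchemaError`. Dataset labels (NA/NE/MO) are taken from
    sheet names or a ``dataset`` column. An absent file raises
    ``FileNotFoundError`` — the pipeline treats that as a notice and
    proceeds in synthetic-only mode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: spreadsheet not found; proceed in synthetic-only mode"
        )
    sheets = pd.read_excel(path, sheet_name=None)
    grouped: dict[str, list[NRateTrial]] = {}
    for sheet, df in sheets.items():
        if df.empty:
            continue
        label = next(
            (lab for lab in _DATASET_LABELS if lab.lower() in str(sheet).lower()),
            None,
        )
        if label is None and "dataset" in {str(c).lower() for c in df.columns}:
            ds_col = next(c for c in df.columns if str(c).lower() == "dataset")
            for lab, sub in df.groupby(ds_col):
                mapped = _map_columns(sub.drop(columns=[ds_col]), sheet)
                mapped["dataset"] = str(lab)
                grouped.setdefault(str(lab), []).extend(
                    _frame_to_trials(mapped, source=f"{path}:{sheet}")
                )
            continue
        if label is None:
            raise SchemaError(
                f"sheet {sheet!r}: cannot infer dataset label (expected one of "
                f"{_DATASET_LABELS} in the sheet name or a 'dataset' column)"
            )
        mapped = _map_columns(df, sheet)
        mapped["dataset"] = label
        grouped.setdefault(label, []).extend(
            _frame_to_trials(mapped, source=f"{path}:{sheet}")
        )
    return grouped
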