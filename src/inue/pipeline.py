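"""End-to-end pipeline: simulate/ingest -> fit -> screen -> NUE -> steps ->
features -> classify, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import CVProtocol, label_slopes, run_protocol
from .economics import (
    GRAIN_N_COEF,
    EconomicsError,
    PriceSet,
    dataset_summary,
    eonr,
    initial_inue,
    nue_profile,
    step_summary,
)
from .fitting import DEFAULT_ALPHA, DEFAULT_R2_MIN, FitError, fit_quadratic_plateau, screen_fit
from .io import fits_to_frame, read_s1_dataset, read_trials, write_trials
from .synthetic import SyntheticSiteConfig, generate_soil_attrs, generate_trials, generate_weather
from .weather import features_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic or file-driven run."""

    out_dir: Path
    seed: int = 0
    n_sites: int = 60
    weather_profile: str = "even"
    noise_sd: float = 300.0
    covariate_effect: float = 0.8
    trials_path: Optional[Path] = None
    s1_dataset_path: Optional[Path] = None
    prices: PriceSet = field(default_factory=PriceSet)
    grain_n_coef: float = GRAIN_N_COEF
    alpha: float = DEFAULT_ALPHA
    r2_min: float = DEFAULT_R2_MIN
    steps: Sequence[float] = tuple(range(0, 260, 20))
    classifier_models: Sequence[str] = ("forest", "tree")
    n_estimators: int = 300
    param_grids: Optional[dict] = None  # per-model tuning-grid override

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        steps = list(self.steps)
        if steps != sorted(steps) or steps[0] != 0:
            raise ValueError("steps must increase strictly from 0")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FileNotFoundError:
                raise
            except Exception as exc:  # noqa: BLE001 - aggregate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all tables plus a run manifest.

    Returns the bundle of in-memory tables keyed by stage name. Raises
    :class:`PipelineError` naming the failing stage otherwise; an absent
    optional spreadsheet is a notice, not an error.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "prices"
        },
        "prices": dataclasses.asdict(config.prices),
        "versions": {
            "inue": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    bundle: dict = {}

    # ingest or simulate -------------------------------------------------
    synthetic_mode = True
    weather_by_site = None
    soil_by_site = None
    if config.s1_dataset_path is not None:
        try:
            grouped = read_s1_dataset(config.s1_dataset_path)
            trials = [t for ts in grouped.values() for t in ts]
            synthetic_mode = False
            manifest["stages"]["ingest"] = {
                "mode": "s1_dataset",
                "site_years_per_dataset": {k: len(v) for k, v in grouped.items()},
            }
        except FileNotFoundError:
            log.warning(
                "%s not found: proceeding in synthetic-only mode",
                config.s1_dataset_path,
            )
            manifest["stages"]["ingest"] = {"mode": "synthetic (spreadsheet absent)"}
    if synthetic_mode and config.trials_path is not None:
        trials = _read_stage(config.trials_path)
        synthetic_mode = False
        manifest["stages"]["ingest"] = {"mode": "trials_csv", "n_trials": len(trials)}
    if synthetic_mode:
        syn = SyntheticSiteConfig(
            n_sites=config.n_sites,
            seed=config.seed,
            weather_profile=config.weather_profile,
            noise_sd=config.noise_sd,
            covariate_effect=config.covariate_effect,
        )
        trials, truth = _simulate(syn)
        truth.to_csv(out / "truth.csv", index=False)
        weather_by_site = {
            (t.site_id, t.year): generate_weather(syn, t.site_id) for t in trials
        }
        soil_by_site = {
            (t.site_id, t.year): generate_soil_attrs(syn, t.site_id) for t in trials
        }
        pd.concat(weather_by_site.values(), ignore_index=True).to_csv(
            out / "weather.csv", index=False
        )
        pd.DataFrame(list(soil_by_site.values())).to_csv(out / "soil.csv", index=False)
        manifest["stages"]["simulate"] = {"n_sites": len(trials), "seed": config.seed}
    write_trials(trials, out / "trials.csv")
    bundle["trials"] = trials

    # fit + screen -------------------------------------------------------
    fits, fit_failures = [], 0
    for t in trials:
        try:
            f = fit_quadratic_plateau(t)
        except FitError as exc:
            log.warning("fit failed for %s/%s: %s", t.site_id, t.year, exc)
            fit_failures += 1
            continue
        screen_fit(f, alpha=config.alpha, r2_min=config.r2_min)
        fits.append(f)
    fit_table = fits_to_frame(fits)
    fit_table.to_csv(out / "fits.csv", index=False)
    screened = [f for f in fits if f.passed_screens]
    manifest["stages"]["fit"] = {
        "n_trials": len(trials),
        "fit_failures": fit_failures,
        "screened_out": {
            "f_test": int(sum(not f.screens.f_significant for f in fits)),
            "r2": int(sum(not f.screens.r2_ok for f in fits)),
            "join_point": int(sum(not f.screens.join_below_max for f in fits)),
        },
        "n_passed": len(screened),
    }
    bundle["fits"] = fit_table

    # NUE profiles -------------------------------------------------------
    nue_rows = []
    for f in screened:
        try:
            prof = nue_profile(f, config.prices, config.grain_n_coef)
        except EconomicsError as exc:  # e.g. EONR below 1 kg/ha
            log.warning("skip %s/%s: %s", f.site_id, f.year, exc)
            continue
        nue_rows.append(
            {
                "site_id": f.site_id,
                "year": f.year,
                "dataset": f.dataset,
                "eonr_kg_ha": prof.eonr,
                "initial_inue_pct": 100.0 * prof.initial_inue,
                "terminal_inue_pct": 100.0 * prof.terminal_inue,
                "slope_grain_n_pct_per_kg": prof.slope_grain_n_pct,
                "avg_nue_at_eonr_pct": 100.0 * prof.avg_nue[-1],
            }
        )
    nue_table = pd.DataFrame(nue_rows)
    nue_table.to_csv(out / "nue.csv", index=False)
    ds_table = dataset_summary(screened, config.prices)
    ds_table.to_csv(out / "dataset_summary.csv", index=False)
    manifest["stages"]["nue"] = {"n_profiles": len(nue_table)}
    bundle["nue"] = nue_table
    bundle["dataset_summary"] = ds_table

    # forgone-profit steps -----------------------------------------------
    per_site, summary = step_summary(
        screened, config.prices, config.steps, config.grain_n_coef
    )
    per_site.to_csv(out / "steps.csv", index=False)
    summary.to_csv(out / "step_summary.csv", index=False)
    manifest["stages"]["steps"] = {"n_rows": len(per_site), "steps": list(config.steps)}
    bundle["steps"] = per_site
    bundle["step_summary"] = summary

    # weather features + classification ----------------------------------
    if weather_by_site is not None:
        feats = features_table(weather_by_site, soil_by_site)
        feats.to_csv(out / "features.csv", index=False)
        bundle["features"] = feats
        manifest["stages"]["features"] = {"n_rows": len(feats)}

        merged = feats.merge(
            nue_table[["site_id", "year", "slope_grain_n_pct_per_kg"]],
            on=["site_id", "year"],
            how="inner",
        )
        labels = label_slopes(
            pd.Series(
                merged["slope_grain_n_pct_per_kg"].to_numpy(), index=merged.index
            )
        )
        X = merged.drop(columns=["site_id", "year", "slope_grain_n_pct_per_kg"])
        protocol = CVProtocol(seed=config.seed, n_estimators=config.n_estimators)
        class_report = {}
        for model in config.classifier_models:
            grid = (config.param_grids or {}).get(model)
            res = run_protocol(X, labels.labels, protocol, model=model, param_grid=grid)
            class_report[model] = {
                "accuracy": res.accuracy,
                "cv_mean_accuracy": res.cv_mean_accuracy,
                "best_params": {k: str(v) for k, v in res.best_params.items()},
                "top_features": res.importances.head(10).round(4).to_dict(),
            }
            res.importances.rename("gini_importance").to_csv(
                out / f"importance_{model}.csv"
            )
            if res.rules:
                (out / "tree_rules.txt").write_text(res.rules)
        (out / "classification.json").write_text(json.dumps(class_report, indent=2))
        manifest["stages"]["classify"] = {
            "n_labelled": len(merged),
            "threshold_magnitude": labels.threshold_magnitude,
            "models": list(config.classifier_models),
        }
        bundle["classification"] = class_report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


_read_stage = _stage("read_trials")(read_trials)
_simulate = _stage("simulate")(generate_trials)
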