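"""EONR, iNUE endpoints and forgone-profit step distributions.

Writes results/nue.csv (per-site EONR and iNUE endpoints),
results/dataset_summary.csv and results/step_summary.csv ($20/ha steps),
and prints the headline efficiencies.
"""

import numpy as np

from common import PRICES, RESULTS, STUDY, ensure_dirs
from inue import (
    eonr,
    fit_quadratic_plateau,
    dataset_summary,
    nue_profile,
    screen_fit,
    step_summary,
    terminal_inue,
    rate_of_decrease,
)
from inue.economics import EconomicsError
from inue.synthetic import generate_trials

import pandas as pd


def main() -> None:
    ensure_dirs()
    trials, _ = generate_trials(STUDY)
    screened = []
    for trial in trials:
        fit = fit_quadratic_plateau(trial)
        if screen_fit(fit).passed:
            screened.append(fit)

    rows = []
    for fit in screened:
        try:
            prof = nue_profile(fit, PRICES)
        except EconomicsError:  # EONR below 1 kg/ha: nothing to profile
            continue
        rows.append(
            {
                "site_id": fit.site_id,
                "year": fit.year,
                "eonr_kg_ha": prof.eonr,
                "initial_inue_pct": 100 * prof.initial_inue,
                "terminal_inue_pct": 100 * prof.terminal_inue,
                "slope_grain_n_pct_per_kg": prof.slope_grain_n_pct,
                "avg_nue_at_eonr_pct": 100 * prof.avg_nue[-1],
            }
        )
    nue = pd.DataFrame(rows)
    nue.to_csv(RESULTS / "nue.csv", index=False)

    ds = dataset_summary(screened, PRICES)
    ds.to_csv(RESULTS / "dataset_summary.csv", index=False)

    _, summary = step_summary(screened, PRICES, steps=tuple(range(0, 260, 20)))
    summary.to_csv(RESULTS / "step_summary.csv", index=False)

    term = 100 * terminal_inue(PRICES)
    print(f"{len(screened)} screened site-years")
    print(f"EONR: mean {nue['eonr_kg_ha'].mean():.0f} kg N/ha, "
          f"range {nue['eonr_kg_ha'].min():.0f}-{nue['eonr_kg_ha'].max():.0f}")
    print(f"initial iNUE: mean {nue['initial_inue_pct'].mean():.0f}%")
    print(f"terminal iNUE at EONR: {term:.1f}% at every site (set by prices)")
    mean_rate = rate_of_decrease(
        nue["initial_inue_pct"].mean() / 100, term / 100, nue["eonr_kg_ha"].mean()
    )
    print(f"endpoint rate of iNUE decrease: {mean_rate:.2f} %/kg N")
    print(f"average NUE at EONR: mean {nue['avg_nue_at_eonr_pct'].mean():.0f}%")

    inue_steps = summary[summary["variable"] == "inue_pct"].set_index("step_usd_ha")
    nue_steps = summary[summary["variable"] == "avg_nue_pct"].set_index("step_usd_ha")
    saved = summary[summary["variable"] == "n_saved_kg_ha"].set_index("step_usd_ha")
    for s in (20, 120, 240):
        print(
            f"forgone profit ${s}/ha: mean iNUE {inue_steps.loc[s, 'mean']:.1f}%, "
            f"mean avg NUE {nue_steps.loc[s, 'mean']:.0f}%, "
            f"N saved {saved.loc[s, 'mean']:.0f} kg/ha "
            f"({inue_steps.loc[s, 'n_sites']:.0f} sites in range)"
        )
    print(f"-> {RESULTS / 'nue.csv'}, dataset_summary.csv, step_summary.csv")


if __name__ == "__main__":
    main()
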