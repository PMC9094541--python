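"""Generate the synthetic study ensemble: trials, weather, soil.

Writes the bulky per-row tables under scratch/analysis/ and prints the
ensemble's structure. Every downstream script regenerates the same
ensemble from the shared seed, so this script is informational.
"""

import pandas as pd

from common import SCRATCH, STUDY, ensure_dirs
from inue.io import write_trials
from inue.synthetic import generate_soil_attrs, generate_trials, generate_weather


def main() -> None:
    ensure_dirs()
    trials, truth = generate_trials(STUDY)
    write_trials(trials, SCRATCH / "trials.csv")
    truth.to_csv(SCRATCH / "truth.csv", index=False)
    weather = pd.concat(
        [generate_weather(STUDY, t.site_id) for t in trials], ignore_index=True
    )
    weather.to_csv(SCRATCH / "weather.csv", index=False)
    soil = pd.DataFrame([generate_soil_attrs(STUDY, t.site_id) for t in trials])
    soil.to_csv(SCRATCH / "soil.csv", index=False)

    print(f"simulated {len(trials)} site-years "
          f"({len(trials[0].n_rates)} plots each: 6 N rates x 4 reps)")
    print(f"true EONR (kg N/ha) over the ensemble: "
          f"mean {((truth['b'] - 5.6) / (2 * truth['a'].abs())).mean():.0f}, "
          f"range {((truth['b'] - 5.6) / (2 * truth['a'].abs())).min():.0f}-"
          f"{((truth['b'] - 5.6) / (2 * truth['a'].abs())).max():.0f}")
    print(f"texture classes: {truth['texture_class'].value_counts().to_dict()}")
    print(f"tables under {SCRATCH}")


if __name__ == "__main__":
    main()
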