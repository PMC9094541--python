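"""Derive windowed weather features plus soil covariates per site-year.

Writes results/features.csv (20 weather features + soil/management per
site-year) and prints the feature ranges per window.
"""

from common import RESULTS, STUDY, ensure_dirs
from inue.synthetic import generate_soil_attrs, generate_trials, generate_weather
from inue.weather import WINDOWS, features_table


def main() -> None:
    ensure_dirs()
    trials, _ = generate_trials(STUDY)
    weather = {(t.site_id, t.year): generate_weather(STUDY, t.site_id) for t in trials}
    soil = {(t.site_id, t.year): generate_soil_attrs(STUDY, t.site_id) for t in trials}
    feats = features_table(weather, soil)
    feats.to_csv(RESULTS / "features.csv", index=False, float_format="%.3f")

    print(f"features for {len(feats)} site-years "
          f"({5 * len(WINDOWS)} weather features + soil/management)")
    for window in WINDOWS:
        ppt = feats[f"ppt_{window}"]
        sdi = feats[f"sdi_{window}"]
        gdd = feats[f"gdd_{window}"]
        print(f"  {window:13s} PPT {ppt.mean():4.0f} mm, SDI {sdi.mean():.2f}, "
              f"GDD {gdd.mean():4.0f} C-days")
    print(f"-> {RESULTS / 'features.csv'}")


if __name__ == "__main__":
    main()
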