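"""Classify High/Low iNUE decline from weather and soil covariates.

Labels each screened site-year's per-kg grain-N slope (2 a k, percentage
points per kg N) against the ensemble median, trains a tuned random
forest and a recursive-partitioning tree (60/40 split, 10-fold x 5-repeat
CV), and reports held-out accuracy, Gini importance rankings and the
tree's decision rules. Also writes the pairwise coefficient/EONR
relationships behind the response-term analysis.
"""

import json

import pandas as pd

from common import PRICES, RESULTS, STUDY, ensure_dirs
from inue import (
    CVProtocol,
    coefficient_relationships,
    eonr,
    fit_quadratic_plateau,
    label_slopes,
    run_protocol,
    screen_fit,
)
from inue.io import fits_to_frame
from inue.synthetic import generate_soil_attrs, generate_trials, generate_weather
from inue.weather import features_table


def main() -> None:
    ensure_dirs()
    trials, _ = generate_trials(STUDY)
    screened = []
    for trial in trials:
        fit = fit_quadratic_plateau(trial)
        if screen_fit(fit).passed:
            screened.append(fit)

    fit_df = fits_to_frame(screened)
    fit_df["eonr"] = [eonr(f, PRICES) for f in screened]
    rel = coefficient_relationships(fit_df)
    rel.to_csv(RESULTS / "coefficient_relationships.csv", index=False)
    r2 = rel.set_index(["var1", "var2"])["r2"]
    print(f"coefficient relationships: r2(a,b) = {r2[('a', 'b')]:.2f}, "
          f"r2(a,EONR) = {r2[('a', 'eonr')]:.2f}")

    keys = [(f.site_id, f.year) for f in screened]
    weather = {k: generate_weather(STUDY, k[0]) for k in keys}
    soil = {k: generate_soil_attrs(STUDY, k[0]) for k in keys}
    feats = features_table(weather, soil)

    slopes = pd.Series(
        [200.0 * f.a * 0.0115 for f in screened], index=range(len(screened))
    )
    labels = label_slopes(slopes)
    print(f"median slope magnitude (threshold): "
          f"{labels.threshold_magnitude:.3f} %/kg N; "
          f"{(labels.labels == 'High').sum()} High / "
          f"{(labels.labels == 'Low').sum()} Low")

    X = feats.drop(columns=["site_id", "year"])
    report = {}
    for model in ("forest", "tree"):
        res = run_protocol(X, labels.labels, CVProtocol(seed=STUDY.seed), model=model)
        report[model] = {
            "held_out_accuracy": res.accuracy,
            "cv_mean_accuracy": res.cv_mean_accuracy,
            "best_params": {k: str(v) for k, v in res.best_params.items()},
            "top_features": res.importances.head(8).round(4).to_dict(),
        }
        res.importances.to_csv(RESULTS / f"importance_{model}.csv")
        print(f"{model}: held-out accuracy {res.accuracy:.2f} "
              f"(CV mean {res.cv_mean_accuracy:.2f}); "
              f"top features: {', '.join(res.importances.index[:3])}")
        if res.rules:
            (RESULTS / "tree_rules.txt").write_text(res.rules)
    (RESULTS / "classification.json").write_text(json.dumps(report, indent=2))
    print(f"-> {RESULTS / 'classification.json'}, importance_*.csv, tree_rules.txt")


if __name__ == "__main__":
    main()
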