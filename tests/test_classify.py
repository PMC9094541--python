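"""Slope labelling, train/tune/validate protocol, coefficient relationships."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import RepeatedKFold

from inue import CVProtocol, coefficient_relationships, label_slopes, run_protocol
from inue.synthetic import SyntheticSiteConfig, generate_soil_attrs, generate_trials, generate_weather
from inue.weather import features_table

from conftest import make_fit

LIGHT = {"max_features": ["sqrt"]}  # single-point grid keeps CV accounting


def planted_features(n_sites=120, seed=9):
    cfg = SyntheticSiteConfig(n_sites=n_sites, seed=seed)
    trials, _ = generate_trials(cfg)
    wx = {(t.site_id, t.year): generate_weather(cfg, t.site_id) for t in trials}
    soil = {(t.site_id, t.year): generate_soil_attrs(cfg, t.site_id) for t in trials}
    feats = features_table(wx, soil)
    return feats.drop(columns=["site_id", "year"])


class TestLabelSlopes:
    def test_median_split_example(self):
        s = pd.Series([-0.4, -0.5, -0.7, -0.8])
        labels = label_slopes(s, threshold=0.6)
        assert list(labels.labels) == ["Low", "Low", "High", "High"]

    def test_tie_goes_to_low(self):
        labels = label_slopes(pd.Series([-0.608, -0.9]), threshold=-0.608)
        assert list(labels.labels) == ["Low", "High"]
        assert labels.threshold == -0.608  # signed convention stored

    def test_own_median_balances_classes(self):
        rng = np.random.default_rng(0)
        for n in (20, 21, 50):
            s = pd.Series(-rng.uniform(0.2, 1.2, n))
            counts = label_slopes(s).table["label"].value_counts()
            assert abs(counts.get("High", 0) - counts.get("Low", 0)) <= 1

    def test_constant_slopes_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            label_slopes(pd.Series([-0.5, -0.5, -0.5]))

    def test_centered_threshold_roughly_balances(self):
        rng = np.random.default_rng(1)
        s = pd.Series(-rng.normal(0.608, 0.15, 500))
        frac_high = (label_slopes(s, threshold=0.608).labels == "High").mean()
        assert 0.4 < frac_high < 0.6


class TestProtocol:
    def test_fold_accounting(self):
        protocol = CVProtocol(seed=3)
        assert protocol.n_tuning_folds == 50
        cv = RepeatedKFold(n_splits=10, n_repeats=5, random_state=3)
        n = 40
        counts = np.zeros(n, dtype=int)
        splits = list(cv.split(np.zeros((n, 1))))
        assert len(splits) == 50
        for _, test_idx in splits:
            counts[test_idx] += 1
        assert np.all(counts == 5)  # each observation tests in one fold per repeat

    def test_planted_signal_recovered(self):
        X = planted_features(seed=9)
        y = np.where(
            X["sdi_establishment"] > X["sdi_establishment"].median(), "High", "Low"
        )
        res = run_protocol(
            X,
            pd.Series(y),
            CVProtocol(seed=1, n_estimators=100),
            model="forest",
            param_grid=LIGHT,
        )
        assert res.accuracy >= 0.9
        assert res.importances.index[0] == "sdi_establishment"
        assert res.n_tuning_folds == 50

    def test_permuted_labels_give_chance_accuracy(self):
        X = planted_features(seed=10)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.permutation(["High", "Low"] * (len(X) // 2)))
        res = run_protocol(
            X, y, CVProtocol(seed=2, n_estimators=100), model="forest",
            param_grid=LIGHT,
        )
        assert 0.25 < res.accuracy < 0.75  # chance level within binomial noise

    def test_same_seed_reproducible(self):
        X = planted_features(n_sites=60, seed=11)
        y = np.where(X["ppt_season"] > X["ppt_season"].median(), "High", "Low")
        kwargs = dict(
            protocol=CVProtocol(seed=5, n_estimators=50),
            model="forest",
            param_grid=LIGHT,
        )
        r1 = run_protocol(X, pd.Series(y), **kwargs)
        r2 = run_protocol(X, pd.Series(y), **kwargs)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.train_index, r2.train_index)
        assert r1.importances.equals(r2.importances)

    def test_tree_emits_readable_rules(self):
        X = planted_features(n_sites=60, seed=12)
        y = np.where(X["ppt_season"] > X["ppt_season"].median(), "High", "Low")
        res = run_protocol(
            X, pd.Series(y), CVProtocol(seed=1), model="tree",
            param_grid={"max_depth": [2, 3]},
        )
        assert res.rules and "class:" in res.rules

    def test_single_class_training_split_advises(self):
        X = planted_features(n_sites=20, seed=13)
        y = pd.Series(["Low"] * len(X))  # degenerate: one class only
        with pytest.raises(ValueError, match="re-seed|stratification"):
            run_protocol(X, y, CVProtocol(seed=0), model="tree")


class TestCoefficientRelationships:
    def test_exact_collinearity_when_join_point_fixed(self):
        rows = []
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.uniform(-0.2, -0.08)
            rows.append({"a": a, "b": -2 * a * 150.0, "c": rng.uniform(4e3, 9e3)})
        df = pd.DataFrame(rows)
        df["eonr"] = (5.6 - df["b"]) / (2 * df["a"])
        table = coefficient_relationships(df)
        r2_ab = table.set_index(["var1", "var2"]).loc[("a", "b"), "r2"]
        assert r2_ab == pytest.approx(1.0)

    def test_independent_coefficients_uncorrelated(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "a": rng.uniform(-0.2, -0.08, 500),
                "c": rng.uniform(4e3, 9e3, 500),
            }
        )
        table = coefficient_relationships(df)
        r2_ac = table.set_index(["var1", "var2"]).loc[("a", "c"), "r2"]
        assert r2_ac < 0.02

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        df["b"] += 0.5 * df["a"]
        t1 = coefficient_relationships(df)
        df2 = pd.DataFrame({"a": 3 * df["a"] + 7, "b": -2 * df["b"] + 1})
        t2 = coefficient_relationships(df2)
        assert t1["r2"].iloc[0] == pytest.approx(t2["r2"].iloc[0])

    def test_too_few_fits_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            coefficient_relationships(pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}))
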