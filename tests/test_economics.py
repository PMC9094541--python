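"""EONR, incremental/average NUE, forgone profit and derived summaries."""

import numpy as np
import pandas as pd
import pytest

from inue import (
    PriceSet,
    avg_nue,
    dataset_summary,
    eonr,
    forgone_profit,
    grain_n_sensitivity,
    initial_inue,
    inue,
    invert_forgone,
    nue_profile,
    partial_profit,
    rate_of_decrease,
    step_summary,
    terminal_inue,
    weighted_mean,
)
from inue.economics import EconomicsError, PlateauWarning, forgone_profit_ratio

from conftest import make_fit


def profit_grid_argmax(fit, prices, resolution=0.01):
    """Brute-force profit maximization oracle at fine N resolution."""
    n = np.arange(0.0, fit.x0 + resolution, resolution)
    pp = prices.price_grain * fit.predict(n) - prices.price_n * n
    return n[np.argmax(pp)]


class TestEonr:
    def test_closed_form_matches_profit_grid(self, example_fit):
        opt = eonr(example_fit, PriceSet(ratio=5.6))
        assert opt == pytest.approx(131.3333, abs=1e-3)
        # raw-price mode must agree with the brute-force profit grid
        raw = PriceSet.from_prices(0.158, 0.88)
        opt_raw = eonr(example_fit, raw)
        assert opt_raw == pytest.approx(profit_grid_argmax(example_fit, raw), abs=0.01)

    def test_b_equal_ratio_gives_zero(self):
        fit = make_fit(b=5.6)
        with pytest.warns(PlateauWarning, match="never profitable"):
            assert eonr(fit, PriceSet(ratio=5.6)) == 0.0

    def test_convex_response_rejected(self):
        fit = make_fit()
        fit.a = 0.05
        with pytest.raises(EconomicsError, match="a < 0"):
            eonr(fit)

    def test_first_order_optimality_at_raw_price_optimum(self, example_fit):
        raw = PriceSet.from_prices(0.158, 0.88)
        opt = eonr(example_fit, raw)
        p_opt = partial_profit(example_fit, opt, raw)
        assert p_opt >= partial_profit(example_fit, opt - 1.0, raw)
        assert p_opt >= partial_profit(example_fit, opt + 1.0, raw)

    def test_eonr_below_join_point(self, example_fit, prices):
        assert 0 < eonr(example_fit, prices) < example_fit.x0


class TestInue:
    def test_terminal_value_set_by_prices_only(self, example_fit, prices):
        opt = eonr(example_fit, prices)
        assert inue(example_fit, opt) == pytest.approx(5.6 * 0.0115, abs=1e-12)
        other = make_fit(a=-0.11, b=38.0, c=7600.0)
        assert inue(other, eonr(other, prices)) == pytest.approx(
            terminal_inue(prices), abs=1e-12
        )

    def test_unfertilized_marginal_efficiency(self, example_fit):
        assert inue(example_fit, 0.0) == pytest.approx(0.5175)

    def test_zero_at_join_point_and_beyond(self, example_fit):
        assert inue(example_fit, example_fit.x0) == pytest.approx(0.0, abs=1e-12)
        with pytest.warns(PlateauWarning):
            assert inue(example_fit, example_fit.x0 + 10) == 0.0

    @pytest.mark.parametrize(
        "n_price_factor,expected_pct", [(1.0, 6.4), (0.6, 3.8), (1.4, 9.0)]
    )
    def test_terminal_inue_under_price_changes(self, n_price_factor, expected_pct):
        prices = PriceSet.from_prices(0.158, 0.88 * n_price_factor)
        assert round(100 * terminal_inue(prices), 1) == expected_pct


class TestAvgNue:
    def test_quadratic_branch_value(self, example_fit):
        # (b + a*N) * k at N = 100
        assert avg_nue(example_fit, 100.0) == pytest.approx(0.345)

    def test_small_rate_limit_equals_initial_inue(self, example_fit):
        assert avg_nue(example_fit, 1e-6) == pytest.approx(
            inue(example_fit, 0.0), rel=1e-6
        )
        assert initial_inue(example_fit) == pytest.approx(inue(example_fit, 1.0))

    def test_undefined_at_zero(self, example_fit):
        with pytest.raises(EconomicsError, match="undefined at N = 0"):
            avg_nue(example_fit, 0.0)

    def test_proportional_in_grain_n_coefficient(self, example_fit):
        assert avg_nue(example_fit, 80.0, 0.00575) == pytest.approx(
            avg_nue(example_fit, 80.0, 0.0115) / 2
        )

    def test_equals_mean_of_per_increment_inue(self, example_fit):
        """Average NUE is the mean of the per-kg increments' iNUE."""
        n = 120
        midpoints = np.arange(n) + 0.5
        increments = [inue(example_fit, m) for m in midpoints]
        assert 100 * avg_nue(example_fit, float(n)) == pytest.approx(
            100 * np.mean(increments), abs=0.05
        )


class TestGrainNSensitivity:
    @pytest.mark.parametrize(
        "base,coef_new,expected",
        [(43.8, 0.010, 38.1), (45.4, 0.012, 47.4), (42.5, 0.0115, 42.5)],
    )
    def test_published_rescalings(self, base, coef_new, expected):
        assert round(grain_n_sensitivity(base, 0.0115, coef_new), 1) == expected

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(ValueError, match="coef_new"):
            grain_n_sensitivity(43.8, 0.0115, 0.2)


class TestProfit:
    def test_no_fertilizer_profit_is_grain_revenue(self, example_fit, prices):
        assert partial_profit(example_fit, 0.0, prices) == pytest.approx(
            0.158 * 5000.0
        )

    def test_forgone_zero_at_eonr_and_decreasing(self, example_fit, prices):
        opt = eonr(example_fit, prices)
        assert forgone_profit(example_fit, opt, prices) == pytest.approx(0.0, abs=1e-9)
        grid = np.linspace(0, opt, 40)
        vals = [forgone_profit(example_fit, n, prices) for n in grid]
        assert all(v >= -1e-9 for v in vals)
        assert all(np.diff(vals) < 0)

    def test_closed_form_identity(self, example_fit, prices):
        opt = eonr(example_fit, prices)
        pg, pn = prices.price_grain, prices.price_n
        for n in (0.0, 30.0, 77.7, 120.0):
            closed = pg * (
                example_fit.a * (opt**2 - n**2) + example_fit.b * (opt - n)
            ) - pn * (opt - n)
            assert forgone_profit(example_fit, n, prices) == pytest.approx(
                closed, abs=1e-9
            )

    def test_super_optimal_rate_rejected(self, example_fit, prices):
        with pytest.raises(EconomicsError, match="exceeds EONR"):
            forgone_profit(example_fit, 200.0, prices)

    def test_quotient_variant_is_one_at_eonr(self, example_fit, prices):
        opt = eonr(example_fit, prices)
        assert forgone_profit_ratio(example_fit, opt, prices) == pytest.approx(1.0)

    def test_joint_price_scaling_leaves_eonr_and_scales_money(self, example_fit):
        base = PriceSet.from_prices(0.158, 0.88)
        scaled = PriceSet.from_prices(0.158 * 3, 0.88 * 3)
        assert eonr(example_fit, base) == pytest.approx(eonr(example_fit, scaled))
        assert forgone_profit(example_fit, 50.0, scaled) == pytest.approx(
            3 * forgone_profit(example_fit, 50.0, base)
        )


class TestInvertForgone:
    def test_zero_step_returns_eonr(self, example_fit, prices):
        assert invert_forgone(example_fit, prices, 0.0) == pytest.approx(
            eonr(example_fit, prices)
        )

    @pytest.mark.parametrize("step", [0.5, 5.0, 20.0, 120.0, 240.0])
    def test_round_trip_within_tenth_of_cent(self, example_fit, prices, step):
        n = invert_forgone(example_fit, prices, step)
        assert forgone_profit(example_fit, n, prices) == pytest.approx(
            step, abs=0.001
        )

    def test_matches_fine_grid_oracle(self, example_fit, prices):
        opt = eonr(example_fit, prices)
        grid = np.arange(0.0, opt, 0.001)
        fg = np.array([forgone_profit(example_fit, n, prices) for n in grid])
        for step in (20.0, 60.0):
            oracle = grid[np.argmin(np.abs(fg - step))]
            assert invert_forgone(example_fit, prices, step) == pytest.approx(
                oracle, abs=0.002
            )

    def test_monotone_in_step(self, example_fit, prices):
        ns = [invert_forgone(example_fit, prices, s) for s in (20.0, 40.0, 60.0)]
        assert ns[0] > ns[1] > ns[2]

    def test_unreachable_step_reports_maximum(self, example_fit, prices):
        fmax = forgone_profit(example_fit, 0.0, prices)
        with pytest.raises(EconomicsError, match=f"{fmax:.2f}"):
            invert_forgone(example_fit, prices, fmax + 1.0)


class TestRateOfDecrease:
    @pytest.mark.parametrize(
        "initial_pct,eonr_kg,expected",
        [(82.0, 132.0, 0.57), (79.0, 147.0, 0.49)],
    )
    def test_published_endpoint_rates(self, prices, initial_pct, eonr_kg, expected):
        rate = rate_of_decrease(initial_pct / 100, terminal_inue(prices), eonr_kg)
        assert round(rate, 2) == expected

    def test_flat_profile_has_zero_rate(self):
        assert rate_of_decrease(0.064, 0.064, 130.0) == 0.0

    def test_zero_eonr_undefined(self):
        with pytest.raises(EconomicsError):
            rate_of_decrease(0.8, 0.064, 0.0)


class TestWeightedMeans:
    def test_initial_inue_weighted_mean(self):
        assert round(weighted_mean([82, 85, 79], [28, 75, 86])) == 82

    def test_eonr_span_weighted_mean(self):
        assert round(weighted_mean([110, 146, 202], [28, 75, 86])) == 166


def _screened_ensemble(n_sites=60, seed=17):
    from inue import fit_quadratic_plateau, screen_fit
    from inue.synthetic import SyntheticSiteConfig, generate_trials

    trials, _ = generate_trials(SyntheticSiteConfig(n_sites=n_sites, seed=seed))
    fits = []
    for t in trials:
        f = fit_quadratic_plateau(t)
        screen_fit(f)
        if f.passed_screens:
            fits.append(f)
    return fits


class TestStepAndDatasetSummaries:
    def test_step_zero_is_terminal_inue_with_nothing_saved(self, prices):
        fits = _screened_ensemble(n_sites=20)
        per_site, _ = step_summary(fits, prices, steps=[0.0])
        assert np.allclose(
            per_site["inue_pct"], 100 * terminal_inue(prices), atol=1e-9
        )
        assert np.allclose(per_site["n_saved_kg_ha"], 0.0, atol=1e-9)

    def test_mean_inue_increases_with_step(self, prices):
        fits = _screened_ensemble(n_sites=60)
        per_site, summary = step_summary(fits, prices, steps=[0, 20, 40, 60, 80])
        means = (
            summary[summary["variable"] == "inue_pct"]
            .sort_values("step_usd_ha")["mean"]
            .to_numpy()
        )
        assert np.all(np.diff(means) > 0)

    def test_unreachable_steps_counted_not_failed(self, prices):
        fits = _screened_ensemble(n_sites=20)
        fmax = max(forgone_profit(f, 0.0, prices) for f in fits)
        _, summary = step_summary(fits, prices, steps=[0.0, fmax + 50.0])
        excluded = summary.loc[
            summary["step_usd_ha"] == fmax + 50.0, "n_excluded"
        ].iloc[0]
        assert excluded == len(fits)

    def test_dataset_summary_weighted_means_and_opt_gap(self, prices):
        fits = _screened_ensemble(n_sites=30)
        for i, f in enumerate(fits):
            f.dataset = "G1" if i % 2 else "G2"
        table = dataset_summary(fits, prices)
        assert set(table["dataset"]) == {"G1", "G2", "weighted_mean"}
        # the agronomic optimum always sits above the economic one
        assert (table["opt_minus_eonr_mean"] > 0).all()
        w = table[table["dataset"] == "weighted_mean"].iloc[0]
        grouped = table[table["dataset"] != "weighted_mean"]
        assert w["eonr_mean"] == pytest.approx(
            np.average(grouped["eonr_mean"], weights=grouped["n_site_years"])
        )


class TestNueProfile:
    def test_profile_invariants(self, example_fit, prices):
        prof = nue_profile(example_fit, prices)
        assert np.all(np.diff(prof.inue) < 0)  # strictly decreasing
        assert prof.forgone_profit[-1] == pytest.approx(0.0, abs=0.5)
        assert np.all(np.diff(prof.forgone_profit) < 0)
        assert prof.terminal_inue == pytest.approx(terminal_inue(prices), abs=1e-3)
        assert prof.slope_grain_n == pytest.approx(2 * example_fit.a * 0.0115)
        # avg NUE on the quadratic branch: (b + a*N) * k
        n = prof.n_grid
        assert np.allclose(
            prof.avg_nue, (example_fit.b + example_fit.a * n) * 0.0115
        )
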