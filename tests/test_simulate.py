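import datetime as dt

import numpy as np
import pytest

from loopsim import ScenarioVector, ValueChainModel, default_config
from loopsim.simulate import SimulationResult


class TestConservation:
    def test_farmer_population_constant(self, baseline_run):
        total = baseline_run.config.adoption.total_farmers
        assert baseline_run.max_population_deviation < 1e-9
        loop = baseline_run.arrays["loop_farmers"]
        assert (loop >= 0).all() and (loop <= total).all()

    def test_market_mass_balance_closes_to_machine_precision(self, baseline_run):
        assert baseline_run.max_balance_residual < 1e-6

    def test_mass_balance_with_cold_storage_active(self, config):
        scen = ScenarioVector(cs_active_raw=1.0, cs_level=2.0)
        r = ValueChainModel(config, scenario=scen).simulate(3)
        assert r.max_balance_residual < 1e-6
        assert r.arrays["stored_A"].max() > 0  # storage actually used

    def test_bounded_stocks(self, baseline_run):
        a = baseline_run.arrays
        assert ((a["trust"] >= 0) & (a["trust"] <= 1)).all()
        assert ((a["pref_A"] >= 0) & (a["pref_A"] <= 100)).all()
        assert (a["demand_B"] >= 0).all()
        for key in a:
            assert np.isfinite(a[key]).all(), key


class TestStructure:
    def test_full_horizon_has_2922_half_days(self, baseline_run):
        assert baseline_run.n_half_days == 2922

    def test_afternoons_have_no_aggregation(self, baseline_run):
        a = baseline_run.arrays
        afternoons = slice(1, None, 2)
        assert np.all(a["loop_supply_A"][afternoons] == 0.0)
        assert np.all(a["loop_supply_B"][afternoons] == 0.0)

    def test_peak_rabi_capacity_anchors(self, config):
        """Baseline trader counts give ~100,000 kg/day (Market A) and
        ~20,000 kg/day (Market B) of handling capacity in peak Rabi."""
        k, d = config.market, config.demand
        cap_A = (
            k.distance_A_count * k.distance_capacity           # mornings
            + 2 * k.wholesaler_A_count * k.wholesaler_capacity
            + 2 * k.retailer_A_count * d.customers_per_retailer_A
            * d.reference_demand
        )
        cap_B = (
            2 * k.wholesaler_B_count * k.wholesaler_capacity
            + 2 * k.retailer_B_count * d.customers_per_retailer_B
            * d.reference_demand
        )
        assert cap_A == pytest.approx(100_000, rel=0.05)
        assert cap_B == pytest.approx(20_000, rel=0.10)

    def test_frame_exposes_calendar(self, short_run):
        df = short_run.frame()
        assert df["half_day"].iloc[0] == 1
        assert df["date"].iloc[0] == dt.date(2017, 10, 1)
        assert df["phase"].iloc[:2].tolist() == ["morning", "afternoon"]

    def test_summary_mentions_key_quantities(self, baseline_run):
        text = baseline_run.summary()
        assert "2922" in text and "Loop farmers" in text


class TestExtremeConditions:
    def test_zero_traders_zero_sales(self, config):
        cfg = config.copy()
        for field in ("distance_A_count", "wholesaler_A_count",
                      "retailer_A_count", "wholesaler_B_count",
                      "retailer_B_count"):
            setattr(cfg.market, field, 0.0)
        cfg.market.entry_coeff = 0.0
        r = ValueChainModel(cfg).simulate(2, end_date=dt.date(2017, 12, 31))
        assert r.arrays["market_A_sales"].sum() == 0.0
        assert r.arrays["market_B_sales"].sum() == 0.0

    def test_zero_supply_zero_sales_and_clamped_high_prices(self, config):
        cfg = config.copy()
        cfg.production.yield_rabi = 0.0
        cfg.production.yield_zaid = 0.0
        cfg.production.yield_kharif = 0.0
        r = ValueChainModel(cfg).simulate(2, end_date=dt.date(2017, 12, 31))
        assert r.arrays["market_A_sales"].sum() == 0.0
        hi = cfg.market.price_clamp_hi
        ref_hi = cfg.fixtures.price_mean * (1 + cfg.fixtures.price_amplitude)
        assert (r.arrays["price_A"] <= hi * ref_hi * 1.01).all()
        # prices sit at the scarcity clamp when nothing arrives
        mean_factor = r.arrays["price_A"].mean() / cfg.fixtures.price_mean
        assert mean_factor > 1.0


class TestScenarioSwitches:
    def test_null_scenario_equals_baseline(self, config, baseline_run):
        """An all-zero scenario vector (storage inactive) reproduces the
        do-nothing run bit for bit (common random numbers)."""
        null = ScenarioVector(0.0, 0.0, 0.0, 0.0, 0.0)
        r = ValueChainModel(config, scenario=null).simulate(1)
        for key in baseline_run.arrays:
            np.testing.assert_array_equal(r.arrays[key],
                                          baseline_run.arrays[key], err_msg=key)

    def test_same_seed_is_bit_identical(self, config):
        scen = ScenarioVector(0.1, 30.0, 0.7, 1.0, 5.0)
        a = ValueChainModel(config, scenario=scen).simulate(9)
        b = ValueChainModel(config, scenario=scen).simulate(9)
        for key in a.arrays:
            np.testing.assert_array_equal(a.arrays[key], b.arrays[key])

    def test_extension_starts_only_at_scenario_start(self, config, baseline_run):
        scen = ScenarioVector(extension_rate=0.274)
        r = ValueChainModel(config, scenario=scen).simulate(1)
        i_switch = 730  # half-days before 2018-10-01
        np.testing.assert_array_equal(
            r.arrays["loop_farmers"][:i_switch],
            baseline_run.arrays["loop_farmers"][:i_switch],
        )
        assert r.arrays["loop_farmers"][-1] > baseline_run.arrays["loop_farmers"][-1]

    def test_storage_increases_market_B_purchases(self, config, baseline_run):
        scen = ScenarioVector(cs_active_raw=1.0, cs_level=2.0)
        r = ValueChainModel(config, scenario=scen).simulate(1)
        assert (
            r.outcome_triple().cum_purchases_B
            > baseline_run.outcome_triple().cum_purchases_B
        )

    def test_supply_shock_lowers_price_and_raises_purchases(self, config):
        """Closed-loop demand check: doubling yields floods the markets,
        depressing retail prices and raising per-customer purchases."""
        cfg = config.copy()
        for f in ("yield_rabi", "yield_zaid", "yield_kharif"):
            setattr(cfg.production, f, 2 * getattr(cfg.production, f))
        end = dt.date(2017, 12, 31)
        shocked = ValueChainModel(cfg).simulate(1, end_date=end)
        normal = ValueChainModel(config).simulate(1, end_date=end)
        sl = slice(60, None)  # skip the smoothing warm-up fortnight
        assert shocked.arrays["retail_price_B"][sl].mean() < \
            normal.arrays["retail_price_B"][sl].mean()
        assert shocked.arrays["purchases_per_customer_B"][sl].sum() > \
            normal.arrays["purchases_per_customer_B"][sl].sum()

    def test_demand_growth_raises_cumulative_purchases(self, config, baseline_run):
        grown = ValueChainModel(
            config, scenario=ScenarioVector(demand_growth=10.0)
        ).simulate(1)
        assert (
            grown.outcome_triple().cum_purchases_B
            > baseline_run.outcome_triple().cum_purchases_B
        )


class TestOutcomeReduction:
    def test_outcomes_cover_scenario_horizon_only(self, baseline_run):
        o_full = baseline_run.outcome_triple(start=dt.date(2017, 10, 1))
        o_scen = baseline_run.outcome_triple()
        assert o_full.cum_purchases_B > o_scen.cum_purchases_B
        assert np.isfinite(o_scen.mean_roi)

    def test_daily_views_are_date_indexed_mornings(self, baseline_run):
        sales = baseline_run.daily_loop_sales_A()
        assert len(sales) == 178
        assert sales.index[0] == dt.date(2018, 3, 1)
        assert (sales.to_numpy() >= 0).all()
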