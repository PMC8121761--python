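import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopsim.config import MarketConfig
from loopsim.market import (
    AgeQueue,
    cold_storage_capacity,
    offered_price,
    quality_adjusted_price,
    spoilage_update,
    trader_entry_exit,
    trader_profit,
)


@pytest.fixture()
def params():
    return MarketConfig()


class TestColdStorage:
    @pytest.mark.parametrize(
        "active, level, market, expected",
        [
            (1, 3.0, "A", 75000.0),
            (1, 3.0, "B", 15000.0),
            (1, 1.0, "A", 25000.0),
            (1, 1.0, "B", 5000.0),
            (0, 3.0, "A", 0.0),
            (1, 0.0, "B", 0.0),
        ],
    )
    def test_table_mapping(self, active, level, market, expected, params):
        assert cold_storage_capacity(active, level, market, params) == expected

    def test_level_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            cold_storage_capacity(1, 3.5, "A", params)

    def test_linear_in_level(self, params):
        assert cold_storage_capacity(1, 1.5, "A", params) == pytest.approx(37500.0)


class TestPrices:
    def test_all_high_grade_full_price(self):
        assert quality_adjusted_price(10.0, 1.0) == 10.0

    def test_all_low_grade_half_price(self):
        assert quality_adjusted_price(10.0, 0.0) == 5.0

    def test_weighted_mix(self):
        assert quality_adjusted_price(10.0, 0.6) == pytest.approx(8.0)

    def test_balanced_market_prices_at_reference(self, params):
        assert offered_price(12.0, 500.0, 500.0, params) == pytest.approx(12.0)

    def test_glut_floors_at_low_clamp(self, params):
        assert offered_price(12.0, 1e9, 1.0, params) == pytest.approx(
            12.0 * params.price_clamp_lo
        )

    def test_scarcity_and_zero_availability_cap_high(self, params):
        assert offered_price(12.0, 1.0, 1e9, params) == pytest.approx(
            12.0 * params.price_clamp_hi
        )
        assert offered_price(12.0, 0.0, 100.0, params) == pytest.approx(
            12.0 * params.price_clamp_hi
        )

    def test_inelastic_anchor(self):
        p = MarketConfig(price_elasticity_eta=0.0)
        assert offered_price(12.0, 10.0, 99999.0, p) == pytest.approx(12.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_price_always_within_clamp_band(self, avail, demand):
        p = MarketConfig()
        out = offered_price(12.0, avail, demand, p)
        assert 12.0 * p.price_clamp_lo - 1e-9 <= out <= 12.0 * p.price_clamp_hi + 1e-9


class TestTraderProfit:
    def test_zero_purchases_minus_fixed_costs(self):
        assert trader_profit(0.0, 0.0, 8.0, 10.0, 500.0) == -500.0

    def test_hand_computed(self):
        assert trader_profit(1000.0, 0.0, 8.0, 10.0, 500.0) == pytest.approx(1500.0)

    def test_storage_rent_example(self, params):
        # 2000 kg stored one half-day at 0.15 Rs/kg adds 300 Rs of cost
        rent = params.storage_rent * 2000.0
        base = trader_profit(1000.0, 0.0, 8.0, 10.0, 500.0)
        with_rent = trader_profit(1000.0, 0.0, 8.0, 10.0, 500.0 + rent)
        assert base - with_rent == pytest.approx(300.0)

    def test_wastage_cannot_exceed_purchases(self):
        with pytest.raises(ValueError):
            trader_profit(10.0, 11.0, 8.0, 10.0, 0.0)


class TestEntryExit:
    def test_zero_profit_no_entries(self, params):
        assert trader_entry_exit(10.0, 0.0, params) == 10.0

    def test_entries_proportional_to_profit(self, params):
        d1 = trader_entry_exit(10.0, 1e6, params) - 10.0
        d2 = trader_entry_exit(10.0, 2e6, params) - 10.0
        assert d2 == pytest.approx(2 * d1)

    def test_persistent_losses_decay_toward_zero_never_negative(self, params):
        count = 5.0
        for _ in range(10000):
            count = trader_entry_exit(count, -1000.0, params)
        assert 0.0 <= count < 0.01

    def test_count_ceiling_respected(self, params):
        assert trader_entry_exit(10.0, 1e12, params, count_max=15.0) == 15.0


class TestSpoilage:
    def test_expiry_at_shelf_life(self):
        q = AgeQueue()
        carried, spoiled = spoilage_update(q, 100.0, shelf_life=4)
        assert (carried, spoiled) == (100.0, 0.0)
        for _ in range(3):
            carried, spoiled = spoilage_update(q, 0.0, shelf_life=4)
            assert spoiled == 0.0
        # fifth half-day: the cohort is older than the shelf life
        carried, spoiled = spoilage_update(q, 0.0, shelf_life=4)
        assert spoiled == pytest.approx(100.0)
        assert carried == 0.0

    def test_cold_storage_extends_life(self):
        q = AgeQueue()
        spoilage_update(q, 100.0, shelf_life=42)
        total_spoiled = 0.0
        for _ in range(10):
            _, s = spoilage_update(q, 0.0, shelf_life=42)
            total_spoiled += s
        assert total_spoiled == 0.0
        assert q.total == pytest.approx(100.0)

    def test_zero_unsold_is_noop(self):
        q = AgeQueue()
        assert spoilage_update(q, 0.0, 4) == (0.0, 0.0)

    def test_storage_cap_spoils_excess_oldest_first(self):
        q = AgeQueue()
        spoilage_update(q, 60.0, 42, storage_cap=1000.0)
        carried, spoiled = spoilage_update(q, 60.0, 42, storage_cap=100.0)
        assert carried == pytest.approx(100.0)
        assert spoiled == pytest.approx(20.0)
        # the remaining oldest cohort shrank first
        assert q.ages[0][0] == 2 and q.ages[0][1] == pytest.approx(40.0)

    def test_fifo_take(self):
        q = AgeQueue()
        spoilage_update(q, 30.0, 42)
        spoilage_update(q, 50.0, 42)
        taken = q.take(40.0)
        assert taken == pytest.approx(40.0)
        # oldest cohort drained first
        assert q.ages[0][1] == pytest.approx(40.0)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_mass_balance_through_queue(self, inflows):
        q = AgeQueue()
        total_in, total_spoiled = 0.0, 0.0
        for x in inflows:
            total_in += x
            _, s = spoilage_update(q, x, shelf_life=4)
            total_spoiled += s
        assert q.total + total_spoiled == pytest.approx(total_in, rel=1e-9, abs=1e-9)
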