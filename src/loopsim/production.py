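"""Marketable F&V production, land allocation and seasonal reinvestment.

Production on a half-day is the product of the number of farmers marketing
that session, their cultivable land, the share of it under F&V, the seasonal
baseline yield and a slowly growing yield multiplier fed by reinvested
profits.  Three pre-marketing outflows (own consumption — higher in
female-headed households — gifts, and pre-farmgate losses) are deducted
before anything reaches a market.

At the first morning of each season, cumulative profits are partially
reinvested: 20% into land (only above the one-tenth-katha affordability
threshold) and 10% into yield enhancement at 1% per Rs 20,000, capped at
+1.5%/year.
"""

from __future__ import annotations

import datetime as dt

from . import simclock
from .config import ProductionConfig

__all__ = [
    "seasonal_fv_base",
    "fv_land_fraction",
    "baseline_yield",
    "marketable_production",
    "non_marketing_outflows",
    "invest_in_land",
    "invest_in_yield",
]

# Mid-season anchor days (month, day) for the land-share cycle.
_ANCHORS = [
    ((12, 15), "rabi"),   # Rabi peak
    ((4, 15), "zaid"),    # Zaid shoulder
    ((8, 1), "kharif"),   # Kharif trough
]


def _day_of_cycle(date: dt.date) -> float:
    """Days since Oct 1 of the current model year (0..365)."""
    anchor = dt.date(date.year if date.month >= 10 else date.year - 1, 10, 1)
    return float((date - anchor).days)


def seasonal_fv_base(date: dt.date, params: ProductionConfig) -> float:
    """Seasonal base share of land under F&V, smoothly interpolated.

    Anchored at the Rabi peak (mid-December), the Zaid shoulder (mid-April)
    and the Kharif trough (early August); linear in between, year-periodic.
    """
    values = {
        "rabi": params.fv_fraction_rabi,
        "zaid": params.fv_fraction_zaid,
        "kharif": params.fv_fraction_kharif,
    }
    # anchor positions in days-since-Oct-1 space
    pts = sorted(
        (_day_of_cycle(dt.date(2018 if m >= 10 else 2019, m, d)), values[key])
        for (m, d), key in _ANCHORS
    )
    x = _day_of_cycle(date)
    # wrap-around linear interpolation over the 365-day cycle
    (x0, y0), (x1, y1), (x2, y2) = pts
    if x < x0:
        span = x0 + 365.0 - x2
        return y2 + (y0 - y2) * (x + 365.0 - x2) / span
    if x < x1:
        return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    if x < x2:
        return y1 + (y2 - y1) * (x - x1) / (x2 - x1)
    span = x0 + 365.0 - x2
    return y2 + (y0 - y2) * (x - x2) / span


def fv_land_fraction(
    date: dt.date,
    fv_price: float,
    staple_price: float,
    params: ProductionConfig,
) -> float:
    """Share of land under F&V: seasonal base times a relative-price modifier.

    The modifier saturates inside (1-band, 1+band) and rises with the
    F&V/staple price ratio, passing through 1 at the reference ratio; the
    final share is clamped to [0, 1].
    """
    base = seasonal_fv_base(date, params)
    band = params.price_adjustment_band
    ref = params.reference_price_ratio
    if staple_price <= 0.0:
        ratio = ref
    else:
        ratio = max(0.0, fv_price / staple_price)
    # saturating map: 0 -> 1-band, ref -> 1, inf -> 1+band
    adj = (1.0 - band) + 2.0 * band * ratio / (ratio + ref)
    return min(1.0, max(0.0, base * adj))


def baseline_yield(season: simclock.Season, params: ProductionConfig) -> float:
    """Marketable yield (kg/m2 per marketing trip) of the season's top crops."""
    return {
        "Rabi": params.yield_rabi,
        "Zaid": params.yield_zaid,
        "Kharif": params.yield_kharif,
    }[season.name]


def marketable_production(
    n_farmers: float,
    marketing_fraction: float,
    land_area_m2: float,
    fv_fraction: float,
    yield_per_m2: float,
    yield_multiplier: float = 1.0,
) -> float:
    """Gross marketable production (kg) on one half-day.

    Linear in every factor: farmers marketing this session × land × F&V share
    × seasonal yield × investment-driven multiplier.
    """
    return (
        n_farmers
        * marketing_fraction
        * land_area_m2
        * fv_fraction
        * yield_per_m2
        * yield_multiplier
    )


def non_marketing_outflows(
    production: float,
    female_fraction: float,
    params: ProductionConfig,
) -> tuple:
    """(own_consumption, given_away, pre_farmgate_loss) in kg.

    Own consumption scales with the share of female-headed households
    (who consume ~10% more F&V); all three leave before marketing.
    """
    own_rate = params.own_consumption_rate * (
        1.0 + params.female_premium * female_fraction
    )
    total_rate = own_rate + params.giveaway_rate + params.pre_farmgate_loss_rate
    if total_rate >= 1.0:
        raise ValueError(
            f"non-marketing outflow rates sum to {total_rate:.3f} >= 1"
        )
    return (
        production * own_rate,
        production * params.giveaway_rate,
        production * params.pre_farmgate_loss_rate,
    )


def invest_in_land(cumulative_profit: float, params: ProductionConfig) -> tuple:
    """(area_bought_m2, spend_rs) at a season start.

    Farmers spend 20% of cumulative profit on land only if that amount
    strictly exceeds the cost of one-tenth of a katha (Rs 7,600 at 76,000
    Rs/katha); otherwise nothing happens.
    """
    if cumulative_profit <= 0.0:
        return 0.0, 0.0
    spend = params.land_invest_rate * cumulative_profit
    if spend <= params.land_invest_threshold:
        return 0.0, 0.0
    area = spend / params.land_price_per_katha * params.katha_m2
    return area, spend


def invest_in_yield(
    cumulative_profit: float,
    annual_headroom: float,
    params: ProductionConfig,
) -> tuple:
    """(yield_multiplier_increment, spend_rs) at a season start.

    10% of cumulative profit converts at 1% yield per Rs 20,000, limited by
    the remaining +1.5%/year headroom; the unused part of the earmarked spend
    is not collected.
    """
    if cumulative_profit <= 0.0 or annual_headroom <= 0.0:
        return 0.0, 0.0
    spend = params.yield_invest_rate * cumulative_profit
    increment = spend * params.yield_gain_per_rs
    if increment > annual_headroom:
        increment = annual_headroom
        spend = increment / params.yield_gain_per_rs
    return increment, spend
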