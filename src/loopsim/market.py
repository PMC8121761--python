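"""Trader cohorts, price formation, storage/spoilage and entry-exit.

Each market hosts a small set of trader cohorts (out-of-state distance
traders — mornings only, Market A only — local wholesalers, and local
retailers whose capacity is customer-demand-driven).  Farmgate prices anchor
on the distance traders' expected (reference) price and respond to the ratio
of downstream demand to availability through a clamped power law; low-grade
produce earns half price, giving a quality-weighted average.

Unsold trader stock ages in half-day FIFO cohorts: 4 half-days of shelf life
without cold storage, 42 with.  Cold-storage capacity is shared across
cohorts in proportion to their share of supplies and is rented at
0.15 Rs/kg-stored/half-day.  Trader entries follow trailing-month profits;
exits occur while a cohort is losing money.
"""

from __future__ import annotations

from .config import MarketConfig

__all__ = [
    "cold_storage_capacity",
    "quality_adjusted_price",
    "offered_price",
    "trader_profit",
    "trader_entry_exit",
    "AgeQueue",
    "spoilage_update",
]


def cold_storage_capacity(active: int, level: float, market: str,
                          params: MarketConfig | None = None) -> float:
    """Cold-storage capacity (kg/half-day) for one market.

    Linear in the investment level: one unit buys 25,000 kg/half-day in
    Market A and 5,000 in Market B; zero when the activation switch is off.
    """
    if not 0.0 <= level <= 3.0:
        raise ValueError(f"storage investment level {level} outside [0, 3]")
    if market not in ("A", "B"):
        raise ValueError(f"unknown market {market!r}")
    unit_A = params.storage_unit_A if params is not None else 25000.0
    unit_B = params.storage_unit_B if params is not None else 5000.0
    unit = unit_A if market == "A" else unit_B
    return (1.0 if active else 0.0) * level * unit


def quality_adjusted_price(offered: float, high_grade_fraction: float) -> float:
    """Weighted average price: high grade at full price, low grade at half."""
    h = high_grade_fraction
    return offered * (h + 0.5 * (1.0 - h))


def offered_price(
    reference_price: float,
    availability: float,
    demand: float,
    params: MarketConfig,
) -> float:
    """Price a trader offers, anchored on the reference price.

    price = reference * clamp((demand/availability)^eta, lo, hi).  Scarcity
    (availability << demand) pushes toward the high clamp, a glut toward the
    low clamp; zero availability prices at the high clamp, zero demand at the
    low clamp.
    """
    lo, hi = params.price_clamp_lo, params.price_clamp_hi
    if availability <= 0.0:
        factor = hi
    elif demand <= 0.0:
        factor = lo
    else:
        factor = (demand / availability) ** params.price_elasticity_eta
        factor = min(hi, max(lo, factor))
    return reference_price * factor


def trader_profit(
    purchases: float,
    wastage: float,
    buy_price: float,
    sell_price: float,
    costs: float,
) -> float:
    """Half-day trader profit (Rs).

    Revenue on (purchases - wastage) at the selling price, minus the full
    purchase bill and all other costs (transport, commissions, storage rent,
    miscellaneous).
    """
    if wastage > purchases + 1e-9:
        raise ValueError("wastage exceeds purchases")
    return (purchases - wastage) * sell_price - purchases * buy_price - costs


def trader_entry_exit(
    count: float,
    profit_30d: float,
    params: MarketConfig,
    count_max: float | None = None,
) -> float:
    """Advance a cohort's trader count one half-day.

    Entries are proportional to positive trailing-month cohort profit; while
    the trailing profit is negative the count decays at ``exit_coeff`` per
    half-day.  Counts never go negative, and an optional ceiling (physical
    stall space in the marketplace) bounds cohort growth.
    """
    d = params.entry_coeff * max(profit_30d, 0.0)
    if profit_30d < 0.0:
        d -= params.exit_coeff * count
    count = max(0.0, count + d)
    if count_max is not None:
        count = min(count, count_max)
    return count


class AgeQueue:
    """FIFO age cohorts of unsold produce, half-day granularity."""

    __slots__ = ("ages",)

    def __init__(self):
        # list of [age_in_half_days, kg], oldest first
        self.ages: list = []

    @property
    def total(self) -> float:
        return sum(kg for _, kg in self.ages)

    def take(self, quantity: float) -> float:
        """Remove up to ``quantity`` kg, oldest first; returns kg removed."""
        taken = 0.0
        while self.ages and taken < quantity - 1e-12:
            age, kg = self.ages[0]
            grab = min(kg, quantity - taken)
            taken += grab
            if grab >= kg - 1e-12:
                self.ages.pop(0)
            else:
                self.ages[0][1] = kg - grab
        return taken


def spoilage_update(
    queue: AgeQueue,
    unsold: float,
    shelf_life: int,
    storage_cap: float | None = None,
) -> tuple:
    """Age the queue one half-day, add today's unsold stock, spoil the rest.

    Produce older than ``shelf_life`` half-days spoils.  When a storage
    capacity applies (cold storage active), total carried stock is capped at
    the cohort's capacity share and the excess — oldest first — spoils.
    Returns (carried_kg, spoiled_kg).
    """
    if unsold < 0:
        raise ValueError("unsold must be non-negative")
    spoiled = 0.0
    aged: list = []
    for age, kg in queue.ages:
        age += 1
        if age > shelf_life:
            spoiled += kg
        else:
            aged.append([age, kg])
    if unsold > 0.0:
        if shelf_life >= 1:
            aged.append([1, unsold])
        else:
            spoiled += unsold
    if storage_cap is not None:
        total = sum(kg for _, kg in aged)
        excess = total - storage_cap
        while excess > 1e-12 and aged:
            age, kg = aged[0]
            drop = min(kg, excess)
            spoiled += drop
            excess -= drop
            if drop >= kg - 1e-12:
                aged.pop(0)
            else:
                aged[0][1] = kg - drop
    queue.ages = aged
    return queue.total, spoiled
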