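"""Retail customer demand: price elasticity, weekly smoothing, growth.

Customer purchase demand responds to the retail price through a constant
expenditure elasticity (negative: higher prices depress demand), compounds
with an externally imposed reference-demand growth rate (the behaviour-change
scenario), and adjusts gradually — consumers revisit their demand roughly
once a week, i.e. a first-order smoothing over 14 half-days.
"""

from __future__ import annotations

from .config import DemandConfig

__all__ = ["target_demand", "smooth_demand", "retailer_demand"]


def target_demand(
    price: float,
    reference_price: float,
    reference_demand: float,
    elasticity: float,
    growth_rate: float = 0.0,
    years_elapsed: float = 0.0,
) -> float:
    """Instantaneous demand target (kg/customer/half-day).

    target = reference_demand * (price/reference_price)^elasticity
             * (1 + growth_rate)^years_elapsed

    ``elasticity`` < 0, so the market-level balancing loop (more supply →
    lower price → more purchases) points the right way.
    """
    if price <= 0.0 or reference_price <= 0.0:
        raise ValueError("prices must be strictly positive")
    growth = (1.0 + growth_rate) ** years_elapsed if years_elapsed > 0 else 1.0
    return reference_demand * (price / reference_price) ** elasticity * growth


def smooth_demand(current: float, target: float, time_constant: float = 14.0) -> float:
    """First-order exponential adjustment toward the target.

    current' = current + (target - current)/time_constant; the fixed point is
    the target, and a step change decays geometrically by (1 - 1/tc) per
    half-day.  An infinite time constant freezes demand.
    """
    if time_constant <= 0:
        return target
    return current + (target - current) / time_constant


def retailer_demand(demand_per_customer: float, customers_per_retailer: float) -> float:
    """Demand per retailer (kg/half-day): customers times per-head demand."""
    return demand_per_customer * customers_per_retailer


def reference_retail_price(cfg: DemandConfig, market: str) -> float:
    return cfg.reference_retail_price_A if market == "A" else cfg.reference_retail_price_B


def elasticity_for(cfg: DemandConfig, market: str) -> float:
    return cfg.elasticity_urban if market == "A" else cfg.elasticity_rural
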