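"""Daily participation, market preference and trader-type allocation.

Three population-level choices are modelled, all driven by the same pair of
signals — guaranteed sales (the share of produce brought to market actually
sold) and marketing profit — with sales security weighted above profit:

* the share of the morning's Loop marketing cohort that aggregates rather
  than self-supplies (a bounded logistic of the trailing-week channel
  comparison);
* the Market A vs Market B preference, a [0, 100] percentage stock adjusted
  by the trailing-week difference in expected profit and sales between the
  two markets;
* the split of each market's supply across trader types (softmax over
  expected price and sales fraction per type).

Non-Loop market shares are constants plus bounded multiplicative noise.
"""

from __future__ import annotations

import math

import numpy as np

from .config import MarketingConfig

__all__ = [
    "loop_participation_share",
    "update_market_preference",
    "nonloop_market_split",
    "trader_allocation",
]


def _logistic(x: float) -> float:
    if x >= 0:
        z = math.exp(-x)
        return 1.0 / (1.0 + z)
    z = math.exp(x)
    return z / (1.0 + z)


def loop_participation_share(
    loop_profit_7d: float,
    nonloop_profit_7d: float,
    loop_sales_frac_7d: float,
    nonloop_sales_frac_7d: float,
    params: MarketingConfig,
    profit_norm: float = 1.0,
) -> float:
    """Share of today's Loop marketing cohort that aggregates.

    A logistic of the sales-weighted channel comparison, mapped into
    [participation_floor, 1]; at exact parity it returns the neutral midpoint
    (floor + 1)/2.  Profits are normalised by ``profit_norm`` (typically the
    trailing mean price) so the weights stay unitless.
    """
    norm = profit_norm if profit_norm > 0 else 1.0
    score = params.weight_sales * (loop_sales_frac_7d - nonloop_sales_frac_7d)
    score += params.weight_profit * (loop_profit_7d - nonloop_profit_7d) / norm
    lo = params.participation_floor
    return lo + (1.0 - lo) * _logistic(params.participation_steepness * score)


def update_market_preference(
    pref_A: float,
    exp_profit_A: float,
    exp_profit_B: float,
    sales_A: float,
    sales_B: float,
    params: MarketingConfig,
    profit_norm: float = 1.0,
) -> float:
    """Advance the Market-A preference stock (percentage points) one step.

    d(pref) = rate * [w_s (sales_A - sales_B) + w_p (profit_A - profit_B)/norm],
    clamped to [0, 100].  The balancing structure emerges in the closed loop:
    shifting supply toward a market depresses its price and sales fraction,
    pushing the preference back.
    """
    norm = profit_norm if profit_norm > 0 else 1.0
    delta = params.pref_adjustment_rate * (
        params.weight_sales * (sales_A - sales_B)
        + params.weight_profit * (exp_profit_A - exp_profit_B) / norm
    )
    return min(100.0, max(0.0, pref_A + delta))


def nonloop_market_split(
    base_A: float,
    noise: float,
    noise_bound: float = 0.10,
) -> float:
    """Fraction of non-Loop supply sent to Market A this half-day.

    ``noise`` is a uniform draw in [-1, 1]; the result is the constant share
    perturbed by up to ``noise_bound`` of its own value, clamped to [0, 1].
    """
    return min(1.0, max(0.0, base_A * (1.0 + noise_bound * noise)))


def aggregation_transport_cost(
    cost_min: float,
    cost_max: float,
    volume_kg: float,
    scale_kg: float,
    noise_u: float,
) -> float:
    """Per-kg aggregation transport cost within the observed range.

    Fuller aggregation loads spread the vehicle cost over more produce, so
    the effective ceiling of the per-kg range falls toward its floor as the
    pooled volume grows (half the premium gone at ``scale_kg``).  ``noise_u``
    in [0, 1] places the day's realised cost within the remaining band.
    """
    if scale_kg > 0:
        f = volume_kg / (volume_kg + scale_kg)
    else:
        f = 0.0  # no scale economy: plain uniform draw over the range
    upper = cost_max - (cost_max - cost_min) * f
    return cost_min + (upper - cost_min) * noise_u


def trader_allocation(
    supply: float,
    exp_prices,
    sales_fracs,
    params: MarketingConfig,
    price_norm: float = 1.0,
    active=None,
) -> np.ndarray:
    """Split ``supply`` (kg) across trader types by softmax attractiveness.

    Attractiveness of type *t* is w_s*sales_frac_t + w_p*price_t/price_norm;
    shares are softmax with slope ``trader_choice_steepness`` over the active
    types (inactive types — e.g. distance traders in the afternoon — get 0).
    With no active types the supply goes nowhere (all-zero allocation).
    """
    exp_prices = np.asarray(exp_prices, dtype=float)
    sales_fracs = np.asarray(sales_fracs, dtype=float)
    n = exp_prices.shape[0]
    if active is None:
        active = np.ones(n, dtype=bool)
    else:
        active = np.asarray(active, dtype=bool)
    out = np.zeros(n)
    if not active.any() or supply <= 0.0:
        return out
    norm = price_norm if price_norm > 0 else 1.0
    score = (
        params.weight_sales * sales_fracs
        + params.weight_profit * exp_prices / norm
    )
    z = params.trader_choice_steepness * score[active]
    z = np.exp(z - z.max())
    out[active] = supply * z / z.sum()
    return out
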