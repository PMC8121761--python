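"""Model configuration: every tunable constant of the simulator.

Constants printed in the field literature (farmer population, capacities,
transport ranges, investment rules, storage economics) are locked by the test
suite; the remainder are calibration defaults chosen once to give a coherent
baseline (see docs/methods.md) and are the natural subjects of the
sensitivity machinery in :mod:`loopsim.sensitivity`.

Configurations round-trip through YAML (``ModelConfig.to_yaml`` /
``ModelConfig.from_yaml``) and individual scalars are addressable by dotted
paths (``get_path`` / ``set_path``) so perturbation designs can target any
numeric constant.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from . import simclock

__all__ = [
    "AdoptionConfig",
    "ProductionConfig",
    "MarketingConfig",
    "MarketConfig",
    "DemandConfig",
    "FixtureConfig",
    "ModelConfig",
    "default_config",
    "get_path",
    "set_path",
    "numeric_paths",
]


@dataclass
class AdoptionConfig:
    """Aggregation membership dynamics (diffusion + trust + utility)."""

    total_farmers: float = 12087.0        # Koilwar block farmer population
    initial_loop_farmers: float = 90.0
    extension_rate: float = 0.0           # p: farmers /1000 non-Loop /half-day
    imitation_coeff: float = 0.0012       # q: word-of-mouth, per half-day
    disadoption_rate: float = 0.0002      # per Loop farmer per half-day at trust 0
    disadoption_mode: str = "trust"       # "trust" | "utility" | "both"
    initial_trust: float = 0.5
    trust_gain: float = 0.004             # per half-day, both monthly trends up
    trust_decay: float = 0.004
    w_profit: float = 0.4                 # utility weights: sales-security first
    w_sales: float = 0.6
    utility_ratio_cap: float = 2.0


@dataclass
class ProductionConfig:
    """Seasonal yields, land allocation and end-of-season reinvestment."""

    loop_land_m2: float = 2000.0          # cultivable land per Loop farmer
    nonloop_land_m2: float = 2000.0
    fv_fraction_rabi: float = 0.8         # peak share of land under F&V
    fv_fraction_zaid: float = 0.65
    fv_fraction_kharif: float = 0.5       # trough share
    price_adjustment_band: float = 0.2    # relative-price modifier in [1-b, 1+b]
    reference_price_ratio: float = 0.6    # F&V/staple price ratio with no effect
    yield_rabi: float = 0.031             # kg marketable per m2 per marketing trip
    yield_zaid: float = 0.022
    yield_kharif: float = 0.018
    own_consumption_rate: float = 0.10    # shares of production, pre-marketing
    giveaway_rate: float = 0.04
    pre_farmgate_loss_rate: float = 0.08
    female_premium: float = 0.10          # extra own consumption, female-headed
    female_fraction_loop: float = 0.12
    female_fraction_nonloop: float = 0.10
    quality_min: float = 0.6              # high-grade share drawn per half-day
    quality_max: float = 1.0
    land_price_per_katha: float = 76000.0
    katha_m2: float = 400.0               # one-tenth katha ~ 40 m2 at face value
    land_invest_rate: float = 0.20
    land_invest_threshold: float = 7600.0  # cost of one-tenth katha
    yield_invest_rate: float = 0.10
    yield_gain_per_rs: float = 0.01 / 20000.0  # 1% per Rs 20,000
    yield_annual_cap: float = 0.015       # max +1.5% yield per model year


@dataclass
class MarketingConfig:
    """Daily participation, market preference and transport economics."""

    initial_pref_A: float = 95.0          # % of Loop supplies to Market A
    pref_adjustment_rate: float = 0.5     # preference points per half-day per unit score
    weight_sales: float = 0.6             # sales security outweighs profit
    weight_profit: float = 0.4
    participation_steepness: float = 6.0  # logistic slope for daily participation
    participation_floor: float = 0.5      # minimum share of the cohort aggregating
    nonloop_share_A: float = 0.9          # >90% of non-Loop F&V goes to the city
    nonloop_noise_bound: float = 0.10     # +/-10% of the constant, per timestep
    transport_loop_A_min: float = 0.50    # Rs/kg, aggregated to Market A
    transport_loop_A_max: float = 0.85
    transport_loop_B_min: float = 0.80
    transport_loop_B_max: float = 1.10
    transport_self_min: float = 1.00      # Rs/kg, self-supply either market
    transport_self_max: float = 1.50
    launch_subsidy: float = 0.5           # first-year subsidy on Loop routes
    commission_rate: float = 0.05         # market commission on farmer revenue
    trader_choice_steepness: float = 10.0  # softmax slope for trader allocation
    transport_scale_kg: float = 0.0       # >0 gives fuller loads cheaper per-kg transport


@dataclass
class MarketConfig:
    """Trader cohorts, price formation, storage and entry/exit."""

    # Baseline trader counts (chosen so peak-Rabi capacity is ~100,000 kg/day
    # in Market A and ~20,000 kg/day in Market B).
    distance_A_count: float = 25.0
    wholesaler_A_count: float = 33.0
    retailer_A_count: float = 350.0
    wholesaler_B_count: float = 12.0
    retailer_B_count: float = 190.0
    distance_capacity: float = 2000.0     # kg/trader/half-day, mornings only
    wholesaler_capacity: float = 600.0    # kg/trader/half-day, all day
    margin_distance: float = 0.15         # selling margin over buy price
    margin_wholesaler: float = 0.20
    margin_retailer: float = 0.30
    misc_cost_distance: float = 200.0     # Rs/trader/half-day (tolls, bribes, ...)
    misc_cost_wholesaler: float = 80.0
    misc_cost_retailer: float = 30.0
    price_elasticity_eta: float = 0.5     # exponent of demand/availability ratio
    price_clamp_lo: float = 0.5           # offered price in [lo, hi] x reference
    price_clamp_hi: float = 1.5
    entry_coeff: float = 2e-8             # traders per Rs of 30-day cohort profit
    exit_coeff: float = 0.001             # per half-day while losing money
    trader_count_cap: float = 1.5         # max growth of a cohort over its baseline count
    shelf_life_base: int = 4              # half-days (2 days) without storage
    shelf_life_cold: int = 42             # half-days (21 days) with storage
    storage_rent: float = 0.15            # Rs per kg stored per half-day
    storage_unit_A: float = 25000.0       # kg/half-day per investment level
    storage_unit_B: float = 5000.0


@dataclass
class DemandConfig:
    """Retail customer demand and its weekly smoothing."""

    reference_demand: float = 0.1         # kg/customer/half-day (~200 g/day)
    elasticity_urban: float = -0.6        # Market A expenditure elasticity
    elasticity_rural: float = -0.9        # Market B
    smoothing_half_days: float = 14.0     # consumers adjust about once a week
    customers_per_retailer_A: float = 150.0
    customers_per_retailer_B: float = 120.0
    reference_retail_price_A: float = 13.5  # Rs/kg at which demand = reference
    reference_retail_price_B: float = 12.0  # weaker rural purchasing power
    demand_growth: float = 0.0            # fraction/yr, scenario 4 sets this


@dataclass
class FixtureConfig:
    """Synthetic stand-ins for the non-public input series."""

    price_mean: float = 12.0              # Rs/kg wholesale reference level
    price_amplitude: float = 0.30         # relative seasonal swing
    price_peak_week: float = 37.0         # week-of-model-year of the price peak (lean season)
    price_noise_sd: float = 0.08          # lognormal sigma, weekly
    staple_price_mean: float = 20.0       # Rs/kg rice/wheat/maize composite
    staple_amplitude: float = 0.05
    staple_noise_sd: float = 0.03
    cost_production_mean: float = 15.0    # Rs/farmer/day, truncated normal
    cost_production_sd: float = 5.0
    cost_labour_mean: float = 20.0        # Rs/farmer/day
    cost_labour_sd: float = 6.0
    corridor_noise_sd: float = 0.05       # multiplicative noise on pseudo-observations


@dataclass
class ModelConfig:
    """Full parameterisation of one simulation."""

    adoption: AdoptionConfig = field(default_factory=AdoptionConfig)
    production: ProductionConfig = field(default_factory=ProductionConfig)
    marketing: MarketingConfig = field(default_factory=MarketingConfig)
    market: MarketConfig = field(default_factory=MarketConfig)
    demand: DemandConfig = field(default_factory=DemandConfig)
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)
    start_date: dt.date = simclock.EPOCH
    scenario_start: dt.date = simclock.SCENARIO_START
    end_date: dt.date = simclock.HORIZON_END
    launch_subsidy_end: dt.date = dt.date(2018, 9, 30)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return _fromdict(cls, data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "ModelConfig":
        return ModelConfig.from_dict(self.to_dict())


def default_config() -> ModelConfig:
    """A fresh configuration with all documented defaults."""
    return ModelConfig()


# ---------------------------------------------------------------------------
# dict round-trip helpers (dates serialised as ISO strings)

def _asdict(obj):
    if is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    return obj


def _fromdict(cls, data):
    import typing

    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        ftype = hints.get(f.name)
        if isinstance(ftype, type) and is_dataclass(ftype):
            kwargs[f.name] = _fromdict(ftype, value)
        elif ftype is dt.date and isinstance(value, str):
            kwargs[f.name] = dt.date.fromisoformat(value)
        else:
            kwargs[f.name] = value
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# dotted-path access, used by the sensitivity machinery

def get_path(config: ModelConfig, path: str):
    """Fetch ``config.section.field`` by dotted string."""
    obj = config
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def set_path(config: ModelConfig, path: str, value) -> None:
    """Assign ``config.section.field`` by dotted string (in place)."""
    parts = path.split(".")
    obj = config
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise AttributeError(f"no config field {path!r}")
    setattr(obj, parts[-1], value)


def numeric_paths(config: ModelConfig) -> list:
    """All dotted paths of scalar numeric constants, with their values.

    Returns ``[(path, value, section), ...]`` — the raw material for a
    perturbation manifest.
    """
    out = []
    for sec in fields(config):
        section = getattr(config, sec.name)
        if not is_dataclass(section):
            continue
        for f in dataclasses.fields(section):
            value = getattr(section, f.name)
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                continue
            out.append((f"{sec.name}.{f.name}", float(value), sec.name))
    return out
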