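"""Synthetic stand-ins for the non-public input data.

The study's primary inputs — an aggregation-dashboard transaction record and
wholesale market price sheets — are not publicly archived, so this module
generates statistically coherent substitutes: a weekly wholesale reference
price with a seasonal cycle (peaking in the lean season), a staple-price
series, truncated-normal household cost draws, and pseudo-observed corridor
target series derived from a baseline run plus multiplicative noise.  Every
fixture is reproducible from (config, seed).
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import simclock
from .config import FixtureConfig, ModelConfig

__all__ = [
    "make_reference_price_series",
    "make_staple_price_series",
    "make_cost_draws",
    "make_cost_series",
    "make_pseudo_observed_series",
    "make_input_bundle",
    "read_series_csv",
]

_WEEK_HALF_DAYS = 14
_WEEKS_PER_YEAR = 52


def _weekly_template(
    mean: float, amplitude: float, peak_week: float, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One model-year of weekly price levels: sinusoid x lognormal noise."""
    weeks = np.arange(_WEEKS_PER_YEAR)
    seasonal = mean * (
        1.0 + amplitude * np.cos(2.0 * np.pi * (weeks - peak_week) / _WEEKS_PER_YEAR)
    )
    if noise_sd > 0:
        noise = rng.lognormal(mean=-0.5 * noise_sd**2, sigma=noise_sd,
                              size=_WEEKS_PER_YEAR)
    else:
        noise = np.ones(_WEEKS_PER_YEAR)
    return seasonal * noise


def _tile_weekly(template: np.ndarray, n_half_days: int) -> np.ndarray:
    """Expand a 52-week template to a piecewise-constant half-day series."""
    week_idx = (np.arange(n_half_days) // _WEEK_HALF_DAYS) % _WEEKS_PER_YEAR
    return template[week_idx]


def make_reference_price_series(
    cfg: FixtureConfig, n_half_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Weekly wholesale reference price (Rs/kg) per half-day.

    One noisy 52-week seasonal template is generated and tiled over the whole
    horizon — mirroring how a single observed price year is repeated over the
    simulation — piecewise-constant over each 14-half-day week.
    """
    template = _weekly_template(
        cfg.price_mean, cfg.price_amplitude, cfg.price_peak_week,
        cfg.price_noise_sd, rng,
    )
    return _tile_weekly(template, n_half_days)


def make_staple_price_series(
    cfg: FixtureConfig, n_half_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Staple (rice/wheat/maize composite) price per half-day, weekly steps."""
    template = _weekly_template(
        cfg.staple_price_mean, cfg.staple_amplitude,
        cfg.price_peak_week + _WEEKS_PER_YEAR / 2.0,  # staples cheap when F&V dear
        cfg.staple_noise_sd, rng,
    )
    return _tile_weekly(template, n_half_days)


def _truncnorm_draws(mean, sd, n, rng):
    if sd <= 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd  # truncate at zero: costs cannot be negative
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def make_cost_draws(cfg: FixtureConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-farmer half-day cost draws (Rs).

    Each on-farm cost component (production inputs, labour) samples a
    truncated normal per draw; components are summed and the daily total is
    halved into a half-day cost.
    """
    prod = _truncnorm_draws(cfg.cost_production_mean, cfg.cost_production_sd, n, rng)
    lab = _truncnorm_draws(cfg.cost_labour_mean, cfg.cost_labour_sd, n, rng)
    return (prod + lab) / 2.0


def make_cost_series(
    cfg: FixtureConfig, n_half_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Population-average per-farmer half-day cost series over the horizon."""
    return make_cost_draws(cfg, n_half_days, rng)


def make_pseudo_observed_series(
    baseline_result,
    cfg: FixtureConfig,
    rng: np.random.Generator,
    window: tuple = (dt.date(2018, 3, 1), dt.date(2018, 8, 25)),
) -> dict:
    """Corridor target series: noisy copies of baseline behaviour.

    Stands in for the dashboard's observed daily aggregated sales in Market A
    and total member counts.  Returns ``{"loop_sales_A": Series,
    "loop_farmers": Series}``, both date-indexed dailies over the evaluation
    window with multiplicative lognormal noise.
    """
    sd = cfg.corridor_noise_sd
    out = {}
    for name, series in (
        ("loop_sales_A", baseline_result.daily_loop_sales_A(window)),
        ("loop_farmers", baseline_result.daily_loop_farmers(window)),
    ):
        if sd > 0:
            noise = rng.lognormal(-0.5 * sd**2, sd, size=len(series))
        else:
            noise = np.ones(len(series))
        out[name] = pd.Series(series.to_numpy() * noise, index=series.index,
                              name=name)
    return out


def make_input_bundle(config: ModelConfig, seed: int, outdir) -> dict:
    """Write the full synthetic input bundle (CSV series + config YAML).

    Returns the paths written.  Series CSVs use an ISO-8601 ``date,value``
    header with one row per calendar day (the morning value).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = simclock.half_day_count(config.start_date, config.end_date)
    ss = np.random.SeedSequence(seed)
    price_rng, staple_rng, cost_rng = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(3)
    )
    paths = {}
    dates = pd.date_range(config.start_date, config.end_date, freq="D").date

    price = make_reference_price_series(config.fixtures, n, price_rng)
    staple = make_staple_price_series(config.fixtures, n, staple_rng)
    for name, series in (("reference_price", price), ("staple_price", staple)):
        daily = series[::2]  # morning value of each day
        path = outdir / f"{name}.csv"
        pd.DataFrame({"date": dates, "value": daily}).to_csv(path, index=False)
        paths[name] = path

    costs = make_cost_draws(config.fixtures, 1000, cost_rng)
    cost_path = outdir / "cost_draws.csv"
    pd.DataFrame({"half_day_cost_rs": costs}).to_csv(cost_path, index=False)
    paths["cost_draws"] = cost_path

    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths


def read_series_csv(path) -> pd.Series:
    """Read a ``date,value`` CSV into a date-indexed series."""
    df = pd.read_csv(path, parse_dates=["date"])
    return pd.Series(df["value"].to_numpy(), index=df["date"].dt.date,
                     name=Path(path).stem)
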