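"""Monte-Carlo sampling of the four-dimensional scenario space.

Four simultaneous upgrades are explored: scaling up aggregation (the
extension coefficient of the diffusion model), subsidising transport to the
small retail market, market-based cold storage (an activation switch plus an
investment level), and external retail demand growth.  Magnitudes are drawn
uniformly within plausible ranges — the broad phase-1 ranges for the horizon
scan, and the narrower phase-2 ranges that bracket the core win-win-win
region — and every draw is paired with a do-nothing baseline run sharing its
noise streams, so outcome deltas isolate the scenario effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig, default_config
from .outcomes import classify, core_subset
from .simulate import SimulationDiverged, ValueChainModel

__all__ = [
    "ScenarioVector",
    "EnsembleSpec",
    "PHASE1_RANGES",
    "PHASE2_RANGES",
    "sample_scenarios",
    "run_ensemble",
]

#: Horizon-scan ranges: extension (farmers /1000 non-members /half-day),
#: Market-B transport subsidy (%), storage activation raw draw, storage
#: investment level, reference demand growth (%/yr).
PHASE1_RANGES = {
    "extension_rate": (0.0, 0.274),
    "subsidy_B": (0.0, 100.0),
    "cs_active_raw": (0.0, 1.0),
    "cs_level": (0.0, 3.0),
    "demand_growth": (0.0, 10.0),
}

#: Refinement ranges bracketing the core win-win-win scenario region.
PHASE2_RANGES = {
    "extension_rate": (0.035, 0.086),
    "subsidy_B": (0.0, 50.0),
    "cs_active_raw": (0.0, 1.0),
    "cs_level": (0.0, 0.62),
    "demand_growth": (7.5, 10.0),
}

_DIMENSIONS = tuple(PHASE1_RANGES)


@dataclass(frozen=True)
class ScenarioVector:
    """One draw of the four scenario magnitudes."""

    extension_rate: float = 0.0
    subsidy_B: float = 0.0
    cs_active_raw: float = 0.0
    cs_level: float = 0.0
    demand_growth: float = 0.0

    @property
    def cold_storage_active(self) -> bool:
        """Storage exists only when the activation draw reaches 0.5."""
        return self.cs_active_raw >= 0.5

    def __str__(self) -> str:
        return (
            f"extension={self.extension_rate:.4f}, subsidy_B={self.subsidy_B:.1f}%, "
            f"storage={'on' if self.cold_storage_active else 'off'}"
            f"@{self.cs_level:.2f}, growth={self.demand_growth:.1f}%/yr"
        )


@dataclass
class EnsembleSpec:
    """Ensemble size, scenario ranges and the master seed."""

    n_runs: int = 100
    ranges: dict = field(default_factory=lambda: dict(PHASE1_RANGES))
    master_seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for dim in _DIMENSIONS:
            lo, hi = self.ranges[dim]
            if lo > hi:
                raise ValueError(f"range for {dim} reversed: ({lo}, {hi})")


def sample_scenarios(spec: EnsembleSpec) -> list:
    """Independent uniform draws of the scenario vector, one per run.

    Reproducible from the master seed; the draws use a dedicated child
    stream so the per-run simulation seeds stay untouched.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    scen_stream = ss.spawn(1)[0]
    rng = np.random.Generator(np.random.PCG64(scen_stream))
    draws = {}
    for dim in _DIMENSIONS:
        lo, hi = spec.ranges[dim]
        draws[dim] = rng.uniform(lo, hi, spec.n_runs) if hi > lo \
            else np.full(spec.n_runs, float(lo))
    return [
        ScenarioVector(**{dim: float(draws[dim][i]) for dim in _DIMENSIONS})
        for i in range(spec.n_runs)
    ]


def _run_seeds(spec: EnsembleSpec) -> list:
    """Deterministic per-run child seeds (below 2**31) from the master seed."""
    ss = np.random.SeedSequence(spec.master_seed + 1)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_runs)]


def run_ensemble(
    spec: EnsembleSpec,
    config: ModelConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate the full ensemble and classify every run.

    Each scenario run is paired with a baseline run under the same child
    seed (common random numbers).  Returns one row per run: the scenario
    coordinates, the three outcomes and their baseline values and deltas,
    the trade-off category and the core flag.  Runs whose stocks diverge
    are excluded and reported in the ``failed`` column of the attrs.
    """
    config = config if config is not None else default_config()
    scenarios = sample_scenarios(spec)
    seeds = _run_seeds(spec)

    rows = []
    failures = []
    for i, (scen, seed) in enumerate(zip(scenarios, seeds)):
        try:
            base = ValueChainModel(config).simulate(seed)
            run = ValueChainModel(config, scenario=scen).simulate(seed)
        except SimulationDiverged as exc:
            failures.append((i, seed, str(exc)))
            continue
        out = run.outcome_triple()
        b = base.outcome_triple()
        rows.append({
            "run_id": i,
            "seed": seed,
            "extension_rate": scen.extension_rate,
            "subsidy_B": scen.subsidy_B,
            "cs_active_raw": scen.cs_active_raw,
            "cs_active": scen.cold_storage_active,
            "cs_level": scen.cs_level,
            "demand_growth": scen.demand_growth,
            "cum_purchases_B": out.cum_purchases_B,
            "cum_profit_loop": out.cum_profit_loop,
            "mean_roi": out.mean_roi,
            "loop_farmers_end": float(run.arrays["loop_farmers"][-1]),
            "base_purchases_B": b.cum_purchases_B,
            "base_profit_loop": b.cum_profit_loop,
            "base_roi": b.mean_roi,
            "delta_purchases_B": out.cum_purchases_B - b.cum_purchases_B,
            "delta_profit_loop": out.cum_profit_loop - b.cum_profit_loop,
            "delta_roi": out.mean_roi - b.mean_roi,
            "category": classify(out, b),
        })
        if progress and (i + 1) % 25 == 0:
            print(f"  {i + 1}/{spec.n_runs} runs done")

    df = pd.DataFrame(rows)
    if len(df):
        # core flags on deltas relative to the (zero-delta) baseline point
        from .outcomes import OutcomeTriple

        core_in = pd.DataFrame({
            "cum_purchases_B": df["delta_purchases_B"],
            "cum_profit_loop": df["delta_profit_loop"],
            "mean_roi": df["delta_roi"],
            "category": df["category"],
        })
        df["core"] = core_subset(core_in, OutcomeTriple(0.0, 0.0, 0.0))
    df.attrs["failed"] = failures
    df.attrs["master_seed"] = spec.master_seed
    return df
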