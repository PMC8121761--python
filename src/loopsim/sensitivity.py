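"""Two-stage parameter sensitivity screening against constraint corridors.

Stage one perturbs each qualitatively uncertain constant one at a time by a
uniform relative error ε ∈ [0.75, 1.25] (V = V₀·ε) and scores whether the
perturbed run still reproduces historical behaviour: a run "behaves" when at
least 95% of its output values fall inside a *constraint corridor* — the
pointwise 95% band of a locally weighted regression (LOESS) fit to the
observed (here: pseudo-observed) series.  Variables whose ensembles keep
≥95% of values in-corridor are insensitive; coverage in [0.90, 0.95) is
"yellow", below 0.90 "red".

Stage two perturbs the yellow set jointly, then the red set jointly, at
±5/±10/±25%, checking that corridor coverage degrades as errors widen.
A two-sample Kolmogorov–Smirnov test on the behaviour-giving versus
non-giving ε subsets flags the truly influential parameters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import ModelConfig, get_path, numeric_paths, set_path
from .simulate import ValueChainModel

__all__ = [
    "ConstraintCorridor",
    "KSResult",
    "perturb",
    "fit_corridor",
    "coverage_fraction",
    "triage",
    "ks_screen",
    "build_manifest",
    "run_one_at_a_time",
    "run_staged",
]

EVAL_WINDOW = (dt.date(2018, 3, 1), dt.date(2018, 8, 25))


@dataclass
class ConstraintCorridor:
    """Pointwise lower/upper behaviour bounds per timestep."""

    timesteps: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("corridor has lower > upper")

    def __len__(self) -> int:
        return len(self.timesteps)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    influential: bool | None  # None when not screenable


def perturb(v0: float, eps_range: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """n perturbed values V = V₀·ε with ε ~ Uniform(eps_range)."""
    lo, hi = eps_range
    if lo <= 0:
        raise ValueError("relative error bounds must be positive")
    eps = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))
    return v0 * eps


def fit_corridor(
    timesteps,
    values,
    span: float = 0.3,
    confidence: float = 0.95,
) -> ConstraintCorridor:
    """LOESS centre curve with a pointwise band of the stated confidence.

    The band half-width is z·σ̂ where σ̂ is the residual standard deviation
    around the locally weighted (degree-1) fit — the level at which a series
    regenerated with the same noise keeps ≈95% of its points inside.  A
    noiseless series collapses the corridor onto the fitted line.
    """
    t = np.asarray(timesteps, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 10:
        raise ValueError(f"need at least 10 points to fit a corridor, got {len(t)}")
    if len(t) != len(y):
        raise ValueError("timesteps and values differ in length")
    fitted = lowess(y, t, frac=span, return_sorted=False)
    resid = y - fitted
    sigma = float(np.std(resid, ddof=1))
    z = stats.norm.ppf(0.5 * (1.0 + confidence))
    half = z * sigma
    return ConstraintCorridor(t, fitted - half, fitted + half, fitted)


def coverage_fraction(values, corridor: ConstraintCorridor) -> float:
    """Share of timesteps whose value lies inside the corridor."""
    y = np.asarray(values, dtype=float)
    if len(y) != len(corridor):
        raise ValueError(
            f"series length {len(y)} does not match corridor {len(corridor)}"
        )
    inside = (y >= corridor.lower) & (y <= corridor.upper)
    return float(inside.mean())


def triage(coverage: float) -> str:
    """Sensitivity tier from corridor coverage."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be a fraction")
    if coverage >= 0.95:
        return "insensitive"
    if coverage >= 0.90:
        return "yellow"
    return "red"


def ks_screen(eps_behaving, eps_non_behaving, alpha: float = 0.05) -> KSResult:
    """Two-sample KS test between behaviour-giving and non-giving ε draws.

    An empty subset (every run behaves, or none does) is not screenable and
    returns ``influential=None``.  Small samples use the exact null
    distribution, larger ones the asymptotic one.
    """
    a = np.asarray(eps_behaving, dtype=float)
    b = np.asarray(eps_non_behaving, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return KSResult(float("nan"), float("nan"), None)
    method = "exact" if min(len(a), len(b)) < 30 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(float(res.statistic), float(res.pvalue),
                    bool(res.pvalue < alpha))


# ---------------------------------------------------------------------------
# perturbation campaigns

def build_manifest(config: ModelConfig, exclude=()) -> pd.DataFrame:
    """Perturbation manifest: every scalar config constant with its V₀.

    Columns: variable (dotted path), V0, group (config section).  Structural
    constants that define the experiment itself (dates, the total farmer
    population) can be excluded by dotted path.
    """
    rows = [
        {"variable": path, "V0": v0, "group": group}
        for path, v0, group in numeric_paths(config)
        if path not in exclude
    ]
    return pd.DataFrame(rows)


def _corridor_outputs(result, corridors: dict) -> dict:
    """Per-target coverage of one run against the fitted corridors."""
    series = {
        "loop_sales_A": result.daily_loop_sales_A(EVAL_WINDOW).to_numpy(),
        "loop_farmers": result.daily_loop_farmers(EVAL_WINDOW).to_numpy(),
    }
    return {
        name: coverage_fraction(series[name], corridors[name])
        for name in corridors
    }


def run_one_at_a_time(
    config: ModelConfig,
    manifest: pd.DataFrame,
    corridors: dict,
    n_sims: int = 20,
    eps_range: tuple = (0.75, 1.25),
    seed: int = 0,
    behaving_threshold: float = 0.95,
) -> tuple:
    """Stage-one screening: one variable at a time.

    For each manifest variable, runs ``n_sims`` perturbed simulations over
    the evaluation window and scores corridor coverage.  Returns
    ``(verdicts, ks_table)``: per-variable pooled coverage + tier, and the
    KS screen over behaviour-giving vs non-giving ε subsets.
    """
    ss = np.random.SeedSequence(seed)
    verdict_rows, ks_rows = [], []
    for _, row in manifest.iterrows():
        var, v0 = row["variable"], float(row["V0"])
        child = ss.spawn(1)[0]
        rng = np.random.Generator(np.random.PCG64(child))
        values = perturb(v0, eps_range, n_sims, rng)
        run_seed = int(child.generate_state(1)[0] % (2**31))
        covs, eps_ok, eps_bad, all_inside = [], [], [], []
        for v in values:
            cfg = config.copy()
            set_path(cfg, var, float(v))
            result = ValueChainModel(cfg).simulate(run_seed,
                                                   end_date=EVAL_WINDOW[1])
            per_target = _corridor_outputs(result, corridors)
            cov = float(np.mean(list(per_target.values())))
            covs.append(cov)
            eps = v / v0 if v0 != 0 else 1.0
            (eps_ok if cov >= behaving_threshold else eps_bad).append(eps)
        pooled = float(np.mean(covs))
        verdict_rows.append({
            "variable": var, "V0": v0, "group": row["group"],
            "coverage": pooled, "tier": triage(pooled),
            "n_behaving": len(eps_ok), "n_sims": n_sims,
        })
        ks = ks_screen(eps_ok, eps_bad)
        ks_rows.append({
            "variable": var, "D": ks.statistic, "p": ks.pvalue,
            "influential": ks.influential,
        })
    return pd.DataFrame(verdict_rows), pd.DataFrame(ks_rows)


def run_staged(
    config: ModelConfig,
    variables,
    corridors: dict,
    stages: tuple = (0.05, 0.10, 0.25),
    n_sims: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Stage-two multivariable perturbation at widening error ranges.

    All listed variables are perturbed jointly, each with its own ε drawn
    from [1-w, 1+w] for every stage width w.  Returns the mean corridor
    coverage per stage; coverage is expected to be non-increasing as the
    error range widens.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for stage_idx, width in enumerate(stages):
        child = ss.spawn(1)[0]
        rng = np.random.Generator(np.random.PCG64(child))
        run_seed = int(child.generate_state(1)[0] % (2**31))
        covs = []
        for _ in range(n_sims):
            cfg = config.copy()
            for var in variables:
                v0 = float(get_path(cfg, var))
                set_path(cfg, var, float(perturb(v0, (1 - width, 1 + width),
                                                 1, rng)[0]))
            result = ValueChainModel(cfg).simulate(run_seed,
                                                   end_date=EVAL_WINDOW[1])
            per_target = _corridor_outputs(result, corridors)
            covs.append(float(np.mean(list(per_target.values()))))
        rows.append({
            "stage": stage_idx, "error_width": width,
            "mean_coverage": float(np.mean(covs)), "n_sims": n_sims,
        })
    return pd.DataFrame(rows)
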