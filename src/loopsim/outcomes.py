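"""Outcome accumulation and the three-dimensional trade-off classifier.

Every scenario run is reduced to three outcome dimensions measured over the
scenario horizon — cumulative retail purchases per customer in the small
market (B), cumulative profit per aggregating farmer, and the scheme's mean
return on investment (transport fees collected post-subsidy over the 0.1
Rs/kg paid to aggregators) — and compared with its paired do-nothing
baseline.  The eight win/lose sign-octants collapse onto six categories,
from ``win_win_win`` to ``lose_lose_lose``; a zero delta counts as a loss
(strict-win rule).  Within each category a "core" subset flags the runs
farthest from the baseline (beyond the category mean distance plus one
standard deviation, on z-scored dimensions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeTriple",
    "CATEGORIES",
    "loop_roi",
    "mean_roi",
    "classify",
    "classify_signs",
    "core_subset",
    "conditional_probability_profile",
]


@dataclass(frozen=True)
class OutcomeTriple:
    """The three outcome dimensions of one run."""

    cum_purchases_B: float   # kg per retail customer, scenario horizon
    cum_profit_loop: float   # Rs per Loop farmer, scenario horizon
    mean_roi: float          # dimensionless fees/compensation ratio

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cum_purchases_B, self.cum_profit_loop, self.mean_roi]
        )


CATEGORIES = (
    "win_win_win",
    "access_profit_wins",
    "access_wins",
    "profit_wins",
    "others",
    "lose_lose_lose",
)


def loop_roi(fees_collected: float, kg_sold_via_loop: float,
             compensation_rate: float = 0.1) -> float:
    """Scheme ROI on one half-day: fees over aggregator compensation."""
    if kg_sold_via_loop < 0:
        raise ValueError("kg sold must be non-negative")
    if kg_sold_via_loop == 0:
        raise ZeroDivisionError("no sales: ROI undefined on this half-day")
    return fees_collected / (compensation_rate * kg_sold_via_loop)


def mean_roi(fees: np.ndarray, kg_sold: np.ndarray,
             compensation_rate: float = 0.1) -> float:
    """Mean per-half-day ROI, skipping half-days with zero sales.

    Returns NaN (flagged undefined) if the scheme sold nothing over the
    whole horizon.
    """
    fees = np.asarray(fees, dtype=float)
    kg_sold = np.asarray(kg_sold, dtype=float)
    mask = kg_sold > 0
    if not mask.any():
        return float("nan")
    return float(np.mean(fees[mask] / (compensation_rate * kg_sold[mask])))


def classify_signs(purchases_win: bool, profit_win: bool, roi_win: bool) -> str:
    """Map one win/lose octant to its trade-off category."""
    if purchases_win and profit_win:
        return "win_win_win" if roi_win else "access_profit_wins"
    if purchases_win:
        return "access_wins"
    if profit_win:
        return "profit_wins"
    return "others" if roi_win else "lose_lose_lose"


def classify(outcome: OutcomeTriple, baseline: OutcomeTriple) -> str:
    """Trade-off category of a run relative to its baseline.

    A dimension "wins" iff it strictly exceeds the baseline; ties count as
    losses.  NaN deltas (e.g. an undefined ROI) count as losses.
    """
    d = outcome.as_array() - baseline.as_array()
    wins = d > 0  # NaN compares False
    return classify_signs(bool(wins[0]), bool(wins[1]), bool(wins[2]))


def core_subset(
    outcomes: pd.DataFrame,
    baseline: OutcomeTriple,
    categories=None,
    normalize: str = "zscore",
) -> np.ndarray:
    """Flag the "core" members of each trade-off category.

    ``outcomes`` needs columns ``cum_purchases_B, cum_profit_loop, mean_roi,
    category``.  Distances from the baseline are 3-D Euclidean, computed on
    z-scored dimensions (scored across the full ensemble including the
    baseline point) unless ``normalize="raw"``.  Within each category, a
    member is core iff its distance strictly exceeds the category mean plus
    one (sample) standard deviation; singleton categories have no core.
    """
    dims = ["cum_purchases_B", "cum_profit_loop", "mean_roi"]
    pts = outcomes[dims].to_numpy(dtype=float)
    base = baseline.as_array()
    if normalize == "zscore":
        all_pts = np.vstack([pts, base])
        mu = np.nanmean(all_pts, axis=0)
        sd = np.nanstd(all_pts, axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - mu) / sd
        base_n = (base - mu) / sd
    elif normalize == "raw":
        base_n = base
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    dist = np.sqrt(np.nansum((pts - base_n) ** 2, axis=1))

    labels = outcomes["category"].to_numpy()
    core = np.zeros(len(outcomes), dtype=bool)
    for cat in categories or CATEGORIES:
        mask = labels == cat
        n = int(mask.sum())
        if n == 0:
            continue
        if n == 1:
            warnings.warn(
                f"category {cat!r} has a single member: no core defined",
                stacklevel=2,
            )
            continue
        d = dist[mask]
        threshold = d.mean() + d.std(ddof=1)
        core[mask] = d > threshold
    return core


def conditional_probability_profile(
    scenario_values: np.ndarray,
    labels,
    n_bins: int,
    value_range: tuple | None = None,
) -> pd.DataFrame:
    """Per-bin category proportions across one scenario range.

    Equal-width bins over ``value_range`` (default: the data range).  Each
    row is one bin; columns are the categories plus ``bin_left, bin_right,
    n``.  Proportions in a non-empty bin sum to 1 over the categories
    present; empty bins carry NaN proportions (marked missing).
    """
    values = np.asarray(scenario_values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("scenario_values and labels differ in length")
    lo, hi = value_range if value_range is not None else (values.min(), values.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        row = {"bin_left": edges[b], "bin_right": edges[b + 1], "n": n}
        for cat in CATEGORIES:
            row[cat] = (labels[mask] == cat).mean() if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
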