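"""Plot helpers for trade-off spaces, scenario profiles and corridors."""

from __future__ import annotations

import numpy as np

_CATEGORY_COLORS = {
    "win_win_win": "tab:green",
    "access_profit_wins": "tab:olive",
    "access_wins": "tab:blue",
    "profit_wins": "tab:orange",
    "others": "tab:gray",
    "lose_lose_lose": "tab:red",
}


def tradeoff_scatter(ensemble, x="delta_purchases_B", y="delta_profit_loop", ax=None):
    """2-D projection of the trade-off space, coloured by category.

    Core runs are drawn solid, non-core translucent — matching the usual
    presentation of win-win scans.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for cat, color in _CATEGORY_COLORS.items():
        sub = ensemble[ensemble["category"] == cat]
        if not len(sub):
            continue
        core = sub["core"] if "core" in sub else np.zeros(len(sub), bool)
        ax.scatter(sub.loc[~core, x], sub.loc[~core, y], s=12, alpha=0.25,
                   color=color, label=f"{cat} (n={len(sub)})")
        ax.scatter(sub.loc[core, x], sub.loc[core, y], s=18, alpha=0.95,
                   color=color)
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=7, loc="best")
    return ax


def conditional_probability_plot(profile, ax=None):
    """Stacked per-bin category proportions along one scenario range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    centers = 0.5 * (profile["bin_left"] + profile["bin_right"])
    width = (profile["bin_right"] - profile["bin_left"]).iloc[0] * 0.9
    bottom = np.zeros(len(profile))
    for cat, color in _CATEGORY_COLORS.items():
        if cat not in profile:
            continue
        vals = profile[cat].fillna(0.0).to_numpy()
        ax.bar(centers, vals, width=width, bottom=bottom, color=color,
               label=cat)
        bottom += vals
    ax.set_ylabel("proportion")
    ax.legend(fontsize=7)
    return ax


def corridor_plot(corridor, observed=None, runs=(), ax=None):
    """Constraint corridor with optional observed series and model runs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = corridor.timesteps
    ax.fill_between(t, corridor.lower, corridor.upper, alpha=0.3,
                    color="tab:blue", label="95% corridor")
    ax.plot(t, corridor.center, color="tab:blue", lw=1)
    if observed is not None:
        ax.plot(t, np.asarray(observed, float), "k.", ms=2, label="observed")
    for run in runs:
        ax.plot(t, np.asarray(run, float), lw=0.6, alpha=0.6)
    ax.legend(fontsize=7)
    return ax
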