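"""Aggregation membership dynamics: diffusion with trust and utility gates.

Membership follows the classic two-channel innovation-diffusion structure —
an external extension channel (coefficient ``p``, expressed per 1000
non-members per half-day) and an internal word-of-mouth channel (``q``) —
multiplicatively gated by two behavioural stocks elicited from stakeholders:

* **trust** in the scheme's ability to keep delivering profits and guaranteed
  sales, a [0, 1] stock nudged by the sign of the trailing monthly trends of
  member profit and sales security;
* relative **utility** of aggregating versus self-supplying, a ratio index
  normalised to 1 at parity and clamped to [0, 2].

Dis-adoption drains the member stock in proportion to distrust (and/or
dis-utility, selectable).  The total farmer population is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AdoptionConfig

__all__ = [
    "AdoptionState",
    "ratio_clamped",
    "loop_utility",
    "update_trust",
    "adoption_flow",
]


@dataclass
class AdoptionState:
    """Member/non-member farmer stocks and the trust stock."""

    loop_farmers: float
    nonloop_farmers: float
    trust: float

    @property
    def total(self) -> float:
        return self.loop_farmers + self.nonloop_farmers


def ratio_clamped(numerator: float, denominator: float, cap: float = 2.0) -> float:
    """``numerator/denominator`` clamped to [0, cap], with degenerate cases.

    Both terms non-positive → parity (1.0); positive over non-positive → the
    cap; non-positive over positive → 0.  Keeps the utility index finite when
    the self-supply channel earns nothing.
    """
    if numerator <= 0.0 and denominator <= 0.0:
        return 1.0
    if denominator <= 0.0:
        return cap
    if numerator <= 0.0:
        return 0.0
    return min(cap, numerator / denominator)


def loop_utility(
    loop_profit_7d: float,
    nonloop_profit_7d: float,
    loop_sales_frac_7d: float,
    nonloop_sales_frac_7d: float,
    params: AdoptionConfig,
) -> float:
    """Relative utility of aggregation over the trailing week.

    utility = w_profit * clamp(profit ratio) + w_sales * clamp(sales ratio),
    each ratio clamped to [0, cap]; equals 1 when the channels are identical.
    """
    cap = params.utility_ratio_cap
    r_profit = ratio_clamped(loop_profit_7d, nonloop_profit_7d, cap)
    r_sales = ratio_clamped(loop_sales_frac_7d, nonloop_sales_frac_7d, cap)
    return params.w_profit * r_profit + params.w_sales * r_sales


def update_trust(
    trust: float,
    profit_trend_30d: float,
    sales_trend_30d: float,
    params: AdoptionConfig,
) -> float:
    """Advance the trust stock one half-day from two monthly trend signs.

    Each strictly positive trend contributes ``trust_gain/2``, each strictly
    negative trend ``-trust_decay/2``; a flat trend contributes nothing.
    Result clamped to [0, 1].
    """
    n_pos = (profit_trend_30d > 0) + (sales_trend_30d > 0)
    n_neg = (profit_trend_30d < 0) + (sales_trend_30d < 0)
    trust = trust + params.trust_gain * (n_pos / 2.0) - params.trust_decay * (n_neg / 2.0)
    return min(1.0, max(0.0, trust))


def adoption_flow(
    state: AdoptionState,
    params: AdoptionConfig,
    utility: float,
    extension_rate: float | None = None,
) -> tuple:
    """(adoptions, dis-adoptions) in farmers per half-day.

    adoptions = [p/1000 * nonloop + q * (loop/total) * nonloop] * trust * utility
    dis-adoptions drain members in proportion to (1 - trust), (2 - utility)/2,
    or their mean, per ``params.disadoption_mode``.  Flows are capped so both
    stocks stay non-negative under the explicit half-day Euler step.
    """
    p = params.extension_rate if extension_rate is None else extension_rate
    total = params.total_farmers
    gross = (
        (p / 1000.0) * state.nonloop_farmers
        + params.imitation_coeff * (state.loop_farmers / total) * state.nonloop_farmers
    )
    adoptions = gross * state.trust * utility
    adoptions = min(adoptions, state.nonloop_farmers)

    if params.disadoption_mode == "trust":
        drive = 1.0 - state.trust
    elif params.disadoption_mode == "utility":
        drive = max(0.0, (2.0 - utility) / 2.0)
    elif params.disadoption_mode == "both":
        drive = 0.5 * ((1.0 - state.trust) + max(0.0, (2.0 - utility) / 2.0))
    else:
        raise ValueError(f"unknown disadoption_mode {params.disadoption_mode!r}")
    disadoptions = min(params.disadoption_rate * state.loop_farmers * drive,
                       state.loop_farmers)
    return adoptions, disadoptions
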