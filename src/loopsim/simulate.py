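"""The half-day stock-and-flow engine and its results object.

:class:`ValueChainModel` wires the component modules into one explicit-Euler
simulation at half-day resolution (Δt = 1 half-day, the system's native
granularity): production and pre-marketing outflows, the aggregate/self-supply
participation choice, the Market A/B preference stock, softmax trader
allocation, anchored price formation with quality adjustment, storage and
spoilage, trader entry/exit, elastic smoothed retail demand, farmer profit
accounting and end-of-season reinvestment, and the diffusion of membership
gated by trust and utility.

All stochastic inputs (quality draws, transport costs, non-Loop split noise,
cost draws, the synthetic price fixtures) are pre-drawn from independent
streams spawned from one seed, so a scenario run and its do-nothing baseline
share identical noise (common random numbers) and every run is exactly
reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import adoption as adp
from . import demand as dmd
from . import fixtures as fx
from . import market as mkt
from . import marketing as mch
from . import production as prd
from . import simclock
from ._windows import RollingSum, TrendWindow
from .config import ModelConfig, default_config
from .outcomes import OutcomeTriple, mean_roi

__all__ = ["ValueChainModel", "SimulationResult", "SimulationDiverged"]

_HALF_DAYS_PER_YEAR = 730.5  # mean Gregorian year, used for compounding


class SimulationDiverged(RuntimeError):
    """A stock became non-finite; the run is unusable."""


class _Cohort:
    """Runtime state of one trader cohort (market x type)."""

    __slots__ = (
        "market", "kind", "count", "count_max", "margin", "misc_cost",
        "cap_per_trader", "morning_only", "queue", "price14", "sf14",
        "profit60",
    )

    def __init__(self, market, kind, count, margin, misc_cost, cap_per_trader,
                 morning_only, price_fill, count_cap=1.5):
        self.market = market
        self.kind = kind
        self.count = count
        self.count_max = count * count_cap
        self.margin = margin
        self.misc_cost = misc_cost
        self.cap_per_trader = cap_per_trader  # None => customer-demand-driven
        self.morning_only = morning_only
        self.queue = mkt.AgeQueue()
        self.price14 = RollingSum(14, price_fill)
        self.sf14 = RollingSum(14, 1.0)
        self.profit60 = RollingSum(60, 0.0)


@dataclass
class SimulationResult:
    """Recorded trajectories and diagnostics of one run."""

    config: ModelConfig
    scenario: object
    seed: int
    arrays: dict
    start_date: dt.date
    end_date: dt.date
    max_balance_residual: float
    max_population_deviation: float

    @property
    def n_half_days(self) -> int:
        return len(self.arrays["loop_farmers"])

    def frame(self) -> pd.DataFrame:
        """All recorded series as a half-day-indexed DataFrame."""
        hds = list(simclock.iter_half_days(self.start_date, self.end_date))
        df = pd.DataFrame(self.arrays)
        df.insert(0, "half_day", [h.index for h in hds])
        df.insert(1, "date", [h.date for h in hds])
        df.insert(2, "phase", [h.phase for h in hds])
        return df

    # -- outcome reduction -------------------------------------------------
    def _horizon_slice(self, start: dt.date | None = None) -> slice:
        start = start or self.config.scenario_start
        i0 = simclock.index_of(max(start, self.start_date)) - simclock.index_of(
            self.start_date
        )
        return slice(i0, self.n_half_days)

    def outcome_triple(self, start: dt.date | None = None) -> OutcomeTriple:
        """The three outcome dimensions over the scenario horizon."""
        sl = self._horizon_slice(start)
        a = self.arrays
        return OutcomeTriple(
            cum_purchases_B=float(a["purchases_per_customer_B"][sl].sum()),
            cum_profit_loop=float(a["profit_loop"][sl].sum()),
            mean_roi=mean_roi(a["roi_fees"][sl], a["roi_kg"][sl]),
        )

    # -- daily views used by calibration ----------------------------------
    def _daily(self, key: str, window: tuple) -> pd.Series:
        lo, hi = window
        dates, values = [], []
        arr = self.arrays[key]
        base = simclock.index_of(self.start_date)
        day = max(lo, self.start_date)
        while day <= min(hi, self.end_date):
            i = simclock.index_of(day) - base
            values.append(arr[i])  # morning value
            dates.append(day)
            day += dt.timedelta(days=1)
        return pd.Series(values, index=dates, name=key)

    def daily_loop_sales_A(self, window=(dt.date(2018, 3, 1), dt.date(2018, 8, 25))):
        """Daily aggregated sales into Market A (kg) — corridor target 1."""
        return self._daily("loop_sold_A", window)

    def daily_loop_farmers(self, window=(dt.date(2018, 3, 1), dt.date(2018, 8, 25))):
        """Daily member count — corridor target 2."""
        return self._daily("loop_farmers", window)

    def summary(self) -> str:
        a = self.arrays
        o = self.outcome_triple()
        lines = [
            "Value-chain simulation summary",
            "------------------------------",
            f"horizon: {self.start_date} .. {self.end_date} "
            f"({self.n_half_days} half-days), seed {self.seed}",
            f"scenario: {self.scenario if self.scenario is not None else 'baseline (do nothing)'}",
            f"final Loop farmers: {a['loop_farmers'][-1]:.1f} "
            f"(initial {self.config.adoption.initial_loop_farmers:.0f})",
            f"final trust: {a['trust'][-1]:.3f}; final Market-A preference: "
            f"{a['pref_A'][-1]:.1f}%",
            f"cumulative purchases per Market-B customer: {o.cum_purchases_B:.2f} kg",
            f"cumulative profit per Loop farmer: {o.cum_profit_loop:.0f} Rs",
            f"mean scheme ROI: {o.mean_roi:.3f}",
            f"max mass-balance residual: {self.max_balance_residual:.3e} kg",
        ]
        return "\n".join(lines)


class ValueChainModel:
    """The simulator: a configuration plus an optional scenario overlay.

    Parameters
    ----------
    config : ModelConfig, optional
        Full parameterisation; defaults to :func:`default_config`.
    scenario : object, optional
        A scenario vector (extension rate, Market-B subsidy %, cold-storage
        activation/level, demand growth %/yr) switched on at
        ``config.scenario_start``; ``None`` runs the do-nothing baseline.
    """

    def __init__(self, config: ModelConfig | None = None, scenario=None):
        self.config = config if config is not None else default_config()
        self.scenario = scenario

    # ------------------------------------------------------------------
    def simulate(self, seed: int = 0, end_date: dt.date | None = None) -> SimulationResult:
        """Run the model from its start date through ``end_date``."""
        cfg = self.config
        acfg, pcfg, mcfg, kcfg, dcfg = (
            cfg.adoption, cfg.production, cfg.marketing, cfg.market, cfg.demand
        )
        scen = self.scenario
        start = cfg.start_date
        end = end_date or cfg.end_date
        n = simclock.half_day_count(start, end)
        scen_start = cfg.scenario_start

        # -- pre-drawn stochastic inputs (one stream per process) -------
        ss = np.random.SeedSequence(seed)
        (s_price, s_staple, s_qual_l, s_qual_n, s_transport, s_split,
         s_cost_l, s_cost_n) = ss.spawn(8)
        rng = lambda s: np.random.Generator(np.random.PCG64(s))  # noqa: E731
        ref_price = fx.make_reference_price_series(cfg.fixtures, n, rng(s_price))
        staple = fx.make_staple_price_series(cfg.fixtures, n, rng(s_staple))
        h_l = rng(s_qual_l).uniform(pcfg.quality_min, pcfg.quality_max, n)
        h_n = rng(s_qual_n).uniform(pcfg.quality_min, pcfg.quality_max, n)
        tr = rng(s_transport)
        tc_loop_u = tr.uniform(0.0, 1.0, n)  # position within the route's cost band
        tc_self_a = tr.uniform(mcfg.transport_self_min, mcfg.transport_self_max, n)
        tc_self_b = tr.uniform(mcfg.transport_self_min, mcfg.transport_self_max, n)
        nl_noise = rng(s_split).uniform(-1.0, 1.0, n)
        cost_l = fx.make_cost_series(cfg.fixtures, n, rng(s_cost_l))
        cost_n = fx.make_cost_series(cfg.fixtures, n, rng(s_cost_n))

        # -- scenario switches -------------------------------------------
        if scen is not None:
            p_scen = float(scen.extension_rate)
            sub_b_scen = float(scen.subsidy_B) / 100.0
            cs_active = bool(getattr(scen, "cold_storage_active",
                                     scen.cs_active_raw >= 0.5))
            cs_level = float(scen.cs_level)
            growth = float(scen.demand_growth) / 100.0
        else:
            p_scen, sub_b_scen, cs_active, cs_level, growth = 0.0, 0.0, False, 0.0, 0.0
        cap_store = {
            "A": mkt.cold_storage_capacity(cs_active, cs_level, "A", kcfg),
            "B": mkt.cold_storage_capacity(cs_active, cs_level, "B", kcfg),
        }

        # -- state ---------------------------------------------------------
        total = acfg.total_farmers
        n_loop = acfg.initial_loop_farmers
        trust = acfg.initial_trust
        pref_a = mcfg.initial_pref_A
        land = {"L": pcfg.loop_land_m2, "N": pcfg.nonloop_land_m2}
        ymult = {"L": 1.0, "N": 1.0}
        yhead = {"L": pcfg.yield_annual_cap, "N": pcfg.yield_annual_cap}
        cumprof = {"L": 0.0, "N": 0.0}
        fem = {"L": pcfg.female_fraction_loop, "N": pcfg.female_fraction_nonloop}
        cur_demand = {"A": dcfg.reference_demand, "B": dcfg.reference_demand}

        price_fill = cfg.fixtures.price_mean * 0.875  # expected quality factor
        ccap = kcfg.trader_count_cap
        cohorts = {
            "A": [
                _Cohort("A", "distance", kcfg.distance_A_count,
                        kcfg.margin_distance, kcfg.misc_cost_distance,
                        kcfg.distance_capacity, True, price_fill, ccap),
                _Cohort("A", "wholesaler", kcfg.wholesaler_A_count,
                        kcfg.margin_wholesaler, kcfg.misc_cost_wholesaler,
                        kcfg.wholesaler_capacity, False, price_fill, ccap),
                _Cohort("A", "retailer", kcfg.retailer_A_count,
                        kcfg.margin_retailer, kcfg.misc_cost_retailer,
                        None, False, price_fill, ccap),
            ],
            "B": [
                _Cohort("B", "wholesaler", kcfg.wholesaler_B_count,
                        kcfg.margin_wholesaler, kcfg.misc_cost_wholesaler,
                        kcfg.wholesaler_capacity, False, price_fill, ccap),
                _Cohort("B", "retailer", kcfg.retailer_B_count,
                        kcfg.margin_retailer, kcfg.misc_cost_retailer,
                        None, False, price_fill, ccap),
            ],
        }
        # fixed retail customer population per market (initial retailer
        # count x customers per retailer); entry redistributes the same
        # customer base rather than conjuring new customers
        cust_total = {
            "A": kcfg.retailer_A_count * dcfg.customers_per_retailer_A,
            "B": kcfg.retailer_B_count * dcfg.customers_per_retailer_B,
        }

        # trailing channel statistics (7 mornings for aggregation; 14
        # half-days for the self-supply channel)
        lw = {k: RollingSum(7, 0.0) for k in ("supply", "sold", "net")}
        nw = {k: RollingSum(14, 0.0) for k in ("supply", "sold", "net")}
        # per-market aggregation statistics for the preference stock
        mk_sup = {m: RollingSum(7, 0.0) for m in "AB"}
        mk_sold = {m: RollingSum(7, 0.0) for m in "AB"}
        mk_net = {m: RollingSum(7, 0.0) for m in "AB"}
        # last observed per-market aggregation statistics (margin, sales
        # fraction); kept when a market receives no supplies so scarcity
        # premia are remembered rather than forgotten
        last_mstats = {"A": (0.0, 1.0), "B": (0.0, 1.0)}
        # monthly trend windows feeding trust (morning pushes)
        tw_margin = TrendWindow(30, 0.0)
        tw_sales = TrendWindow(30, 1.0)

        # -- recorders -------------------------------------------------------
        keys = [
            "loop_farmers", "trust", "utility", "pref_A", "participation",
            "loop_supply_A", "loop_supply_B", "loop_sold_A", "loop_sold_B",
            "nonloop_supply_A", "nonloop_supply_B",
            "market_A_supply", "market_B_supply",
            "market_A_sales", "market_B_sales",
            "price_A", "price_B", "retail_price_B", "demand_B",
            "purchases_per_customer_B", "profit_loop", "profit_nonloop",
            "roi_fees", "roi_kg", "stored_A", "stored_B",
            "spoiled_A", "spoiled_B", "traders_A", "traders_B",
            "yield_mult_loop", "loop_net", "loop_credit",
        ]
        rec = {k: np.zeros(n) for k in keys}

        max_resid = 0.0
        max_pop_dev = 0.0
        eps = 1e-9
        launch_end = cfg.launch_subsidy_end
        t0_scen = simclock.index_of(scen_start) - simclock.index_of(start)

        def channel_stats(supply_window, sold_window, net_window):
            s = supply_window.total
            if s > eps:
                return net_window.total / s, min(1.0, sold_window.total / s)
            return 0.0, 1.0

        # -- main loop -------------------------------------------------------
        for t, hd in enumerate(simclock.iter_half_days(start, end)):
            date = hd.date
            morning = hd.is_morning
            season = hd.season
            ref = ref_price[t]
            scen_on = scen is not None and date >= scen_start
            store_on = scen_on and cs_active and cs_level > 0.0

            # season-start reinvestment and annual yield-cap reset
            if morning and date.month == 10 and date.day == 1:
                yhead = {"L": pcfg.yield_annual_cap, "N": pcfg.yield_annual_cap}
            if morning and simclock.is_season_start(date) and t > 0:
                for pop in ("L", "N"):
                    profit0 = cumprof[pop]
                    area, spend_land = prd.invest_in_land(profit0, pcfg)
                    inc, spend_yield = prd.invest_in_yield(profit0, yhead[pop], pcfg)
                    land[pop] += area
                    ymult[pop] *= 1.0 + inc
                    yhead[pop] -= inc
                    cumprof[pop] -= spend_land + spend_yield

            # -- production and outflows --------------------------------
            n_nonloop = total - n_loop
            fvfrac = prd.fv_land_fraction(date, ref, staple[t], pcfg)
            y0 = prd.baseline_yield(season, pcfg)
            mf_l = simclock.marketing_fraction(season, loop=True, phase=hd.phase)
            mf_n = simclock.marketing_fraction(season, loop=False, phase=hd.phase)
            prod_l = prd.marketable_production(n_loop, mf_l, land["L"], fvfrac,
                                               y0, ymult["L"])
            prod_n = prd.marketable_production(n_nonloop, mf_n, land["N"],
                                               fvfrac, y0, ymult["N"])
            net_l = prod_l - sum(prd.non_marketing_outflows(prod_l, fem["L"], pcfg))
            net_n = prod_n - sum(prd.non_marketing_outflows(prod_n, fem["N"], pcfg))

            # -- participation and market split --------------------------
            l_margin, l_sf = channel_stats(lw["supply"], lw["sold"], lw["net"])
            n_margin, n_sf = channel_stats(nw["supply"], nw["sold"], nw["net"])
            if morning:
                share = mch.loop_participation_share(
                    l_margin, n_margin, l_sf, n_sf, mcfg, profit_norm=ref
                )
                loop_agg = net_l * share
                transfer = net_l - loop_agg
                loop_sup = {"A": loop_agg * pref_a / 100.0, "B": 0.0}
                loop_sup["B"] = loop_agg - loop_sup["A"]
            else:
                share = 0.0
                loop_agg = 0.0
                transfer = net_l  # zero: no Loop production in the afternoon
                loop_sup = {"A": 0.0, "B": 0.0}
            nl_supply = net_n + transfer
            frac_a = mch.nonloop_market_split(mcfg.nonloop_share_A, nl_noise[t],
                                              mcfg.nonloop_noise_bound)
            nl_sup = {"A": nl_supply * frac_a, "B": nl_supply * (1.0 - frac_a)}

            # external demand growth lifts all downstream demand (retail
            # customers directly; wholesaler/export offtake via the same
            # behaviour-change multiplier)
            years = max(0.0, t - t0_scen) / _HALF_DAYS_PER_YEAR if scen_on else 0.0
            growth_mult = (1.0 + growth) ** years if growth > 0.0 else 1.0

            # -- per-market trading --------------------------------------
            sold_loop = {"A": 0.0, "B": 0.0}
            rev_loop = {"A": 0.0, "B": 0.0}
            sold_nl = 0.0
            rev_nl = 0.0
            retail_price = {}
            for m in ("A", "B"):
                chs = cohorts[m]
                supply_l = loop_sup[m]
                supply = supply_l + nl_sup[m]
                frac_l = supply_l / supply if supply > eps else 0.0

                active = np.array([not (c.morning_only and not morning)
                                   for c in chs])
                prices = np.array([c.price14.mean() for c in chs])
                sfs = np.array([c.sf14.mean() for c in chs])
                alloc = mch.trader_allocation(supply, prices, sfs, mcfg,
                                              price_norm=ref, active=active)
                alloc_share = alloc / supply if supply > eps else np.zeros(len(chs))

                # first pass: capacities, purchase limits, first-choice offers
                caps = np.zeros(len(chs))
                limits = np.zeros(len(chs))
                shares_cap = np.zeros(len(chs))
                purch1 = np.zeros(len(chs))
                for k, c in enumerate(chs):
                    if not active[k]:
                        continue
                    if c.cap_per_trader is None:
                        caps[k] = cust_total[m] * cur_demand[m]
                    else:
                        caps[k] = c.count * c.cap_per_trader * growth_mult
                    carried_in = c.queue.total
                    limits[k] = max(0.0, caps[k] - carried_in)
                    if store_on:
                        shares_cap[k] = cap_store[m] * alloc_share[k]
                        limits[k] += max(0.0, shares_cap[k] - carried_in)
                    purch1[k] = min(alloc[k], limits[k])
                # spillover: supply refused by a saturated trader type is
                # re-offered once, pro rata, to types with spare headroom
                leftover = float(np.sum(alloc[active] - purch1[active]))
                spare = np.where(active, limits - purch1, 0.0)
                spare_sum = float(spare.sum())
                extra = np.zeros(len(chs))
                if leftover > eps and spare_sum > eps:
                    extra = spare * min(1.0, leftover / spare_sum)

                sales_total = 0.0
                purch_total = 0.0
                stored = 0.0
                spoiled_m = 0.0
                psum = 0.0
                pw = 0.0
                qsum = 0.0
                qn = 0
                for k, c in enumerate(chs):
                    if not active[k]:
                        c.profit60.push(0.0)
                        continue
                    cap = caps[k]
                    s_c = alloc[k] + extra[k]
                    carried_in = c.queue.total
                    cap_share = shares_cap[k]
                    purchases = min(purch1[k] + extra[k], limits[k])
                    offered = mkt.offered_price(ref, carried_in + s_c, cap, kcfg)
                    qp_l = mkt.quality_adjusted_price(offered, h_l[t])
                    qp_n = mkt.quality_adjusted_price(offered, h_n[t])
                    purch_l = purchases * frac_l
                    purch_n = purchases - purch_l
                    bill = purch_l * qp_l + purch_n * qp_n
                    avg_qp = bill / purchases if purchases > eps else \
                        mkt.quality_adjusted_price(offered, 0.5 * (h_l[t] + h_n[t]))

                    sales = min(carried_in + purchases, cap)
                    sold_old = c.queue.take(min(carried_in, sales))
                    unsold_new = max(0.0, purchases - (sales - sold_old))
                    shelf = kcfg.shelf_life_cold if store_on else kcfg.shelf_life_base
                    carried, spoiled = mkt.spoilage_update(
                        c.queue, unsold_new, shelf,
                        cap_share if store_on else None,
                    )
                    rent = kcfg.storage_rent * carried if store_on else 0.0
                    sell_price = avg_qp * (1.0 + c.margin)
                    # equivalent to trader_profit() with wastage = spoilage:
                    # revenue on what moved, full purchase bill, rent + misc
                    profit = sales * sell_price - bill - rent - c.misc_cost
                    resid = abs((carried_in + purchases)
                                - (sales + spoiled + carried))
                    if resid > max_resid:
                        max_resid = resid

                    c.price14.push(avg_qp)
                    c.sf14.push(purchases / s_c if s_c > eps else 1.0)
                    c.profit60.push(profit)
                    c.count = mkt.trader_entry_exit(c.count, c.profit60.total, kcfg,
                                                    count_max=c.count_max)

                    sales_total += sales
                    purch_total += purchases
                    stored += carried
                    spoiled_m += spoiled
                    psum += avg_qp * purchases
                    pw += purchases
                    qsum += avg_qp
                    qn += 1
                    sold_loop[m] += purch_l
                    rev_loop[m] += purch_l * qp_l
                    sold_nl += purch_n
                    rev_nl += purch_n * qp_n
                    if c.cap_per_trader is None:
                        retail_price[m] = avg_qp * (1.0 + c.margin)
                        if m == "B" and cust_total["B"] > 0:
                            rec["purchases_per_customer_B"][t] = (
                                sales / cust_total["B"]
                            )
                            rec["retail_price_B"][t] = retail_price[m]

                rec[f"market_{m}_supply"][t] = supply
                rec[f"market_{m}_sales"][t] = sales_total
                # purchase-weighted price; with no trade, the mean quoted
                # (offered, quality-adjusted) price is recorded instead
                rec[f"price_{m}"][t] = psum / pw if pw > eps else (
                    qsum / qn if qn else ref
                )
                rec[f"stored_{m}"][t] = stored
                rec[f"spoiled_{m}"][t] = spoiled_m
                rec[f"traders_{m}"][t] = sum(c.count for c in chs)

            # -- retail demand adjustment --------------------------------
            for m in ("A", "B"):
                rp = retail_price.get(m)
                if rp and rp > 0:
                    target = dmd.target_demand(
                        rp, dmd.reference_retail_price(dcfg, m),
                        dcfg.reference_demand, dmd.elasticity_for(dcfg, m),
                        growth, years,
                    )
                    cur_demand[m] = dmd.smooth_demand(
                        cur_demand[m], target, dcfg.smoothing_half_days
                    )

            # -- farmer accounting ---------------------------------------
            if date <= launch_end:
                sub_a, sub_b = mcfg.launch_subsidy, mcfg.launch_subsidy
            else:
                sub_a, sub_b = 0.0, (sub_b_scen if scen_on else 0.0)
            tc_a = mch.aggregation_transport_cost(
                mcfg.transport_loop_A_min, mcfg.transport_loop_A_max,
                loop_agg, mcfg.transport_scale_kg, tc_loop_u[t],
            )
            tc_b = mch.aggregation_transport_cost(
                mcfg.transport_loop_B_min, mcfg.transport_loop_B_max,
                loop_agg, mcfg.transport_scale_kg, tc_loop_u[t],
            )
            fee_a = loop_sup["A"] * tc_a * (1.0 - sub_a)
            fee_b = loop_sup["B"] * tc_b * (1.0 - sub_b)
            rev_l_total = rev_loop["A"] + rev_loop["B"]
            loop_net = rev_l_total * (1.0 - mcfg.commission_rate) - fee_a - fee_b

            nl_fee = nl_sup["A"] * tc_self_a[t] + nl_sup["B"] * tc_self_b[t]
            nl_net = rev_nl * (1.0 - mcfg.commission_rate) - nl_fee
            share_tr = transfer / nl_supply if nl_supply > eps else 0.0
            credit = share_tr * nl_net

            profit_l = (loop_net + credit) / n_loop - cost_l[t] if n_loop > eps \
                else -cost_l[t]
            profit_n = nl_net * (1.0 - share_tr) / n_nonloop - cost_n[t] \
                if n_nonloop > eps else -cost_n[t]
            cumprof["L"] += profit_l
            cumprof["N"] += profit_n

            # -- behavioural stocks --------------------------------------
            sold_l_total = sold_loop["A"] + sold_loop["B"]
            if morning:
                lw["supply"].push(loop_agg)
                lw["sold"].push(sold_l_total)
                lw["net"].push(loop_net)
                for m in ("A", "B"):
                    mk_sup[m].push(loop_sup[m])
                    mk_sold[m].push(sold_loop[m])
                    net_m = rev_loop[m] * (1.0 - mcfg.commission_rate) - (
                        fee_a if m == "A" else fee_b
                    )
                    mk_net[m].push(net_m)
                margin_now = loop_net / loop_agg if loop_agg > eps else 0.0
                sf_now = min(1.0, sold_l_total / loop_agg) if loop_agg > eps else 1.0
                tw_margin.push(margin_now)
                tw_sales.push(sf_now)
                trust = adp.update_trust(trust, tw_margin.trend(),
                                         tw_sales.trend(), acfg)
                # market preference from trailing per-market statistics;
                # a market with no recent supplies keeps its last observed
                # statistics (a remembered scarcity premium can pull the
                # preference back off its clamp).
                for m in ("A", "B"):
                    sup_m = mk_sup[m].total
                    if sup_m > eps:
                        last_mstats[m] = (mk_net[m].total / sup_m,
                                          min(1.0, mk_sold[m].total / sup_m))
                pref_a = mch.update_market_preference(
                    pref_a, last_mstats["A"][0], last_mstats["B"][0],
                    last_mstats["A"][1], last_mstats["B"][1], mcfg,
                    profit_norm=ref,
                )
            nw["supply"].push(nl_supply)
            nw["sold"].push(sold_nl)
            nw["net"].push(nl_net)

            # -- adoption -------------------------------------------------
            l_margin, l_sf = channel_stats(lw["supply"], lw["sold"], lw["net"])
            n_margin2, n_sf2 = channel_stats(nw["supply"], nw["sold"], nw["net"])
            util = adp.loop_utility(l_margin, n_margin2, l_sf, n_sf2, acfg)
            state = adp.AdoptionState(n_loop, n_nonloop, trust)
            p_now = p_scen if scen_on else acfg.extension_rate
            adoptions, disadoptions = adp.adoption_flow(state, acfg, util,
                                                        extension_rate=p_now)
            n_loop = min(total, max(0.0, n_loop + adoptions - disadoptions))
            dev = abs((n_loop + (total - n_loop)) - total)
            if dev > max_pop_dev:
                max_pop_dev = dev

            # -- record ---------------------------------------------------
            rec["loop_farmers"][t] = n_loop
            rec["trust"][t] = trust
            rec["utility"][t] = util
            rec["pref_A"][t] = pref_a
            rec["participation"][t] = share
            rec["loop_supply_A"][t] = loop_sup["A"]
            rec["loop_supply_B"][t] = loop_sup["B"]
            rec["loop_sold_A"][t] = sold_loop["A"]
            rec["loop_sold_B"][t] = sold_loop["B"]
            rec["nonloop_supply_A"][t] = nl_sup["A"]
            rec["nonloop_supply_B"][t] = nl_sup["B"]
            rec["demand_B"][t] = cur_demand["B"]
            rec["profit_loop"][t] = profit_l
            rec["profit_nonloop"][t] = profit_n
            rec["roi_fees"][t] = fee_a + fee_b
            rec["roi_kg"][t] = sold_l_total
            rec["yield_mult_loop"][t] = ymult["L"]
            rec["loop_net"][t] = loop_net
            rec["loop_credit"][t] = credit

            if not np.isfinite(n_loop) or not np.isfinite(cumprof["L"]):
                raise SimulationDiverged(
                    f"non-finite stock at half-day {t + 1} ({date} {hd.phase})"
                )

        return SimulationResult(
            config=cfg, scenario=scen, seed=seed, arrays=rec,
            start_date=start, end_date=end,
            max_balance_residual=max_resid,
            max_population_deviation=max_pop_dev,
        )
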