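# Methods

`loopsim` is a system-dynamics simulator of a smallholder fruit-and-vegetable
(F&V) value chain in Bihar, India, organised around a village-level
aggregation scheme ("the Loop"): an aggregator pools members' produce each
morning and trucks it to market on their behalf. Two markets compete for the
produce — a large urban wholesale market (**Market A**) and a small
retail-oriented local market (**Market B**). The model asks under which
combinations of four upgrades — scaling up aggregation membership,
subsidising transport to Market B, market-based cold storage, and external
retail demand growth — the system reaches a *win-win-win*: more F&V
purchased per customer in the small market, higher cumulative profit per
aggregating farmer, and a sustainable scheme (fees collected cover the
0.1 Rs/kg paid to aggregators).

## Time base and calendar

The simulation advances in **half-days** (a morning and an afternoon market
session per day) from 2017-10-01 to 2021-09-30 — 2922 half-days, integrated
with an explicit forward-Euler step at the system's native Δt of one
half-day. Three cropping seasons partition the year: Rabi (Oct–Feb), Zaid
(Mar–May) and Kharif (Jun–Sep). Farmers market once every 5/7/8 days in
Rabi/Zaid/Kharif respectively; aggregation happens only in the morning
session, self-supplying farmers use both sessions. Future scenarios switch
on at 2018-10-01 (half-day 731 by this indexing; the first model year is
the historical calibration/evaluation period).

## State and flows

Stocks: member and non-member farmer populations (total fixed at 12,087;
90 initial members), a trust stock in [0,1], a Market-A preference stock in
[0,100]%, per-farmer cumulative profit for both populations, yield
multipliers and land areas, trader counts for five cohorts (Market A:
distance traders, wholesalers, retailers; Market B: wholesalers, retailers),
FIFO age-queues of unsold trader stock, and smoothed per-customer retail
demand in each market.

Each half-day:

1. **Production.** Marketable output = farmers marketing this session ×
   land × share of land under F&V × seasonal yield × investment multiplier.
   The F&V land share cycles seasonally (peak ≈0.80 mid-Rabi, trough ≈0.50
   in Kharif, 0.65 in Zaid, linearly interpolated) and is modulated within
   ±20% by the F&V/staple price ratio through a saturating response.
   Own consumption (10%, +10% in female-headed households), gifts (4%) and
   pre-farmgate losses (8%) are deducted before marketing.
2. **Participation and market choice.** A bounded logistic of the
   trailing-week comparison between the aggregation and self-supply
   channels (guaranteed-sales fraction weighted 0.6, per-kg margin 0.4)
   sets the share of the morning cohort that aggregates; the rest is
   marketed through the self-supply channel, with its net revenue credited
   back pro rata. The Market-A preference stock drifts with the trailing
   difference in per-kg net margin and sales fraction between markets;
   non-members split ~90/10 toward Market A with ±10% per-step noise.
3. **Trading.** Within each market, supply splits across trader cohorts by
   a softmax over each cohort's trailing price and sales fraction. Offered
   prices anchor on the distance traders' expected price — a weekly
   reference series — scaled by (downstream demand / availability)^η
   clamped to [0.5, 1.5]; low-grade produce (a uniform 60–100% high-grade
   draw per population per half-day) earns half price. Purchases are capped
   by remaining capacity (plus any cold-storage headroom); supply refused
   by a saturated cohort is re-offered once to cohorts with spare headroom.
   Unsold trader stock ages in half-day FIFO cohorts: shelf life 4
   half-days, or 42 with cold storage; with storage active, carried stock
   beyond the cohort's capacity share spoils, and carried stock pays
   0.15 Rs/kg/half-day rent. Trader entries follow positive trailing-month
   cohort profits; counts decay while losing money and are capped at 1.5×
   their baseline (stall space).
4. **Retail demand.** Customer demand responds to the retail price with a
   constant elasticity (urban −0.6, rural −0.9), compounds with the
   external growth scenario, and adjusts by first-order smoothing over 14
   half-days (consumers revisit their demand about weekly). The scenario's
   growth multiplier also lifts wholesaler/export downstream demand.
5. **Farmer accounting.** Channel revenue minus 5% commission and per-kg
   transport (aggregated: 0.50–0.85 Rs/kg to A, 0.80–1.10 to B, both 50%
   subsidised during the scheme's first year; self-supply: 1.00–1.50) gives
   the channel net; per-farmer profit subtracts truncated-normal household
   production/labour costs (35 Rs/day). At each season start, 20% of
   cumulative profit buys land if it exceeds the cost of one-tenth katha
   (7,600 Rs at 76,000 Rs/katha), and 10% buys yield gains at 1% per
   Rs 20,000, capped at +1.5%/year.
6. **Membership.** Adoption follows a two-channel innovation-diffusion
   flow — extension (p, per 1000 non-members/half-day; the scaling-up
   scenario) plus word-of-mouth (q) — multiplicatively gated by trust and
   by the relative utility of aggregation (profit and sales-fraction ratios
   clamped to [0,2], parity = 1). Trust moves with the sign of the
   trailing-month trends in member margin and guaranteed sales.
   Dis-adoption drains members in proportion to distrust.

All stochastic inputs (quality draws, transport costs, non-member split
noise, household costs, the synthetic price fixtures) are pre-drawn from
independent streams spawned from one seed. A scenario run and its
do-nothing baseline therefore share identical noise (common random
numbers), so outcome deltas isolate scenario effects.

## Scenarios, outcomes and classification

Four scenario magnitudes are drawn uniformly: extension rate 0–0.274
farmers/1000 non-members/half-day, Market-B transport subsidy 0–100%,
cold-storage activation (active iff the [0,1] draw ≥ 0.5) with investment
level 0–3 (one level = 25,000 kg/half-day in A, 5,000 in B), and reference
demand growth 0–10%/yr. A phase-2 refinement samples the narrower ranges
0.035–0.086, 0–50%, 0–0.62 and 7.5–10%/yr.

Each run is reduced to three outcomes over the scenario horizon: cumulative
purchases per Market-B customer (kg), cumulative profit per member farmer
(Rs), and mean scheme ROI — per-half-day transport fees collected
(post-subsidy) over 0.1 Rs/kg sold, averaged over half-days with sales.
Against the paired baseline, a dimension "wins" iff strictly greater (ties
are losses); the eight sign-octants collapse to six categories from
`win_win_win` to `lose_lose_lose`. Within each category, "core" members lie
farther from the baseline than the category's mean + 1 SD of 3-D Euclidean
distance, computed on z-scored dimensions (the dimensions carry different
units; a raw-units mode is selectable).

## Sensitivity and calibration machinery

Every scalar configuration constant can be perturbed multiplicatively,
V = V₀·ε with ε ~ U(0.75, 1.25) (one-at-a-time) or jointly at ±5/±10/±25%
(two-stage multivariable design). Behaviour reproduction is scored against
**constraint corridors**: a LOESS (locally weighted, degree-1, span 0.3)
fit to an observed series with a pointwise band of ±1.96 residual standard
deviations — the level at which a series regenerated with the same noise
keeps ≈95% of its points inside. The band is deliberately a *prediction*
band, not a mean-confidence band: coverage is judged on raw model output
values, so the corridor must accommodate observation-level noise.
Coverage ≥0.95 marks a variable insensitive, [0.90, 0.95) "yellow", <0.90
"red". A two-sample Kolmogorov–Smirnov test (exact null below n=30)
compares the ε draws of behaviour-giving (run coverage ≥95%) versus
non-giving runs; p < α flags the parameter as influential.

The corridor targets are daily aggregated sales into Market A and the
member count over 2018-03-01 to 2018-08-25 (356 half-days). Because the
originating dashboard data is not public, the fixture module synthesises
pseudo-observations: baseline-run trajectories with multiplicative
lognormal noise (σ = 0.05).

## Synthetic fixtures

The non-public inputs are emulated with documented statistical structure:
a weekly wholesale reference price (12 Rs/kg mean, ±30% seasonal sinusoid
peaking in the lean season, lognormal weekly noise, one 52-week template
tiled over the horizon — mirroring how a single observed price year is
repeated), a staple-price series in antiphase (20 Rs/kg), and
truncated-normal household cost components (production 15 ± 5, labour
20 ± 10 Rs/day, halved into half-day costs). What the fixtures do *not*
emulate: real price spikes from weather shocks, festival demand surges,
within-season yield autocorrelation, or any correlation between costs and
farm size. Passing tests therefore demonstrate internal consistency of the
machinery and qualitative system behaviour, not predictive fidelity for
the real chain.

## Parameter provenance and key defaults

Printed, locked constants (asserted by tests): the farmer population and
initial membership, marketing intervals, transport cost ranges, trader
capacities (2,000 and 600 kg/trader/half-day), peak-Rabi market capacities
(~100,000 / ~20,000 kg/day), quality range and half-price rule, the land
and yield investment rules, storage capacities/rent/shelf-life, the
aggregator compensation rate, and all scenario ranges.

Unpublished constants are config defaults chosen once for a coherent
baseline and exposed to the sensitivity machinery. The notable ones, with
rationale:

* land 2,000 m²/farmer and seasonal yields 0.031/0.022/0.018 kg/m² per
  marketing trip — sized so peak-Rabi supply ≈ the printed ~120,000 kg/day
  combined market capacity;
* trader counts 25/33/350 (A) and 12/190 (B) — reproduce the printed
  peak-Rabi capacities with the printed per-trader capacities;
* price exponent η = 0.5, clamp [0.5, 1.5] — lean-season scarcity then
  yields roughly the observed 1.5–2× seasonal price swing;
* choice weights: sales 0.6 vs profit 0.4 everywhere, encoding the
  stakeholder emphasis on marketing security over price;
* softmax slope 10 for trader choice, logistic slope 6 and floor 0.5 for
  participation, preference adjustment 0.5 points/half-day;
* diffusion q = 0.0012/half-day and dis-adoption 0.0002 — slow organic
  growth from 90 members (×~8 over four years) absent extension;
* household costs 35 Rs/day against ~55 Rs/day average marketing revenue —
  modest positive farmer margins (~5–7,000 Rs/yr).

## Design choices where the design was open

* **Trust/utility composition.** Multiplicative gates on both diffusion
  channels, normalised to 1 at parity; ratio clamp [0,2] with both-negative
  treated as parity. Dis-adoption is trust-driven by default
  (utility-driven and mixed modes are selectable).
* **Trader count ceiling.** Pure entries-proportional-to-profits growth
  inflates handling capacity without bound, pinning all prices at the
  scarcity clamp and deadening every feedback; counts are therefore capped
  at 1.5× baseline, read as physical stall space.
* **Fixed customer population.** The retail customer base per market is
  fixed at (initial retailers × customers/retailer); retailer entry
  redistributes the same customers rather than conjuring new ones, so the
  per-customer purchase outcome is not mechanically diluted by entry.
* **Second-pass clearing.** Supply refused by a saturated trader type is
  re-offered once to types with spare capacity — farmers do not dump
  produce while the neighbouring stall has headroom. Without it, the
  softmax's slow trailing-signal adjustment strands several percent of
  supply in every glut.
* **Unsupplied-market memory.** The preference stock uses the last
  observed statistics of a market that currently receives no supplies,
  so a remembered scarcity premium can pull the preference back off its
  0/100 clamp.
* **Launch subsidy.** The scheme's first-year transport subsidy is a flat
  50% on both routes, expiring 2018-09-30; the scenario subsidy applies to
  the Market-B route only, from the scenario start.
* **Demand growth.** Compounded per half-day ((1+g)^years, a year =
  730.5 half-days) and applied to all downstream demand — retail reference
  demand directly, wholesaler/export offtake through the same multiplier —
  reading the scenario as market-wide behaviour change.
* **Optional transport scale economy.** `transport_scale_kg > 0` makes
  fuller aggregation loads cheaper per kg within the printed ranges; off
  by default because collected fees per kg then fall with volume, pushing
  scheme ROI down exactly where membership scales up.

## Numerical notes

Stocks are continuous (fractional farmers and traders are population
averages). Flows are capped so no stock goes negative; the farmer total is
conserved exactly by construction and per-market mass balance
(carried-in + purchases = sales + spoilage + carried-out) closes to
floating-point precision, both asserted over full runs. Zero-supply and
zero-trader conditions degrade gracefully (no sales; prices at the
scarcity clamp). Trailing statistics use O(1) ring buffers (7 mornings for
the aggregation channel, 14 half-days for self-supply and trader signals,
30+30 mornings for trust trends). A run over the full horizon takes well
under a second, so the shipped analyses use scaled ensembles — 100–200
phase-1 runs and ~80 phase-2 runs with a paired baseline each, and
20–50 simulations per sensitivity stage — as the package's standard
desk-scale design (full study scale is 5,000/500).

## Known limitations

* The parameterisation is synthetic-coherent, not data-fitted: headline
  ensemble fractions (e.g. the share of win-win-win futures) are not
  comparable to values estimated on the proprietary dashboard data.
* Under these defaults the scenario space produces no region where member
  profits rise while Market-B purchases fall: supply-side upgrades
  (extension, storage) depress per-kg margins through the same price
  feedback that raises availability, and the profit-positive levers
  (subsidy, demand growth) raise availability too. The "profit wins"
  category is therefore empty at ensemble scale, and conditional
  statements about its frequency across scenario ranges are vacuous here.
  The Market-A preference equilibrium sits at its upper clamp (matching
  the observed ~95% urban flow), which mutes the market-switching pathway
  that would otherwise generate profit-wins.
* Population-share formulation throughout: no farmer or consumer
  heterogeneity, no credit relations, no inter-market arbitrage shipments,
  and F&V is a single homogeneous commodity.
* The corridor machinery validates behaviour reproduction against
  *pseudo*-observations generated by the model itself plus noise; with
  real dashboard data the corridors would be fit to the observed series
  instead (same API).
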