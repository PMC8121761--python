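# loopsim

A system-dynamics simulator of a smallholder fruit-and-vegetable (F&V)
value chain built around village-level aggregation in Bihar, India — for
food-systems researchers and development practitioners who want to
horizon-scan value-chain upgrades for producer-versus-consumer trade-offs
before trialling them in the field.

An aggregation scheme pools members' produce each morning and trucks it to
one of two markets: a large urban wholesale market ("Market A") or a small
retail-oriented market ("Market B"). The model simulates, at half-day
resolution over 2017-10-01 to 2021-09-30 (2922 half-days), the coupled
dynamics of seasonal production and land allocation, membership diffusion
(a Bass-type two-channel adoption flow gated by trust and relative
utility), daily participation and market choice, price formation anchored
on a weekly reference price, trader entry/exit, cold storage and spoilage,
elastic smoothed retail demand, and farmer profit accumulation with
end-of-season reinvestment.

A Monte-Carlo scenario engine samples four upgrade magnitudes — membership
extension rate (0–0.274 farmers/1000 non-members/half-day), Market-B
transport subsidy (0–100%), cold-storage activation and investment level
(0–3; one level = 25,000 kg/half-day in A, 5,000 in B), and external
demand growth (0–10%/yr) — runs each against a noise-matched do-nothing
baseline, and classifies every run on three outcome dimensions
(cumulative Market-B purchases per customer, cumulative profit per member
farmer, scheme ROI = fees collected / 0.1 Rs/kg aggregator compensation)
into six trade-off categories from `win_win_win` to `lose_lose_lose`.
A sensitivity toolkit perturbs any configuration constant (V = V₀·ε,
ε ∈ [0.75, 1.25]), scores behaviour reproduction against LOESS constraint
corridors, and screens influential parameters with a Kolmogorov–Smirnov
test. All non-public inputs are replaced by documented synthetic fixtures.

See `docs/methods.md` for the model description, parameter provenance and
limitations.

## Worked example

```python
from loopsim import ValueChainModel, ScenarioVector

baseline = ValueChainModel().simulate(seed=1)
print(baseline.summary())

scenario = ScenarioVector(subsidy_B=100.0, demand_growth=5.0)
upgraded = ValueChainModel(scenario=scenario).simulate(seed=1)

from loopsim.outcomes import classify
print(classify(upgraded.outcome_triple(), baseline.outcome_triple()))
```

prints

```
Value-chain simulation summary
------------------------------
horizon: 2017-10-01 .. 2021-09-30 (2922 half-days), seed 1
scenario: baseline (do nothing)
final Loop farmers: 735.2 (initial 90)
final trust: 0.594; final Market-A preference: 100.0%
cumulative purchases per Market-B customer: 80.30 kg
cumulative profit per Loop farmer: 21867 Rs
mean scheme ROI: 6.781
max mass-balance residual: 0.000e+00 kg
access_profit_wins
```

Membership grows organically about eightfold over four years; nearly all
aggregated produce flows to the urban market (the preference stock sits at
its upper clamp, matching the ~95% urban share observed in such schemes);
farmers clear roughly 5–7,000 Rs/year. The fully subsidised Market-B route
plus 5%/yr demand growth raises both small-market purchases and farmer
profit relative to the paired baseline — but the forgone fee income pulls
the scheme's ROI below baseline, hence `access_profit_wins` rather than
`win_win_win`.

The same machinery scales to ensembles:

```python
from loopsim import EnsembleSpec, run_ensemble
table = run_ensemble(EnsembleSpec(n_runs=100, master_seed=7))
print(table["category"].value_counts())
```

or from the shell:

```bash
loopsim simulate --seed 1
loopsim ensemble --phase 1 --n-runs 100 --seed 7 --out runs/
loopsim classify runs/ensemble.csv --dimension cs_level
loopsim sensitivity --seed 1 --n-sims 10 --out sens/
loopsim fixtures --seed 1 --out inputs/
```

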