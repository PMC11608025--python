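# trophodyn

Catch-based trophic indicators for annual fisheries landings statistics.

Fisheries agencies publish decades of annual landings by species and sector
(e.g. Taiwan's coastal fisheries within 12 nm vs offshore fisheries in the
12–200 nm EEZ band). `trophodyn` turns such long-format catch tables, paired
with a species catalog of trophic levels and migratory classes, into the
standard ecosystem indicators used to diagnose "fishing down the food web"
and fishery expansion, and summarises their long-term trends. It is written
for fisheries ecologists and managers who work with yearbook-style catch
statistics rather than stock-assessment data.

## Indicators

With `Y_ij` the catch of species *i* in year *j* and `TL_i` its trophic
level (from FishBase-style feeding studies):

* **Mean trophic level** — `MTL_j = Σ_i TL_i·Y_ij / Σ_i Y_ij`, the
  catch-weighted mean trophic level of the year's landings. A sustained
  decline is the classical fishing-down signal; an increase can reflect
  intensified targeting of high-TL stocks.
* **Fishing-in-Balance** — `FiB_j = log10(Y_j·(1/TE)^MTL_j) −
  log10(Y_0·(1/TE)^MTL_0)`, with transfer efficiency `TE = 0.10` and a
  fixed baseline year (default 1970). FiB is constant when a drop of one
  trophic level is energetically compensated by a ten-fold catch increase;
  negative values suggest catches below ecosystem-consistent expectations.
* **Contribution to trophic level** — `CTL_i = TL_i·Y_ij / Σ_i TL_i·Y_ij ×
  100%`, each species' share of the TL-weighted catch, used to rank the
  species driving MTL/FiB dynamics.

On top of the indicators the package provides

* **curation**: catalog validation, exclusion of taxa with unreliable
  trophic assignments (anchovies/larval fish, squid, bivalves, lobsters,
  crabs), restriction to the top-100 species by pooled landed mass;
* **cumulative exclusion scenarios**: all species → minus tuna → minus
  oceanic migrants → minus seasonal migrants (leaving the indigenous
  assemblage), with packaged species lists and retained-catch accounting;
* **per-decade trend summaries**: OLS per indicator × scenario × sector with
  R² and the two-sided slope p-value;
* **a synthetic yearbook generator** with analytic ground truth, including
  a fishing-down regime (high-TL indigenous species decay, low-TL species
  absorb the released mass) for end-to-end validation.

## Worked example

```python
from trophodyn import SyntheticConfig, TrophicDynamics, generate_fishing_down_dataset

cfg = SyntheticConfig(seed=1)                       # 100 species, 1970-2021
catalog, catch, truth = generate_fishing_down_dataset(cfg)
print("analytic per-decade MTL slope:", round(truth.mtl_per_decade, 4))

res = TrophicDynamics(catch, catalog).fit()
print(res.summary())
```

prints (abridged):

```
analytic per-decade MTL slope: -0.0639

Retained catch per scenario (% of curated mass, period-pooled):
sector        coastal  offshore
scenario
scenario_all    100.0     100.0
scenario_1       95.5      95.5
scenario_2       88.3      88.3
scenario_3       77.9      77.9

Linear trends (per-decade change, R², p):
indicator     scenario   sector  per_decade_change  r_squared p_display
      MTL scenario_all offshore              -0.06       0.98     <0.01
      FiB scenario_all offshore              -0.06       0.98     <0.01
      ...
      MTL   scenario_3 offshore              -0.08       0.98     <0.01
```

The fitted per-decade MTL change of −0.06 recovers the analytic slope of the
fishing-down regime (−0.0639): high-trophic-level indigenous species decline
at 2 %/yr while low-TL species replace their mass, dragging the mean trophic
level of the landings down by about 0.06–0.08 levels per decade. Retention
drops monotonically across the cumulative scenarios, and every trend is
tight (R² = 0.98) because the generator's noise (σ = 0.05, log-normal) is
small relative to the drift.

The same analysis runs from the shell on CSV inputs:

```sh
trophodyn simulate --seed 1 --out-catalog catalog.csv --out-catch catch.csv --out-truth truth.yaml
trophodyn mtl   --catch catch.csv --catalog catalog.csv --sector offshore --out mtl.csv
trophodyn fib   --catch catch.csv --catalog catalog.csv --sector coastal --scenario 2 --out fib.csv
trophodyn trends --catch catch.csv --catalog catalog.csv --out trends.csv
trophodyn run   --config run.yaml      # full pipeline: tables + manifest.json
```

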