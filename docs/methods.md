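# Methods

## Data model

The analysis operates on two tables. The **species catalog** assigns each
taxon a trophic level `TL_i` (dimensionless, constrained to [1, 5]; primary
producers = 1) and one of four migratory classes — `tuna`,
`oceanic_migratory`, `seasonal_migratory`, `indigenous` — that drive
scenario membership. Catalog keys are case-folded, whitespace-collapsed
scientific names; family-level rows without a binomial (e.g. a "moray eels"
group) are legal records keyed by a family tag. No fuzzy name matching or
synonym resolution is attempted: catch records whose species is absent from
the catalog are dropped and reported with their total mass, never silently.

The **catch table** is long-format annual landings, one row per
(year, sector, species), with at most one record per cell and non-negative
mass. Catch is stored internally in tonnes; yearbook-style inputs declared
as kg are divided by 1000 on read. A missing (year, sector, species) cell
means zero catch for indicator sums, but a year wholly absent from the data
is omitted from output series rather than zero-filled.

Curation mirrors the conventions of catch-based indicator studies: taxa
whose trophic assignment is unreliable (anchovies and larval fish prone to
misidentification; squid, bivalves, lobsters and crabs) carry an
`excluded_taxon` flag and are removed, and the analysis is restricted to the
top-N species (default N = 100) ranked by catch pooled over all years and
both sectors. Pooling the ranking across sectors, and breaking ties by
ascending species key, are package decisions made for determinism; a
per-sector ranking is not offered because nothing downstream depends on it.

## Indicators

For year *j*, `MTL_j = Σ_i TL_i·Y_ij / Σ_i Y_ij`. Years with zero total
catch yield a missing value, not zero. MTL is bounded by the trophic levels
of the species present, and is invariant under any global rescaling of the
catch column — properties the test suite asserts directly.

`FiB_j = log10(Y_j·(1/TE)^MTL_j) − log10(Y_0·(1/TE)^MTL_0)` with transfer
efficiency `TE = 0.10` and baseline year 1970 by default. Two choices here
deserve note. First, the logarithm base: the index is computed in base 10,
matching its standard formulation and the magnitude of published values
(roughly −1 to 2 for multi-decade landings series); a natural log would
rescale every value by ln 10. Second, the trophic-level term is the *same
year's MTL of the (scenario-filtered) catch*, not a per-species quantity —
this is what makes the formula evaluable from annual totals and is the
reading consistent with "mean TL of the total catch at year *i*". The
baseline year is set to exactly 0 rather than left to floating-point
cancellation.

`CTL_i = TL_i·Y_ij / Σ_i TL_i·Y_ij × 100%` per year. Annual values sum to
100% for every year with positive catch (asserted to 1e-9 relative in
tests). Period-average CTL is the arithmetic mean of annual CTL over the
window, with absence years counted as 0% — this weights the ranking toward
persistently important species; a presence-years-only mean is available via
`absent_as_zero=False`, and per-sector or pooled-sector computation via the
`sector` argument (rankings default to pooled sectors). The alternative
reading — CTL of period-pooled catches — is deliberately not the default:
"average CTL over a period" is interpreted as a mean of annual shares.

Indicator tables are displayed at 2 decimals; internal values keep full
precision.

## Scenarios

Exclusion scenarios are cumulative: `scenario_all` (no exclusion) ⊃
`scenario_1` (minus 5 tuna taxa) ⊃ `scenario_2` (minus 13 oceanic-migratory
taxa, including the Carcharhinidae family group) ⊃ `scenario_3` (minus 19
seasonally migratory taxa, leaving the indigenous assemblage). Each packaged
definition carries both the explicit species list and the corresponding
migratory classes; resolution removes the union, so the packaged lists work
on real catalogs while class-based removal covers synthetic or user
catalogs whose names differ. When an explicitly listed species appears in
the catalog under a class the scenario does not exclude, a warning is
emitted and the list wins — the lists are the operational definition, the
class column a cross-check. Two taxa (Trachurus japonicus, Sphyraena
barracuda) are known to sit ambiguously between the seasonal-migratory and
indigenous groupings in the source material; the packaged lists exclude
them in `scenario_3`.

Retained fraction is the period-pooled mass ratio `100·Σ filtered / Σ
baseline` per sector — one number per scenario × sector — not a mean of
annual ratios. Monotonicity of retention across the cumulative scenarios is
a structural invariant and is tested on every synthetic replicate.

## Trend summaries

Each indicator series is fitted by ordinary least squares against calendar
year (`scipy.stats.linregress`); the summary reports the per-decade change
(10 × slope), R² and the two-sided t-test p-value with n − 2 degrees of
freedom, with p < 0.01 displayed as "<0.01". At least three non-missing
points are required; missing years are skipped, never interpolated. A
constant series is reported with slope 0, R² 0 and p 1 (the zero-SS_tot
convention). No autocorrelation correction or multiple-testing adjustment is
applied — these are plain linear-trend descriptions, and serially
correlated indicator series will have optimistic p-values; treat them as
descriptive. The trend window defaults to the full series and is a
parameter, since published decade-rate statements sometimes refer to
sub-windows.

## Synthetic yearbook generator

The generator emulates the study conditions of a multi-decade yearbook
analysis: 52 annual records (1970–2021), 100 species apportioned
5/13/19/63% across the four migratory classes (largest-remainder rounding),
trophic levels drawn uniformly within per-class ranges (tuna 3.9–4.5,
oceanic 3.5–4.5, seasonal 2.8–4.4, indigenous 2.0–4.5), and every species'
catch split 15%/85% between the coastal and offshore sectors, echoing
systems where the offshore fleet takes over 80% of national landings.
Per-species base catches are log-normal around a 1000 t/yr median
(log-scale spread 1.0), giving the right-skewed species-abundance profile of
real landings and offshore totals on the order of 1e5 t.

Expected trajectories are exponential per class
(`base_i·exp(rate_class·(t−t0))`, default rates 0). Observation noise is
multiplicative log-normal with σ = 0.05 and a mean-preserving correction
(log-mean −σ²/2), so the noiseless trajectory is the expectation of the
noisy one. Randomness is split into two streams: structural draws (trophic
levels, base catches) come from a fixed root keyed by a stable CRC-32 hash
of each species_id, so the ground truth is a function of the configuration
alone and adding a species never perturbs the others; the `seed` parameter
re-rolls only the observation noise, making replicate tables share one
analytic truth.

The fishing-down regime modifies the indigenous class: species above the
class-median TL decay as `exp(−r·t)` with r = 0.02/yr by default, and the
released mass is redistributed to the below-median species in proportion to
their base catches, keeping the indigenous total exactly constant in the
noiseless limit. The implied MTL trajectory is computed analytically from
the noiseless trajectories, and its per-decade slope (the OLS slope of that
deterministic series, ×10) is the recovery target for validation: over 200
noise replicates the pipeline's estimated per-decade MTL slope matches it
with |bias| < 0.01.

What the generator does **not** emulate: population dynamics (no
stock–recruitment or effort feedback — trajectories are phenomenological),
reporting gaps and species re-classifications over time, gear-level
structure, within-year seasonality, and cross-species noise correlation
(climate or market shocks hitting many species at once). Passing the
recovery tests therefore demonstrates that the pipeline is an unbiased,
correctly wired estimator under clean multiplicative noise — not that real
yearbook data meet those assumptions.

## Numerical and degenerate-input conventions

* Zero-catch years: missing MTL/FiB values; all-missing CTL rows.
* FiB requires a positive-catch baseline year; otherwise a configuration
  error rather than a silent shift of baseline.
* Share and retention denominators of zero produce missing values or
  explicit errors, never ±inf.
* Ranking ties (top-N selection, CTL ranking) break by ascending species
  key for determinism.
* Pipeline outputs are computed fully in memory before any file is written,
  so a failed run leaves no partial outputs; the run manifest records
  parameters and input checksums sufficient to reproduce a run exactly.

## Validation problem sizes

The test suite and the acceptance script use: brute-force formula oracles on
3-species × 5-year randomised tables (agreement to 1e-12; OLS to 1e-10
against a centred normal-equations solve), and a 200-replicate Monte-Carlo
recovery experiment at the default study conditions (100 species, 52 years,
σ = 0.05), chosen as the smallest design that pins the slope-recovery bias
well below the 0.01 per-decade acceptance band. Reproduction of the
published 1970–2021 yearbook-study tables requires that study's deposited
raw data at `data/supplementary/`; the corresponding test states this
requirement explicitly and fails (rather than skips) when the file is not
present, so the gap is visible.
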