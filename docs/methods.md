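# Methods

## Operating model

The simulated stock follows an annual-step Schaefer surplus production
model:

    B[y+1] = B[y] + g(B[y]) * (1 + eps[y]) - C[y],    g(B) = r B (1 - B/K)

* `B[y]` — biomass at the start of year `y` (catch units).
* `r` — intrinsic growth rate (1/year). Named life histories: slow 0.2,
  medium 0.6, fast 1.0; any positive value is accepted for custom stocks.
* `K` — carrying capacity, derived as `4 * MSY / r` with MSY fixed at 100
  catch units, so the production peak `rK/4` is identical across life
  histories and rules are directly comparable. Relative biomass `B/K`
  is the quantity rules and reference points operate on.
* `eps[y]` — biological variability (below); `eps = 0` recovers the
  deterministic model.

The model is deliberately minimal: single stock, no age or length
structure, no spatial structure, annual time step, logistic production.
Its role is to be a transparent test bed for rule behaviour, not a stock
assessment platform.

### Numerical guards

The difference equation can drive biomass negative when the catch limit
exceeds the available stock. Two guards keep the state admissible:

* realised catch is capped at 95% of start-of-year biomass
  (`CATCH_CAP_FRAC`); the projection engine counts binding events and the
  CLI exits with code 3 when the cap binds in more than half of all
  projection replicate-years, flagging a pathological rule;
* biomass is floored at `1e-6 * K` (`BIOMASS_FLOOR_FRAC`).

Both are configuration constants of the operating model, not claims about
the fishery; for sensible rules they never bind.

### Catch histories

Projections start from an exploited stock. Biomass begins at `K`
(the unfished level) in the first historical year and is fished down by a
10-year catch history (configurable; the last historical year is labelled
2019 by default):

* under-exploited — nominal catch constant at 2/3 MSY;
* fully-exploited — constant at MSY;
* over-exploited — linear ramp from 3/4 MSY to 4/3 MSY.

Each year's catch is `nominal * (1 + nu)`, `nu ~ N(0, sd)` i.i.d. with
sd 0.1 by default, floored at zero. The noise is multiplicative so the
same sd applies across life histories whose nominal catches differ.
History is propagated without biological variability; the stochasticity
of the historical period is the catch noise itself.

### Biological variability

Process noise on surplus production represents fluctuations in
recruitment, growth and natural mortality. It is a stationary AR(1)
sequence applied multiplicatively to `g(B)`:

    x[y] = rho * x[y-1] + sqrt(1 - rho^2) * sd * z[y],   z ~ N(0,1)

with the initial state drawn from the stationary distribution, so the
marginal standard deviation equals the configured `sd` (default 0.2) in
every year and the lag-1 autocorrelation equals `rho` (default 0.5,
configurable). Positive autocorrelation produces the runs of
better/worse-than-average growth that make rule robustness interesting;
`sd = 0` yields exactly zero noise regardless of `rho`. The AR(1) form
is this package's choice of a simple stationary positively-autocorrelated
process; both parameters are exposed in the configuration.

## Estimation step

No assessment model is run. The estimate the rule sees is

    Best = max(0, Btrue/K * (1 + bias + e)),   e ~ N(0, sd)

Multiplicative error keeps the estimation error proportional to stock
size, and `bias` (default 0) models a consistently over- or
under-estimating assessment as a clean scale factor. Estimates above 1
are not clamped — an over-estimate may exceed the unfished level and the
rule returns Cmax there anyway. The estimate observed at the start of a
year sets the catch limit applied during that year, and the limit is
taken exactly (no implementation error).

## Harvest rules

The threshold-catch ("hockey stick") rule has four parameters: catch is
Cmin at or below relative biomass Blim, Cmax at or above Belbow, linear
between the inflexion points (implemented with `np.interp`, which makes
the rule continuous, monotone and exact at both corners). Validity
requires 0 ≤ Cmin ≤ Cmax and 0 ≤ Blim < Belbow ≤ 1. A constant-catch
rule (fixed limit, ignores status) is included as the non-feedback
comparator. Note that the long-term stock level under a threshold rule
depends on all four parameters jointly; Belbow is not itself a target.

## Replicates and random numbers

One master seed drives everything. Replicate `i` draws from the
dedicated substream `SeedSequence(seed, spawn_key=(i,))`, so replicate
`i`'s trajectory depends only on `(seed, i)`: increasing the replicate
count never perturbs existing replicates, and replicates can be
reconstructed individually. Within a replicate the three noise vectors
(historical catch noise, AR(1) biological variability, estimation-error
normals) are drawn up front in a fixed order before the rule is
consulted. Two consequences:

* rules evaluated under the same seed see identical noise — common
  random numbers — which shrinks the Monte-Carlo variance of
  between-rule differences (basket evaluation defaults to this; an
  independent-seeding mode derives a separate sub-2^31 seed per rule);
* changing one noise setting to zero does not shift the draws of the
  others, so paired sensitivity runs stay paired.

History is redrawn per replicate by default (each replicate is a full
independent realisation); a shared-history mode reuses a single
historical draw across replicates when a common starting point is wanted.

Defaults: 250 replicates, 10 historical years, 30 projection years,
biological variability sd 0.2 / rho 0.5, estimation error and bias 0.

## Performance indicators

Computed over projection years, per replicate, from the true state
(biomass rows report the true relative biomass, not the estimate the
rule saw):

* **biomass** — B/K.
* **prob_above_lrp** — per-year fraction of replicates with B/K strictly
  above the limit reference point (LRP = 0.2); a risk measure, reported
  so that larger is better.
* **catch** — realised catch.
* **relative_cpue / relative_effort** — effort is `E = C/(qB)` with
  catchability q fixed at 1, CPUE is `C/E = qB`; both are scaled by
  their value in the last historical year of the same replicate. With
  constant q, CPUE is exactly proportional to biomass; the indicator is
  kept because the proportionality does not survive real-world
  hyperstability.
* **catch_stability** — `clamp(1 - |C[y] - C[y-1]| / Cvar_max, 0, 1)`
  with Cvar_max = K/10 by default; 1 means catches never change. The
  first projection year uses the last historical catch as its
  predecessor so every projection year has a value.
* **trp_proximity** — `clamp(1 - |B/K - TRP| / max(TRP, 1-TRP), 0, 1)`
  with TRP = 0.5; symmetric above/below the target.

The stability and proximity transforms are clamped into [0, 1] (the
clamp at 0 engages when a change exceeds Cvar_max or the stock is
farther from the target than the scaling distance).

### Period summaries

Projection years are split into three contiguous windows (short /
medium / long term), by default equal thirds with remainder years
assigned to the long window; the windows are overridable. Each
indicator is averaged per replicate within each window, then summarised
across replicates as the median with the 90th percentile range (5th and
95th percentiles) and the 80th range (10th and 90th), using numpy's
linear-interpolation quantile definition. The probability-above-LRP row
is already a cross-replicate proportion, so it is period-averaged and
its percentile columns are left blank rather than bootstrapped.

## Basket comparison

A basket is a set of uniquely-named rules evaluated under one scenario,
one configuration and one master seed (common random numbers unless
independent seeding is requested). The report is a pure function of
(basket, seed): re-running reproduces byte-identical CSVs. Reports can
be thinned by dropping indicators or rules; the provenance block records
the full configuration, the per-rule catch-cap binding fractions, and
everything dropped, so a filtered table cannot be mistaken for a
complete one. Bar/box figures are a convenience rendering of the table.

## What the simulations do and do not show

The generator produces exactly the study conditions described above: a
logistic single-stock dynamic at MSY 100, i.i.d. relative catch noise in
history, AR(1) production noise, multiplicative estimation error.
Passing tests demonstrate that the feedback loop, the rule algebra, the
indicator arithmetic and the seeding discipline are correct under those
conditions. They say nothing about structural uncertainty a real MSE
must face — age structure, regime shifts, hyperstable CPUE, assessment
lag, implementation error — all of which are out of scope here.

## Known limitations and numerical notes

* Under a constant catch exactly at MSY the map has derivative 1 at the
  fixed point B = K/2 (semistable): convergence from above is algebraic,
  `u[n] ~ K/(r n)`, so a stock fished down from K approaches relative
  biomass 0.5 only slowly (≈0.54 after 40 years for the medium stock,
  within 0.01 only after roughly 160 years). Tests of the fixed point
  therefore use long horizons.
* Problem sizes used in the checks: moment-recovery tests use 1e5-draw
  sequences (sampling error well below the asserted tolerances of
  ±0.005 on the sd and ±0.02 on the autocorrelation); the
  historical-noise sd is recovered from 1,000 independent 10-year
  histories (10,000 years), keeping each history short enough that the
  catch cap never binds under sustained MSY-level catches.
* Quantiles are linear-interpolation (numpy default); stated here
  because percentile conventions differ across tools.
* Effort/CPUE relative scaling divides by the last historical year's
  value; if that value is zero (possible only under a zero-catch custom
  history) the relative columns are NaN rather than inf.
* Degenerate inputs: single-year catch series have no stability value
  and are rejected; empty periods, duplicate rule names, and dropping
  every rule from a report are errors.
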