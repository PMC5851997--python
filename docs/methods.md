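# Methods

## Scope and model

`peatghg` computes a global inventory of greenhouse-gas emissions from
degrading (drained) peatlands and compares it, over time, against the
carbon-sequestration potential of agricultural mineral soils. The
accounting is deliberately simple and transparent: per-area emission
factors by land use and climate, explicit min/mean/max uncertainty
ranges, linear pool depletion, and a saturating mineral-soil sink. No
process-based peat decomposition model is attempted.

## Grid contract

All spatial operations act on an **equal-area cell grid**: every cell
has the same area in hectares. This is the only property the analysis
needs from a map projection, so the projection itself is out of scope;
any raster resampled to (approximately) equal-area cells satisfies the
contract. Rasters are exchanged on disk as CSV cell tables
(`cell_id, row, col, value`).

## Classification

*Land use.* ESA-GLC-style integer cover classes map to the IPCC classes
cropland (CL: codes 11, 14, 20), forest land (FL: 40, 50, 60, 70, 90,
100, 110, 130, 160, 170) and grassland (GL: 120, 140, 150, plus the
mixed-urban 190), with two mixed classes kept distinct (30 → CL/GL/FL,
180 → GL/FL) and non-assignable classes (200–230: water, bare,
snow/ice) excluded from all accounting. Unknown codes map to NONE with
a warning rather than an error, so dialectal rasters degrade gracefully.
A cropland-probability layer is then superimposed: cells with
probability **strictly greater than 0.5** become CL whatever their
prior class, except cells already excluded — exclusion happens before
the overlay and is not reversed.

*Climate.* Köppen classes collapse, by pure per-cell lookup, to three
emission-factor zones — tropical, temperate, boreal+polar (boreal and
polar share emission factors but remain separable as reporting
subzones, as does an oceanic tag on the maritime temperate classes).
The shipped Köppen→zone table is editable config: the three target
zones are fixed by the emission-factor structure, but the per-class
assignment (notably of the arid B classes, split here by their
hot/cold temperature regime) is an explicit, overridable choice.

The product of 5 land-use × 3 climate classes gives 15 emission
classes. Mapped stratum areas can be proportionally rescaled onto an
independent global area estimate (`rescale_areas`), which preserves all
pairwise proportions exactly.

## Degradation allocation

Degraded-area statistics exist per country. The allocation rule:

* Cropland on peat is always fully degrading (drainage precedes
  cropping): CL cells carry degradation fraction 1.
* With c = cropland-on-peat / peat area and d = degraded / peat area
  (clipped to [0, 1]): if d ≤ c the cropland area is taken as the
  better estimate and all non-CL peat gets fraction 0; if d > c the
  residual degraded area (d − c) × peat area is spread uniformly over
  the country's non-CL accountable peat — including the mixed classes,
  which are accountable non-CL peat.
* If the residual spread would exceed 1 (inconsistent statistics), the
  fraction is clipped at 1 with a warning. Countries absent from the
  statistics default to 0 outside CL (the non-degraded end of the
  scale) and only when the caller opts out of strict mode.

For every country on the d > c branch, the cell-level degraded area
(Σ degradation × cell area) reproduces the reported statistic exactly;
on the override branch the effective degraded area is the cropland
area. `degraded_area_check` reports both readings.

## Emissions

Per-gas emission factors (CO₂, CH₄, N₂O as gas-native mass; DOC as C
mass, assumed fully oxidized downstream) carry explicit
(min, mean, max) **ranges, not confidence intervals**; uncertainty
propagates by interval arithmetic (min with min, max with max) through
every operation, and the ordering min ≤ mean ≤ max is enforced
throughout. CO₂-equivalent aggregation uses configurable GWPs
(defaults: CH₄ 28, N₂O 265; a 100-year horizon without feedbacks).
Mixed-class factors combine their members with an unweighted mean of
means and the range envelope (min of mins, max of maxes), so the
combined range contains every member's range — the conservative
reading of "combination" under explicit-extremes uncertainty.

Potential emission = CO₂-eq rate × cell area (what the cell would emit
if drained); actual emission = potential × degradation fraction, hence
actual ≤ potential everywhere. Summaries aggregate per reporting
climate (tropical, temperate, boreal, polar, oceanic) with areas per
land-use column; totals rows are always computed, never stored.
Reported per-area rates are per area of *peatland*, not per degraded
area: a class half degraded reports half its potential rate.

The shipped per-gas EF table (`data/ef_synthetic.yaml`) is a
**synthetic stand-in** with realistic magnitudes for drained organic
soils; computations that must reproduce published aggregates run from
the packaged overview fixture instead (below).

## The overview fixture

`table1_fixture()` returns the published per-climate overview — peat
area by land-use column, degrading area, actual emissions
(min/mean/max) and C stocks — exactly as printed per row, with the
sub-0.1 oceanic row carried as 0. Totals are computed by summation, so
printed component rounding is visible rather than hidden: the row areas
sum to 463.1 Mha (printed total 463.2), the degrading stocks to
80.7 Gt C (printed 80.8), and the minimum emissions to 0.30 Gt CO₂-eq
(printed 0.31). All headline recomputation starts from this fixture.

## Nitrogen budgets

N stock = C stock / (C/N median). Zone medians are configured
constants: 29.7 (tropical peat), 49.0 (temperate/boreal/polar peat),
10.7 (mineral-soil organic matter); the derivation path for the
mineral median — exclude Histosols, C/N < 5 or > 100, organic C
concentration > 200 mg g⁻¹, then take the standard median — is
implemented and validated on synthetic sample tables whose clean
subpopulation has a known log-normal median. The three exclusion rules
are applied as independent OR-ed predicates; filtering is idempotent.

Mineral-soil C storage binds 1/10.7 ≈ 0.0935 kg N per kg C. Storing
the 24–64 Gt C sink capacity implies 2.24–5.98 Gt N, or 35.6–94.9 Mt N
a⁻¹ over 63 years. The N-cost ratio divides mineral N-per-C by the
peat budget's N-per-C (total release / total degrading C); from the
fixture's printed inputs it evaluates to ≈3.28 (published 3.4, formed
from unrounded simulation values — the difference is pure input
rounding, and the package reports the recomputed value).

## Trajectories and scenarios

*Peat.* Each degrading class emits at its constant C-equivalent rate
(CO₂-eq × 12/44) until its pool is exhausted: cumulative emission
min(rate·t, pool) per layer, summed over classes. Linear depletion is
the natural reading of constant per-area emission factors; the pool cap
is the only constraint the endpoint data impose. The all-GHG
C-equivalent flux draws down the C pool; callers wanting a CO₂+DOC-only
drawdown pass those rates instead.

*Mineral sink.* S(t) = S_max(1 − e^(−kt)) with k = ln(100)/63 a⁻¹, so
99% of S_max is reached at 63 years; S_max layers default to
{24, 44, 64} Gt C (the published range after its ±1/5 prudential
margin, and its midpoint). The functional form is pluggable
(`mineral_sink(form=...)`) because the source model's exact saturation
equation is not available here; any nondecreasing curve calibrated to
(S_max, 63 y) preserves the qualitative results, but **equivalence
points are form-dependent** (see Limitations).

*Equivalence point.* The first year cumulative peat emission ≥
cumulative sink, linearly interpolated between steps; +∞ if no crossing
within the horizon, t = 0 if the peat series never falls below the
sink. Layer pairing is "opposed" by default (earliest point from max
emissions vs min sink, latest from min emissions vs max sink), the
conservative envelope; matched pairing is available.

*Expansion scenario.* The degraded-area multiplier follows
M(t) = 1 + (m − 1)·t/(t + K) with asymptote m = 2 and K = 60 years:
newly degraded area enters as vintages carrying proportional pools and
rates, each depleting with the class's exhaustion time, so the
asymptotic cumulative release is m × Σ pools (161.4 Gt C from the
fixture's stocks). The asymptote is a *doubling* because the scenario's
cumulative cap equals twice the current stocks; the literal
"half-saturation = doubling at 60 y" reading would imply an asymptotic
tripling, which contradicts that cap, so M(60) = 1.5 here.

## Numerical choices

* Default time step 0.5 a, horizon 1200 a for the bundled report
  (chosen so the scenario's vintage superposition stays in-memory and
  fast); halving dt moves every crossing by < 1% (tested). The scenario
  warns if dt > K/10.
* Area rescaling preserves pairwise ratios to < 1e−9 relative error.
* Degraded-area conservation holds to 1e−6 relative error.
* Ties at the cropland threshold keep the prior class (strict >).
* Range validation rejects unordered triples at construction.

## Synthetic world

The generator emulates the input stack's statistical structure:
latitudinal climate bands (with a polar tail), per-band Bernoulli peat
extent, categorical land-cover draws matching target composition (half
of the intended cropland entering via the probability overlay, half via
cover codes), country stripes, and country statistics computed from the
realized maps so rasters and tables can never disagree. Defaults (256 ×
256 cells, 100 ha cells, peat fractions 0.20/0.10/0.40 by zone, land
use 15% CL / 25% GL / 45% FL / 10% mixed / 5% unassignable, country
degradation targets spanning both allocation branches) describe a
plausible northern-heavy peat world at a size where the full pipeline
runs in seconds. What passing tests on this world show: the
accounting's bookkeeping (area conservation, degraded-area
conservation, closed-form aggregate agreement within 2%) — not spatial
realism; there is no autocorrelation, basin geometry, or realistic
country-size distribution, so nothing here validates map-level pattern
claims. C/N populations are log-normal (strictly positive,
right-skewed, matching observed peat C/N spreads), with contamination
records violating exactly one exclusion rule each.

## Known limitations

* Equivalence points depend on the sink's functional form. With the
  default exponential saturation the mean crossing from the fixture is
  ≈84 years; the published analysis, using its source-specific
  saturation equation, reports 238 (140–1021) years. The package
  therefore asserts the *properties* of the crossing (existence,
  finiteness, > 63 years, monotonicity in rates and S_max, dt
  stability), not its published value, and the CLI report flags the
  form dependence.
* Peat-fire and mined-peat combustion fluxes are not modelled; CH₄
  rewetting credits are not modelled (all rates ≥ 0).
* Min/max totals are envelopes (perfectly correlated extremes across
  classes), the conservative reading of range uncertainty.
* The per-gas EF defaults are synthetic stand-ins; inventory-grade runs
  must supply an authoritative EF table via config.
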