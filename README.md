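# peatghg

Greenhouse-gas accounting for the world's degrading peatlands, and a
head-to-head comparison with soil carbon sequestration on agricultural
mineral soil.

Drained (degraded) peatlands are a large, persistent GHG source: peat
that accumulated over millennia oxidizes once the water table is
lowered for cropland, grassland or forestry. `peatghg` implements the
full accounting chain as a tested, reusable Python library:

1. **Grid classification** — an equal-area peatland cell grid is
   classified by IPCC land use (CL/GL/FL plus two mixed classes, from an
   ESA-GLC-style cover raster with a cropland-probability overlay at
   threshold 0.5) and by generic climate zone (tropical / temperate /
   boreal+polar, from a Köppen raster), yielding 5 × 3 = 15 emission
   classes.
2. **Degradation allocation** — country statistics of degraded peat
   area are turned into per-cell degradation fractions: cropland on
   peat is fully degrading (fraction 1); the residual reported degraded
   area is spread uniformly over the country's other peat land uses.
3. **Emission mapping** — per-class emission factors for CO₂, CH₄, N₂O
   and leached DOC are aggregated to CO₂-equivalents,
   `E = CO₂ + GWP_CH₄·CH₄ + GWP_N₂O·N₂O + (44/12)·DOC`,
   carrying explicit (min, mean, max) ranges through every step by
   interval arithmetic. Potential emissions (if drained) times the
   degradation map give actual emissions, summarized per climate zone.
4. **C/N budgets** — nitrogen stocks and avoidable releases follow from
   carbon stocks via C/N medians (tropical peat 29.7, northern peat
   49.0, mineral-soil organic matter 10.7, the latter derived from
   profile databases after excluding Histosols, C/N outside [5, 100]
   and organic C concentration > 200 mg g⁻¹).
5. **Trajectories** — each degrading class emits at a constant rate
   until its C pool is exhausted; the competing mineral-soil sink
   saturates at 24–64 Gt C within 63 years on 4923 Mha of agricultural
   land. Their crossing (the *equivalence point*) marks when cumulative
   peat emissions overtake the maximum mineral-soil sink. A
   Michaelis–Menten scenario doubles the exploited area asymptotically
   with a 60-year half-saturation.

A seeded synthetic-world generator emulates the full GIS input stack
(peat extent, land cover, cropland probability, Köppen classes, country
blocks, and matching country statistics), so the entire pipeline runs
and is testable without any download.

## Worked example

```python
import peatghg as pg

# the packaged per-climate overview: areas (Mha), actual emissions
# (Gt CO2-eq/a, min/mean/max) and peat C stocks (Gt C)
summary, budgets = pg.table1_fixture()
totals = pg.summary_totals(summary)
print(f"actual emissions: {totals['emission_mean_gt']:.2f} "
      f"({totals['emission_min_gt']:.2f}-{totals['emission_max_gt']:.2f}) Gt CO2-eq/a")
print(f"as carbon:        {pg.co2eq_to_ceq(totals['emission_mean_gt']):.2f} Gt CO2-C-eq/a")
print(f"avoidable N release: {pg.total_n_release(budgets):.2f} Gt N")
print(f"N cost ratio (mineral soil vs peat): {pg.n_cost_ratio(budgets):.2f}")
```

prints

```
actual emissions: 1.91 (0.30-3.38) Gt CO2-eq/a
as carbon:        0.52 Gt CO2-C-eq/a
avoidable N release: 2.30 Gt N
N cost ratio (mineral soil vs peat): 3.28
```

— i.e. today's degrading peatlands emit about 1.91 Gt CO₂-eq per year
(0.52 Gt as carbon mass), restoration could avoid a cumulative 2.30 Gt
of nitrogen release, and storing the same carbon in mineral soil would
bind roughly 3.3 times more nitrogen per unit carbon than peat releases.

The same numbers come from the command line, end to end:

```sh
peatghg synth --seed 1 --outdir world     # synthetic input stack
peatghg account --indir world             # classification -> emission summary
peatghg project                           # budgets, trajectories, report
```

`peatghg project` also writes `trajectories.csv` (cumulative peat
emissions, the mineral-soil sink, and the doubling scenario, per
uncertainty layer) and a report comparing every recomputed headline
number with its published estimate.

## Layout

| module | contents |
| --- | --- |
| `peatghg.grid` | land-cover/climate reclassification, emission classes, area rescaling |
| `peatghg.degradation` | country statistics → per-cell degradation fractions |
| `peatghg.emissions` | EF aggregation, potential/actual maps, per-climate summary |
| `peatghg.nitrogen` | C/N sample filtering, medians, N budgets |
| `peatghg.trajectory` | pool-exhaustion series, mineral sink, equivalence, scenarios |
| `peatghg.synthetic` | seeded world & C/N sample generators, overview fixture |
| `peatghg.io`, `peatghg.cli` | CSV cell-table rasters, YAML config, `peatghg` CLI |

See `docs/methods.md` for the model description, parameter defaults,
and known limitations.
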