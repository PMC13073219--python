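# dualdispatch

Simulation of out-of-hospital cardiac-arrest (OHCA) response times under
two dispatch strategies: sending the emergency medical service (EMS)
alone, versus *dual dispatch* — simultaneously alerting EMS and the local
volunteer fire service and counting the earlier arrival.

Survival after OHCA falls steeply with every minute before CPR starts.
Fire services are far more numerous than ambulance stations in many rural
regions (here ~13 fire stations per EMS station), but volunteer crews have
longer turnout times because members must first reach their station. The
question this package quantifies is whether dual dispatch still shortens
the time to curbside arrival, and by how much, as a function of turnout
time and local population density.

It is a library for epidemiologists and EMS planners, used from Python
(see `examples/`) with a thin `dualdispatch` CLI for batch runs.

## Model

For each simulated arrest *i* and service *s* ∈ {EMS, FIRE}:

    response_i(s) = turnout(s) + travel_i(s)

where `travel_i(s)` is the fastest-route driving time (Dijkstra on a road
graph weighted by minutes = 60·length/speed) from the event to the best of
its *k* = 10 Euclidean-nearest stations of service *s*. The two outcome
measures per event are `response_i(EMS)` (EMS-only) and
`min_s response_i(s)` (dual dispatch). Defaults: turnout 2 min (EMS),
5 min (fire), with 8 min as the standard sensitivity value.

Analyses: per-strategy summaries (mean, SD, percentiles, 10-min coverage,
fire-first fraction), a paired two-sided t-test of the per-event
difference, an exploratory sweep over fire turnout locating the value
beyond which the difference is no longer significant (α = 0.05), and a
Gaussian identity-link GLM

    response ~ β₀ + β_d·density + β_s·strategy + β_ds·density×strategy

with density in inhabitants/km² at the event's raster cell and
strategy = 1 for dual dispatch.

Because the real station locations, population raster and road network of
the studied region are not redistributable, the package generates a
*synthetic* study region with the same statistical structure: ~19,200 km²,
1.73 M inhabitants, heterogeneous density (rural background plus Gaussian
population clusters), a connected speed-classed road graph, 121 EMS and
1590 fire stations, and station-to-scene travel times spanning roughly
1–25 minutes. Adapters for real station GeoJSON and ESRI ASCII-grid
rasters feed the same pipeline.

## Worked example

```python
from dualdispatch import (
    GeographyConfig, Strategy, TurnoutConfig, compare_strategies,
    generate_geography, sample_events, simulate_responses, summarize,
)

region, network, stations = generate_geography(GeographyConfig(seed=42))
events = sample_events(region, network, 1000, seed=42)
records = simulate_responses(events, stations, network, TurnoutConfig(2.0, 5.0), k=10)

ems = summarize(records, Strategy.EMS_ONLY, thresholds=(10.0,))
dual = summarize(records, Strategy.DUAL, thresholds=(10.0,))
comp = compare_strategies(records)
```

Running `python examples/02_simulate_dispatch.py` (the same computation)
prints:

```
EMS-only: mean 9.8 min (SD 5.1), p90 16.9 min, 59.1% within 10 min
dual:     mean 5.8 min (SD 1.6), p90 7.7 min, 99.8% within 10 min
fire service first at 71.0% of events
paired t-test: mean reduction 4.0 min, p = 6.91e-124
```

Dual dispatch cuts the mean time to curbside arrival by about four
minutes on this synthetic draw and brings nearly every event inside the
clinically relevant 10-minute threshold; the volunteer fire service is
first on scene at most events despite its 3-minute turnout handicap. The
other examples show the geography generator, the turnout sweep (the
advantage disappears only once fire turnout reaches ~25 min), the density
GLM (β_density < 0, β_interaction > 0: the gain concentrates in sparsely
populated areas) and the persisted run-report workflow.

## CLI

```sh
dualdispatch generate --config geo.yaml --seed 42 --out geo/
dualdispatch simulate --out run/ --events 1000 --ems-turnout 2 --fire-turnout 5 --k 10
dualdispatch sweep    --run run/ --grid 2:25:1 --alpha 0.05
dualdispatch report   --run run/
```
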