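# Methods

## Scope and model

The package simulates response times to hypothetical out-of-hospital
cardiac arrests under EMS-only versus dual EMS + volunteer-fire dispatch.
The clock starts at alarm and ends at curbside arrival: response =
turnout + fastest-route travel. Dispatch-centre processing time and the
interval from curb to patient contact are outside the clock by
construction, as is everything a dispatch strategy cannot change. Unit
unavailability, simultaneous missions, day/night stratification and
crew-assembly dynamics are deliberately not modelled; the simulation
assumes the nearest units are always available, so its estimates are an
upper bound on the benefit of dual dispatch.

## Synthetic geography

All downstream stages run on a generated region so that the pipeline has
no external data dependency. The generator targets the structure of a
large, sparsely populated federal state with dense municipal fire
coverage:

- **Density raster.** A uniform rural background plus a mixture of
  isotropic Gaussian clusters (centres uniform, spreads uniform in
  2–8 km, relative masses lognormal), evaluated on a 2-km grid and
  renormalised so the raster mass equals the configured population
  exactly. Defaults: 160 × 120 km (19,200 km²), 1.73 M inhabitants,
  25 clusters holding ~60% of the pre-normalisation mass, background
  50 inhabitants/km². The background was chosen as roughly half the
  region-wide mean density (90/km²): low enough that the max/median
  contrast exceeds an order of magnitude, high enough that rural areas
  hold a realistic share of both events and stations.
- **Road graph.** Node cells are drawn with probability ∝ density + 50
  (the floor keeps rural road coverage), positions uniform within cells.
  Edges are a 4-nearest-neighbour scaffold; components are bridged at
  their closest node pairs, which guarantees a single connected
  component; 3% additional long-range (≥ 20 km) edges act as motorways.
  Edge length is Euclidean distance × 1.2 (winding factor); speeds are
  three classes — 40 km/h where either endpoint cell is ≥ 300/km²
  (urban), 70 km/h rural, 100 km/h motorway. No lights-and-sirens or
  congestion adjustment is applied; both services face the same network.
  These road parameters were calibrated once so that station-to-scene
  travel times at study scale span roughly 1–25 minutes (observed:
  0–29 min, mean EMS travel ≈ 8 min), matching the regime the model is
  meant to emulate; they are not re-tuned per run.
- **Stations.** 121 EMS bases drawn population-weighted without
  replacement over cells (demand-driven placement); 1590 fire stations
  from a 50/50 blend of population-weighted and
  uniform-over-settled-cells draws (municipal ubiquity). Every station
  snaps to its nearest road node not already occupied by a station of the
  same service; the per-service exclusivity keeps "nearest station" sets
  well defined and, on rare collisions, the snap falls to the next-nearest
  free node (the recorded snap distance reflects this).

Everything is deterministic given the config seed; the three generators
use independent substreams of one `SeedSequence` so that, e.g., changing
the station count cannot perturb the raster.

## Events

Arrest locations are sampled in two stages: a raster cell with
probability proportional to its population, then a uniform position
within the cell. This makes the weight surface exactly testable
(cell-count goodness of fit against the known weights) and gives
zero-population cells exactly zero events. Events snap to the nearest
road node with no off-road penalty — the response ends at the curb. The
default count is 1000 events per run, matching the approximate annual
number of arrests suitable for additional dispatch in a region of this
size.

## Routing and the k-nearest prefilter

Travel time is the shortest path on the road graph with edge weight in
minutes. Edges are undirected (no one-way streets), so station→event and
event→station times coincide. To bound computation, each event is routed
only to its k = 10 nearest stations per service, with nearness measured
by straight-line distance (the only metric available before routing);
`k="all"` disables the prefilter and is exact. The prefilter is auditable:
with k = 10 the per-event best travel time can only be pessimistic, and
the test suite measures the mismatch rate against the exact answer
(≤ 5% of events on study-scale instances, typically far less for the
fire service whose candidates are close). Ties between equally fast
stations resolve to the smaller station id. Implementation:
`scipy.sparse.csgraph.dijkstra`, one single-source pass per distinct
event node; the tests check it against an independent Bellman–Ford
relaxation oracle.

## Dispatch semantics

Per event: `ems_response = 2 + ems_travel`, `fire_response = fire_turnout
+ fire_travel`, `dual_response = min(ems_response, fire_response)`. The
first arriver is FIRE only under strict inequality; exact ties count as
EMS-first, making the fire-first fraction conservative. A single
(daytime) turnout pair is used — in the emulated system both services
need one extra minute at night, so the contrast is unchanged — but both
values are independently configurable. `fire_turnout → ∞` recovers
EMS-only exactly, which the degenerate paired test (t = 0, p = 1) and the
tests rely on.

## Statistics

- **Summaries.** Sample SD (n−1), linear-interpolated percentiles,
  threshold coverage as an inclusive fraction (default threshold 10 min).
- **Comparison.** Paired two-sided t-test on per-event differences: both
  strategies are evaluated on the same events, so the design is
  intrinsically paired. An unpaired Welch variant is available behind
  `kind="welch"` for comparison. All-zero differences return p = 1
  rather than NaN.
- **Turnout sweep.** Travel times are turnout-independent and cached;
  the sweep re-derives records per grid value (default 1-min steps,
  2–25 min) and reports the smallest fire turnout whose paired test has
  p ≥ α = 0.05. No multiple-testing correction is applied — the sweep is
  exploratory. On draws whose EMS travel tail is long, the advantage can
  persist past 25 min; the acceptance script extends its grid to 60 min
  so the reported threshold is always a realised number.
- **GLM.** Gaussian family, identity link, on long-format data (two rows
  per event): intercept, raw density (inhabitants/km², untransformed),
  strategy indicator, interaction. R² = 1 − RSS/TSS. Rank-deficient
  designs (e.g. constant density) raise an error naming the collinear
  column. Fitted via statsmodels; parameter recovery and CI coverage are
  verified against simulated data with known coefficients.

## What the synthetic region does and does not show

Passing tests demonstrate the method's internal correctness (exact
routing, prefilter bounds, dominance, monotonicity, sampling fidelity,
GLM calibration) and that the qualitative pattern — dual dispatch faster
on average, higher 10-min coverage, fire first at most events, benefit
concentrated at low density — emerges from the stated structural
conditions (13:1 station ratio, 2/5-min turnouts, heterogeneous density).
They do not certify the magnitudes for any real region: cluster shapes,
road topology and station siting are stylised, real GLM coefficient
scales depend on the real density distribution (our synthetic densities
top out around 2,700/km², so β magnitudes are larger than with a raster
that reaches tens of thousands), and the no-unavailability assumption
biases toward dual dispatch.

## Numerical choices and degenerate inputs

Percentile method `linear`; tie rule EMS-first; station-id ascending
tie-breaks in candidate ordering; coincident-node edges dropped at
construction; disconnected adapter networks raise a routing error rather
than returning infinity; all-zero rasters, empty record sets, n < 2
tests and unsorted sweep grids raise typed errors. Reduced problem sizes
used in the test suite (≤ 900-node graphs, ≤ 300 events for unit tests;
the full 6,000-node, 1000-event configuration for the end-to-end checks)
were chosen so the whole suite exercises every scale the API supports.
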