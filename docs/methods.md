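# Methods

## Model

The placement problem is a capacitated set-covering location problem
(CSCLP) over grid cells. Demand cells `i ∈ I` carry populations
`a_i > 0`; candidate sites `j ∈ J` carry per-CHW capacities `k_j`; the
neighborhood `N_i` contains the sites within the maximum walking time
`S` of cell `i`. The program minimizes the total CHW count
`Z = Σ_j Y_j` subject to universal coverage (`Σ_{j∈N_i} X_ij ≥ 1`),
capacity (`Σ_i a_i X_ij ≤ k_j Y_j`) and integer `Y_j ≥ 0`. Allocations
`X_ij` are continuous: a cell's inhabitants may be split between
several CHWs. The classical formulation makes sites binary; we use
integer multiplicities so that a dense cell can host several CHWs —
without this the model is infeasible wherever `a_i > max_j k_j`.
Candidate sites default to the demand cells themselves (CHWs live where
the people they serve live).

Assumptions inherited from the planning context: walking is the only
travel mode, costs are symmetric, CHWs are interchangeable within a
cell, and coverage is purely geographic (no disease-risk weighting).

## Travel times

The friction raster gives minutes to cross 1 km of each cell. Adjacent
cells (8-connected by default; 4-connectivity by flag) are joined by
edges costing the arithmetic mean of the two frictions times the step
length (`cell_size`, ×√2 diagonally). Travel times are Dijkstra
shortest paths on this graph, swept from the smaller of the two index
sets and truncated at `S`; the `≤ S` comparison carries a 1e−9
tolerance so exact-boundary cells are kept deterministically. The
access surface (time to nearest CCS) is a multi-source sweep with
unreachable cells at +∞.

## Strata and scenarios

Cells are rural or urban by the degree-of-urbanization rule: density
strictly above 300 persons/km² groups into contiguous clusters
(8-connected by default) and clusters with strictly more than 2000
people are urban. A user-supplied commune mask overrides either label
to metropolitan. Four built-in scenarios share `S = 60` min:

| scenario | demand | capacities (persons/CHW) |
|---|---|---|
| A | all inhabited cells | 1000 rural / 2500 urban / 4000 metro |
| B | only cells > 30 min from a CCS | 1000 rural / 2500 urban & metro |
| C | all | ≤ 60 min from CCS: 4000 everywhere; beyond: 1000 rural / 2500 urban & metro |
| C2 | all | rural always 1000; urban 4000 within 60 min else 2500; metro 2500 |

Proximity conditions are strict on the far side ("more than 30/60
minutes"), so boundary cells fall on the near side. In C2 the
metropolitan stratum keeps 2500 at any CCS distance (the 4000-within-60
rule applies only to urban cells); capacity rules are an ordered
first-match list, so user scenarios can override this. Capacities
translate into visit frequencies by
`visits/household/year = households_per_day × working_days /
(capacity / household_size)` with defaults 8 households/day, 4.3
persons/household, 220 working days — hence 1000 → 7.57 ≈ 8 visits,
2500 → 3, 4000 → 1.89 ≈ 2.

## Solving

The mixed-integer program is solved by HiGHS through
`scipy.optimize.milp`. Two implementation choices matter:

* **Valid strengthening cuts.** The raw formulation's LP relaxation
  spreads fractional CHWs of size `a_i/k_j` over the grid, leaving an
  enormous branch-and-bound gap (observed > 60 % on a 1600-cell
  region). Two per-cell inequality families close most of it without
  ever cutting an integer solution: set-covering cuts
  `Σ_{j∈N_i} Y_j ≥ 1` (any cell's allocation forces a CHW within
  reach, since `X_ij > 0` requires `Y_j ≥ 1`) and absorption cuts
  `Σ_{j∈N_i} k_j Y_j ≥ a_i` (a cell's whole population must fit in its
  neighborhood's capacity).
* **Zone decomposition.** Country-scale runs solve each administrative
  zone independently (cross-zone pairs dropped), which mirrors how the
  planning decision is organized and turns one intractable MIP into
  several tractable ones. On the default 40×40 region, per-zone solves
  prove optimality in seconds to tens of seconds where the whole-grid
  model cannot close the gap in minutes. The partitioned total can
  exceed the unrestricted optimum (restriction removes options); both
  solvers are exposed.

`Y_j` is bounded above by `ceil(reachable population / k_j)` — provably
never binding at an optimum — to shrink the search. The optimality gap
is expressed in whole CHWs (`gap_abs`, default 0 = proven optimum); the
backend's relative gap is derived conservatively from an upper bound on
`Z` so the absolute deviation cannot exceed `gap_abs`. Ties between
equally optimal placements are broken arbitrarily by the solver; tests
assert objectives and feasibility, never site identity.

An exhaustive oracle (`brute_force_solve`, instances up to 8 sites)
enumerates `Y` vectors in order of total count and certifies
feasibility by max-flow on the transportation network
(source → cells → reachable sites → sink, capacities scaled to integer
millipersons); the first feasible vector is optimal. `check_solution`
audits any solution against all constraint families at tolerance 1e−6.

## Reporting

Per-CHW assigned population divides a site's inflow `Σ_i a_i X_ij`
equally among its `Y_j` CHWs — the only symmetric choice; real
programmes would redistribute workload between neighbouring CHWs when
drawing individual catchments. Summaries report mean and 5 %/95 %
quantiles (empirical distribution over CHWs, linear interpolation), the
fraction of CHWs at capacity (within 1e−6·k_j) and the fraction
assigned fewer than 100 people. Gap analysis against current staffing
reports `current − suggested` per zone: negative = deficit. The
sensitivity suite perturbs each threshold (walking time, all
capacities, CCS proximity, urban density, urban cluster population)
by ±10 % independently and reruns the pipeline; exact per-zone solves
make the monotone response (tighten ⇒ no fewer CHWs, relax ⇒ no more)
a theorem rather than a tendency.

## Synthetic regions

`generate_region` targets the structural features the method needs, not
any real geography: Gaussian-decay urban cores (tails truncated at
1e−3 of the peak so rural emptiness is genuine) over a sparse
background capped below 290 persons/km² (so stratum labels are
predictable by construction), a smooth friction field in
[10, 60] min/km plus a high-friction ridge, CCS drawn with probability
∝ population², vertical-strip zones and a metropolitan disc around the
densest core. Defaults — 40×40 km at 1 km resolution, 120 000 people,
two cores holding 55 % of the population, six CCS, six zones — give a
department-scale instance with meaningful urban/rural contrast, partial
CCS coverage, and exact per-zone solves in well under a minute; tests
use a 24×24 / 40 000-person variant for speed. One integer seed drives
independent per-layer substreams, so every layer is individually
reproducible. What passing tests on such regions show is that the
machinery is correct (feasibility, optimality, conservation,
monotonicity); they say nothing about the quality of any real
population or friction raster, which dominates real-world results.

## Degenerate inputs and edge cases

Empty demand sets (e.g. a fully CCS-covered zone under scenario B) are
legal and yield zero CHWs with a warning; a demand cell with an empty
neighborhood raises a named infeasibility error (population unreachable
within `S`). Raking a zone with zero population but a positive target
raises rather than inventing support. Aggregation of shapes not
divisible by the factor sums trailing partial blocks as-is, conserving
totals. All layers must share shape, origin and cell size exactly; no
silent resampling. Rasters are exchanged as plain-text ESRI ASCII
grids; nodata cells are masked on read and untraversable in the cost
graph.

## Known limitations

Exact solves scale poorly past a few hundred demand cells per zone;
larger runs should allow a small absolute gap (a handful of CHWs per
zone, negligible against national totals) or finer partitions. The model ignores non-walking travel,
facility capacity other than CHW attachment, financial access and
within-cell heterogeneity. The generator's regularity (vertical-strip
zones, single ridge) is deliberate and not a statistical model of any
country.
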