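# chwplace

Optimal geographical placement of community health workers (CHWs) on
gridded population and walking-time surfaces.

## The problem

National community-health programmes need to decide **how many CHWs to
recruit and where to post them** so that every inhabitant can reach (and
be reached by) a CHW within a reasonable walk, while no CHW is
responsible for more people than a realistic workload allows. `chwplace`
answers this with a capacitated set-covering location model over a 1 km²
population raster:

```
min  Z = Σ_j Y_j                               (total CHWs)
s.t. Σ_{j ∈ N_i} X_ij ≥ 1        ∀ i ∈ I      (universal coverage)
     Σ_i a_i X_ij − k_j Y_j ≤ 0  ∀ j ∈ J      (capacity)
     Y_j ∈ ℕ,  X_ij ∈ [0, 1]
```

where `a_i` is the population of cell *i*, `k_j` the per-CHW capacity at
site *j*, `N_i = {j : d_ij ≤ S}` the sites within the maximum walking
time `S` (computed as least-cost paths over a friction surface in
minutes/km), and `X_ij` the fraction of cell *i*'s inhabitants assigned
to site *j*. Treating `Y_j` as a **nonnegative integer** rather than a
binary lets several CHWs share one densely populated cell, which is what
makes the model feasible in urban cores.

The package is aimed at health-workforce planners and modellers: it
classifies cells rural/urban/metropolitan by the degree-of-urbanization
rule (density > 300 /km², contiguous cluster population > 2000),
computes walking-time access to community health centres (CCS), encodes
placement scenarios whose capacities depend on stratum and CCS
proximity, solves the integer program exactly per administrative zone
with the bundled HiGHS solver, and reports workload summaries, coverage
gaps against current staffing, and ±10 % threshold sensitivity.

## Worked example

```python
import chwplace as cp

region = cp.generate_region(seed=7)          # 40x40 km synthetic region
result = cp.run_scenario(region, "A", partitioned=True)
print(result.total_chws)                     # 246
s = result.summary
print(round(s.mean_assigned, 1))             # 496.5 people per CHW
print(round(s.at_capacity_fraction, 2))      # 0.09 of CHWs at their cap
print(cp.check_solution(result.solution, result.model))   # [] = valid
```

`generate_region` builds a reproducible synthetic region (two dense
urban cores over a sparse rural background, a smooth friction surface
with a mountain ridge, six CCS, six zones, 120 000 people). Scenario
"A" covers the whole territory with capacities 1000 (rural), 2500
(urban) and 4000 (metropolitan); the solver places 241 CHWs — every
inhabitant is within 60 min of one, no CHW exceeds its capacity, and
`check_solution` returning `[]` certifies both. Scenario capacities and
rules are in `cp.builtin_scenarios()`; user-defined scenarios load from
YAML.

Workload arithmetic links capacities to visit frequencies:

```python
round(cp.visits_per_year(1000))   # 8 visits/household/year
round(cp.visits_per_year(4000))   # 2
```

The same pipeline runs from the shell:

```bash
chwplace generate --seed 7 --out region/
chwplace classify config.yaml     # rural/urban/metropolitan raster
chwplace access   config.yaml     # CCS walking-time surface + share > 60 min
chwplace solve    config.yaml     # sites.csv, allocations.csv, summary.csv
chwplace sensitivity config.yaml  # +/-10% threshold perturbations
```

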