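# Methods

## The model

`acsforage` is an individual-based simulation of foragers moving in
continuous space on a square landscape of side `L = 2000` with periodic
(toroidal) boundaries, so the landscape behaves as edgeless.  All positions
— of foragers and of resource items — are continuous 2-D coordinates;
distances use the minimum-image convention.

### Landscape

Resources are clustered: `k` parent points are placed uniformly at random
subject to a minimum pairwise toroidal separation of `3g` (rejection
sampling, capped at 10⁶ candidate draws), and resource items are scattered
uniformly on the disk of radius `g` around their parent — a Matérn-style
cluster pattern with a fixed number of parents.  The per-cluster item count
at initialization is Poisson with the cluster's expected count (the "expected
number" convention of the Matérn cluster process); replacement counts during
a run are deterministic.  A cluster disk is a "patch"; everything else is
"matrix".  The study geometries pair `k ∈ {16, 8, 4, 2, 1}` with
`g ∈ {80, 80√2, 160, 160√2, 320}` so that the habitat area `k·π·g²` is the
same 8.04% of the landscape in every case.

### Movement (area-concentrated search)

Each forager carries a searching time `ΔS` — the number of consecutive
steps since it last captured an item.  At every step it turns by an angle
drawn from a wrapped normal distribution with mean 0 and standard deviation

    d(ΔS) = d_min + (d_max − d_min) · (1 − ΔS^α / (ΔS^α + h^α))

then advances a fixed step length `p` along its heading.  Right after a
find (`ΔS = 0`) the turn SD is `d_max = 1` rad and the path is tortuous
(area-concentrated search); as `ΔS` grows past the half-saturation constant
`h = 200` steps the SD relaxes toward `d_min = 0.01` rad and movement
becomes near-ballistic.  The shape exponent is `α = 3`.  Two control modes
are the limits of `h`: `h = 0` gives straight-line movement (SLM; the 0/0
at `ΔS = 0` is special-cased to `d_min`, the value of the h → 0⁺ limit for
every positive `ΔS`), and `h = 10,000` pins the SD near `d_max` for any
attainable `ΔS` (a plain correlated random walk, CRW; `d(2000) = 0.9921`).

The turn SD is interpreted as the *standard deviation in radians* of the
wrapped normal.  An alternative reading — `d` as the mean resultant length
(autocorrelation) of turning, rising with `ΔS` — was implemented and
rejected during development: it produces a qualitatively wrong regime
structure (stronger, not weaker, confinement in sparse many-cluster
landscapes and a near-unit foraging-success contrast between the one- and
16-cluster geometries).

### Foraging

Per time step, foragers are processed in a fresh uniform random
permutation.  Each moves one step and immediately harvests *all* live items
within its perception radius `c = 1` of its new position (closed boundary:
distance ≤ c).  Because movement never reads the resource pool, all moves
are drawn vectorized first and only harvesting is sequential; later movers
in a step see the depletion left by earlier ones, which is equivalent to
the fully interleaved schedule.  After all foragers have moved, every item
removed during the step is replaced by a fresh daughter point of a
uniformly chosen parent ("global replacement"), so the landscape-wide item
count is constant at every step boundary while local depletion by intense
harvesting remains possible.  `ΔS` is then reset to 0 for foragers that
harvested at least one item and incremented by 1 for the rest.  Harvest
checks happen only at step endpoints, not along the step path.

### Runs

A replicate releases `N = 80` foragers — inside clusters (cluster chosen
uniformly, position uniform on its disk; clusters are congruent, so this is
uniform by area) or uniformly over the landscape for the control modes and
the random-start variant — with uniform headings and `ΔS = 500` (near-
straight initial movement), and iterates `T = 10,000` steps.  Statistics
use the last 2,000 steps only.  The master seed spawns three independent
substreams (landscape, initialization, stepping), so each replicate has an
independently realized landscape and a fixed seed reproduces a run bit for
bit.

## Resource-supply convention of the scenario grid

The grid's density ladder `u ∈ {0.01, …, 1.27}` parameterizes resource
supply through the single-cluster geometry: a grid scenario with `k`
clusters uses a within-cluster item density of `u/k`, i.e. the expected
landscape-wide item count is `π·g²·u` — the supply of the corresponding
one-cluster landscape divided across the `k` clusters (one-cluster
scenarios realize density `u` exactly).  This is the convention under which
the system exhibits its documented regime structure: sparse many-cluster
landscapes remain in the random-distribution regime (≈8% of foragers inside
clusters, patch occupancy well below saturation) and the foraging-success
contrast between the one- and 16-cluster geometries reaches the order of
60-fold at `u = 0.01`.  Holding within-cluster density at `u` for every `k`
instead (the other natural convention, available by constructing a
`LandscapeSpec` directly) saturates the many-cluster scenarios: crossing a
`g = 80` cluster at density 0.01 sweeps ≈2.5 expected items, so nearly
every crossing triggers search behavior and the "random regime" disappears.

## Statistics

All statistics are computed per replicate from the analysis window, as
across-individual averages; scenario values are means of per-replicate
means (never pooled individuals).

1. **Foraging success** — fraction of window steps with ≥1 item harvested.
2. **Clusters harvested** — number of distinct clusters a forager harvested
   from (attributed by its cluster membership at the harvesting step);
   zero-harvest foragers stay in the mean.
3. **Patch visitation time** — mean duration of inside episodes.
4. **Patch searching time** — mean duration of outside episodes.
5. **Permanent-emigration percentage** — emigrations whose outside
   excursion lasts ≥ 200 steps, as % of classifiable emigrations (the rest
   are foray loops).
6. **Patch occupancy** — % of window steps a patch holds ≥1 forager,
   averaged over patches.
7. **Percent of foragers in clusters** — per-step fraction inside any
   cluster, averaged over the window.
8. **Patch changes** — per forager, emigrations whose next entry is into a
   different cluster than the source.

Membership uses the post-move position once per step, with the closed disk
(distance ≤ g); the 3g parent separation makes membership unique.  A
forager's membership series is segmented into maximal inside/outside
episodes; each inside→outside transition is an emigration event.

Conventions where the definitions leave room:

- *Window-edge censoring.* Episodes touching a window boundary contribute
  their truncated durations to the visitation/searching means.  An
  emigration whose outside episode is right-censored below the 200-step
  cutoff cannot be classified and is excluded from statistic 5; one
  censored at ≥ 200 steps is already determined and counts as permanent.
- *Exclusion rule.* Foragers with no inside step during the window are
  excluded from statistics 3, 4, 5 and 8 (not from 1, 2, 6, 7).  Being
  inside at the window start counts as having entered.
- *Loop-backs.* A return to the source cluster is never a patch change.
- *Distance to patch center* (one-cluster scenarios only): mean toroidal
  distance to the parent point over foragers inside the cluster at the
  final logged step; foragers outside at that step are omitted.  The
  uniform-occupancy baseline is `2g/3 ≈ 213`.

## Numerical choices

- **Spatial index.** The resource pool lives in a periodic uniform-grid
  cell list (linked head/next arrays) with cell size ≥ the perception
  radius, mutated in place by small numba kernels; a query scans the
  covering block of cells.  The contract is exactness: tests compare
  against brute-force scans over randomized pools.  The per-step
  move-and-harvest sweep is a single fused kernel over the same arrays.
- **Wrapped normal.** Plain normal draw wrapped into (−π, π]; for SDs ≤ 1
  rad the wrapped mass is negligible but wrapping is always applied.
- **Boundaries.** Perception and membership disks are closed (≤); a
  zero-measure choice fixed for test determinism.
- **Degenerate inputs.** Infeasible parent packings raise after the
  rejection cap; harvesting a non-live item raises; `h = 0` and underflowed
  `h^α` are handled as the SLM limit.

## What the acceptance script measures

`scripts/acceptance.py` re-runs the simulation from scratch at the study
conditions and reports: the one- vs 16-cluster foraging-success ratio at
`u = 0.01` (10 replicates each) and at `u = 1.27` (5 each), the maximum
inside:outside population-density ratio over the one-cluster ladder
(5 replicates per density, density ratio `(f/0.0804)/((1−f)/0.9196)` from
the in-cluster fraction `f`), the SLM control's percentage of foragers in
clusters (`k = 4`, `u = 0.16`), patch occupancy for `k = 8` at `u = 0.01`,
and the percentage in clusters for `k = 16` at `u = 0.01`.  Replicate
counts are scaled to desk hardware; ratio statistics built from small-mean
proportions carry large replicate-level sampling error, which is why the
test suite checks them against factor-of-two bands while percentage-scale
statistics get absolute bands.

## Limitations

- No births, deaths, starvation or dispersal mortality: the population is
  fixed and only redistributes.
- Resource dynamics are the one-for-one global replacement equilibrium; no
  local regrowth or prey dynamics.
- The synthetic landscapes use congruent disks and a single density per
  scenario; heterogeneous patch quality (mainland–island, source–sink
  settings) is out of scope.
- Harvest detection is endpoint-only; a fast mover could in principle step
  across an item's perception disk without detecting it, though with
  `p = c` this is a minor geometric effect.
- Passing tests demonstrate the emergent regime structure of this model
  family on synthetic Matérn-clustered landscapes; they say nothing about
  real organisms' movement rules, perception, or memory.
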