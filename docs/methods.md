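# Methods

`tipland` simulates land-system change at coarse resolution under exogenous
demand for four land-system services — cropland, forest, grassland and
shrubland area. This note documents the model, its parameters, the
numerical choices we made where the procedure was genuinely open, and what
the synthetic test scenes do and do not demonstrate.

## Land systems

The simulation state is a *land-system* raster: each coarse cell carries a
class combining the dominant land-cover type with a within-cell density
level. With ten basic cover types (cropland, forest, grassland, shrubland,
wetland, water body, tundra, artificial surfaces, bare land, snow/ice) and
three density levels (low/medium/high) the legend has up to 30 classes,
coded type-major: `code = 3 * cover_type + density`.

Construction from a fine categorical cover raster:

1. **Block-majority upscaling.** A non-overlapping window (33 × 33 by
   convention, turning 30 m cells into 990 m cells) is slid over the cover
   raster; each coarse cell takes the modal cover class of its block and
   the modal class's area fraction among the block's valid cells. Modal
   ties resolve to the lowest class code (deterministic). Edge-truncated
   blocks are kept when at least half the block lies inside the raster —
   the procedure's sources are silent on edges, and this keeps the area
   bias small. All-nodata blocks become nodata.
2. **Natural-breaks density classing.** Per cover type, the dominant
   fractions of all cells of that type are split into three classes by the
   natural-breaks (minimum within-class sum of squared deviations)
   criterion. The optimizer is exact: prefix-sum enumeration of every
   2-breakpoint partition of the sorted values, ties to the first optimum.
   The breakpoints are the low- and medium-class maxima, so the density
   intervals are left-inclusive: fraction ≤ b1 → low, ≤ b2 → medium,
   else high. Breakpoints are fitted once over the whole study region
   (one global legend), not per basin. Types with fewer than three
   distinct fraction values are degenerate; their cells are assigned high
   density and the condition is flagged in the result.
3. **Nearest-neighbour resampling** (e.g. 990 m → 1 km) assigns each
   output cell the value of the input cell whose centre is nearest — it is
   value-preserving, which matters for categorical data.

Validation at the ten-class thematic resolution merges densities back
(`code // 3`).

## Demand and supply

Demand comes from integrated-assessment-model (GCAM-style) land-area
tables: rows of (basin, land type, year, area). Each land type maps to one
of the four services through an editable dictionary; the types treated as
unchanging (tundra, urban, rocky, snow/ice, desert) are dropped; anything
else is rejected loudly. A service's demand is the summed area of its
types. Areas are km² internally; the reader accepts `km2` or `thous_km2`
on ingest because IAM outputs conventionally use thousands of km². For
historical validation the demand can instead be derived from an observed
end-year cover map (total area of each service's backing cover type).

On the supply side every land-system class j gets a capacity vector
`CA[j, d]`: the area of service d one cell of class j provides, estimated
as the mean area of the backing cover type among the fine cells nested in
coarse cells of class j. A class can supply several services and a service
several classes (many-to-many); density classes of non-service cover types
carry all-zero rows and participate only through the conversion matrix.

## Location suitability

Per candidate class, a random forest is trained on per-cell driver vectors
labelled from an observed map pair: by default label A marks cells of the
class at the first date that left it by the second (`target="loss"`, the
literal sample rule), with a conventional gain-oriented alternative
(`target="presence_at_y2"`) behind a switch, because the loss-oriented
rule sits oddly with the output's interpretation as suitability for
conversion *to* the class; which reading the original procedure used is
ambiguous, so both are available and the choice is logged in run metadata.
The ensemble is 200 trees on 25% per-tree row subsamples; we read the "25%
sampling proportion" as subsampling without replacement
(`BaggingClassifier` over `sqrt`-feature decision trees), with an optional
class-balanced mode. The majority label is capped at 10× the minority to
bound memory (seeded). The class-A probability surface is P_loc ∈ [0, 1].

The driver stack includes density-of-cover layers computed from the land
system itself: per coarse cell, the area proportion of each cover type
among its nested fine cells.

## Allocation

One external iteration converts cells until the supply of the four
services meets demand. A cell c's conversion potential for class j is

    P_pot(c,j) = P_loc(c,j) + P_res(T0(c)) + P_nei(c,j) + P_comp(c,j)

- `P_res` is the class's conversion resistance, estimated as its observed
  persistence share between two dates (classes unseen at the first date
  default to 0.5). It depends only on the cell's class at the start of the
  external iteration, so within a cell it is constant across candidate
  classes and only affects cross-cell ordering — implemented literally
  anyway.
- `P_nei` is the neighbourhood term, kept at its default of 0 (the hook
  exists; no kernel library is built).
- `P_comp` is the adaptive competitive advantage,
  `sum_d inertia(d,i) * (CA[j,d] - CA[u,d]) / sum_j CA[j,d]`, with u the
  cell's current class — the marginal service gain of switching, which is
  the only reading that makes the mechanism adaptive per cell. The
  normalizer runs over all classes with nonzero capacity. Inertia
  accumulates the demand–supply gap across internal iterations, damped by
  a speed that starts at `seed` (default 1) and grows by `step` (default
  0.001) per iteration; the self-referential printed update is read as
  accumulation, and at i = 1 inertia is zero.

Permissions come from a binary conversion matrix derived from the observed
map pair (`M[a,b] = 1` iff some cell transitioned a → b; diagonal forced
to 1).

**Convergence** is per-service: `|Supply_d − Demand_d| ≤
max(tolerance · Demand_d, max_j CA[j,d])` with a relative tolerance of
0.1% and an absolute floor of one cell-equivalent of the largest capacity
(supply moves in single-cell quanta, so no tighter target is meaningful).
Services with neither demand nor capacity have an identically zero gap and
receive a dummy band so the arithmetic stays defined.

**Demand-driven gating.** The engine only considers conversions that
strictly shrink the tolerance-weighted L1 gap, under two per-service caps:
a service inside its band may not leave it, and one outside may slip by at
most one band width per move. Without the gating, converting the globally
best candidate regardless of direction systematically overshoots services
whose classes are absorbing under the observed conversion matrix (once
overshot, no permitted conversion can give the area back), and the
simulation cannot converge. The gating preserves the ranking principle —
among admissible conversions, the highest potential wins.

**Phases.** The coarse phase converts exactly one cell per internal
iteration (the best admissible candidate; ties break on row-major cell
index, then class code) up to a cap of 20,000 iterations, freezing each
converted cell for the rest of the external iteration to rule out
oscillation. If demand is still unmet, the fine phase sweeps cells one at
a time in descending potential — including cells the coarse phase
converted, whose permissions then follow their current class — keeping
only gap-shrinking moves; strict decrease guarantees termination.
Demand infeasible under the permitted relabellings (demand exceeding the
sum over cells of the best reachable capacity) is reported before any
iteration. Multi-step horizons interpolate demand linearly between
endpoint years, one external iteration per step.

Everything is deterministic given the inputs: two runs with one
configuration produce byte-identical change logs.

## Validation

Map agreement is Cohen's kappa, `(P0 − Pc)/(1 − Pc)` with the
marginal-product chance term (the verbal "random case" admits other chance
models; this is the standard convention). Change-prediction accuracy is
the figure of merit `B/(A+B+C+D)` over the change components: A changed in
reality only, B changed in both to the correct class, C changed in both to
the wrong class, D changed in the simulation only. Degenerate inputs
(single-class tables, no change anywhere) return a typed `Undefined`
outcome, never a silent zero. Both metrics are computed at 30- and
10-class thematic resolution.

## Synthetic scenes

The generators produce every input with known structure: autocorrelated
cover rasters (rank-uniformized smoothed Gaussian fields partitioned at
the cumulative abundance weights, so realized shares track the targets;
correlation length 0 degenerates to i.i.d. multinomial cells), driver
stacks with recorded class-linked effect sizes (default: two class-linked
signals at 3 SD against unit noise, three smooth fields, one pure-noise
layer), before/after map pairs from explicit transition rules with the
realized per-class persistence persisted as ground truth, and geometric
demand trajectories.

The default end-to-end scene is a 300 × 300 cover raster (500 × 500 in the
convergence check, giving a 100 × 100 land-system grid under a window of
5) with three transition rules: forest → cropland and grassland →
cropland, both pushed by the cropland-linked driver, and shrubland →
grassland at random. These scenes exercise the statistical structure the
method consumes — multi-class mosaics, drivers that separate transitions,
many-to-many capacities — but not real-world geography: no basins,
coastlines, climate gradients, or the 65-layer driver suite used with real
data. Passing tests therefore demonstrate the correctness and internal
consistency of the machinery, not the accuracy attainable on real
land-cover products.

## Problem sizes and limitations

The shipped checks use grids up to 500 × 500 fine cells (100 × 100
allocation cells), where a full pipeline run takes seconds; the engine's
per-iteration cost is one (cells × candidate classes) array scan plus a
30 × 30 competitive-advantage update, so larger scenes scale linearly per
conversion. Known limitations: the allocator is greedy (single-move
gating cannot perform compensating exchanges, so tightly coupled demands
near infeasibility may stall with an honest non-convergence report);
neighbourhood effects are stubbed at zero; reprojection is out of scope
(georeferencing passes through untouched); and the conversion matrix is
purely observational — transitions never seen between the two reference
dates are forbidden even if physically plausible.
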