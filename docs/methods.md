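# Methods

## Problem and model

The package estimates *potential spatial access*: the share of a population
living within a given road-travel distance of health facilities capable of a
defined level of emergency care. Access is distance-based, not time-based —
in settings where road-surface and speed data are unavailable, a 50 km
network distance is a common proxy for the distance travelable within about
one prehospital hour, with 5 and 10 km capturing walking-scale access.
Distances are symmetric and undirected; there is no travel-time costing,
one-way restriction or turn penalty. Utilization, cost and preference are
out of scope: the estimates are supply-side.

The pipeline has four stages, each usable on its own.

### 1. Capability classification

Facilities carry boolean/count audit attributes (infrastructure, personnel,
supplies). The criteria form a near-hierarchy: Level B requires all Level A
criteria; Level C is reached either by satisfying Level B plus > 50
inpatient beds and a surgeon on staff, or *by designation* (a
government-designated tertiary hospital). Consequences encoded exactly:

- flags are **overlapping** (a Level B facility counts in Level A
  catchments too); per-level summary percentages can sum past 100;
- a designation-route Level C facility does **not** inherit A or B — a
  designated tertiary hospital without running water contributes only to
  tertiary catchments;
- the bed threshold is strict (`> 50`), the provider minimum inclusive
  (`≥ 2`), and the instrument criterion requires all three instruments.

Missing attributes are distinct from observed absence. `missing_policy`
controls them: `as_false` (default) treats unrecorded items as absent —
the conservative choice, biasing capability downward — while `error`
rejects incomplete records for strict audits.

### 2. Road network and service areas

Digitized road layers routinely contain crossings that are not graph nodes.
`build_network` nodes the arrangement (GEOS noding via `unary_union`),
merges endpoints within `snap_tol_m` (default 1 m — digitized networks
carry sub-meter jitter), recomputes lengths from corrected geometry, and
drops pieces that collapse to zero length, with a warning. Edge ids are
assigned in sorted-WKB order so all tie-breaks are reproducible.

Facilities attach to the *nearest point on the nearest edge* (not the
nearest node), because facilities often sit off small unmapped tracks;
`max_snap_m` (default 5,000 m) bounds the attachment and snap failures are
reported per facility rather than silently dropped.

A service area at cutoff *r* is computed by multi-source Dijkstra over edge
lengths, seeded with each source's along-edge offsets. An interior point
of an edge is reached through endpoint *u*, endpoint *v*, or directly along
the edge from a source snapped to it; the union of the three interval
families per edge is exact, and partial edges are cut by arc-length
interpolation. Unreachable components are excluded, not errors. The
cutoff-0 service area is the source points themselves.

Buffering uses round caps/joins. Note the polygonal buffer is inscribed in
the true offset curve; the shortfall is bounded by the sagitta (≈ 0.5% of
the radius at the default quadrant segmentation), which matters only when
comparing against geometric oracles.

### 3. Zonal statistics

Cell membership is by **cell center**, boundary-inclusive. Cells (100 m
nominal) are small relative to the 1,000 m buffer, and the center rule
makes partition sums exact, which area-weighting would not. When a center
lies exactly on a shared boundary, exclusive assignment goes to the first
region in sorted `region_id` order, so a partition conserves population to
the last person; population outside every region is reported as a
remainder. Region proportions with a zero denominator are undefined and
surface as N/A, never as 0.

### 4. Coverage tables and uncertainty

Per level, the service area is the union over all capable facilities
(order-independent, and equivalent to pooling per-facility catchments).
National proportions are computed raster-wide *and* as the
population-weighted mean of regional proportions; when regions partition
the raster the two agree exactly (the maximum difference is recorded in
`table.attrs["national_vs_regions_max_diff"]`), and the raster-wide value
is the one reported, since real region polygons may not cover every cell.

The uncertainty interval (UI) is the min/max of coverage at buffer sizes
1,000 m × {0.5, 1, 1.5}. With nested buffers this is simply the
small/large-buffer pair; it quantifies sensitivity to the "how far from a
road do people live" assumption, not sampling error.

The Euclidean variant replaces catchments with disks of radius *r* around
facility points (no snapping, no extra buffer). Geometry gives a
one-sided bound: a disk of radius *r* + buffer contains the buffered
network catchment at cutoff *r*, so Euclidean coverage at *r* + 1 km
dominates network coverage at *r* row by row — a useful concordance check
on road-network completeness.

Display tables round half-up to one decimal in percent (0.4875 → "48.8");
raw CSVs keep full precision.

## Synthetic countries

The generator emulates the statistical structure of the real inputs so that
end-to-end behavior is testable without restricted data:

- **Settlements**: uniformly placed with minimum separation; populations
  log-normal (median `settlement_pop_median`, shape
  `settlement_pop_sigma`).
- **Population raster**: each settlement's population is split into an
  urban core and a rural halo (Gaussian kernels, `urban_sigma_m` /
  `rural_sigma_m`) and allocated to cells multinomially — so the raster
  total equals the drawn settlement populations exactly.
- **Roads**: a minimum-spanning-tree trunk over settlements with gentle
  mid-point bends, extra nearest-neighbour links creating cycles, and
  radial branch roads per settlement.
- **Facilities**: sited at settlements with population-proportional
  probability (a configurable fraction scattered along rural roads);
  attribute vectors are drawn hierarchically — target level first, then
  attributes consistent with it plus noise on the free attributes — so
  realized prevalence matches the configured `p_A ≥ p_B ≥ p_C`
  (defaults 0.12 / 0.07 / 0.012, the mix typical of national SPA rosters);
  `p_designation_only_c` adds designation-route tertiary facilities that
  fail basic infrastructure.
- **Regions**: Voronoi cells of the most populous settlements, clipped to
  the square extent — valid, non-overlapping, exhaustive.

Presets: `sparse` (120 km square, 10 settlements, ~3 persons/km², 500 m
cells) and `dense` (50 km square, 12 settlements, ~360 persons/km², 250 m
cells), with equal facility counts (30) so coverage contrasts reflect
geography rather than supply. The preset cell sizes are coarser than the
100 m default deliberately: they keep whole-pipeline runs and their oracle
recomputations fast while staying far below the 1,000 m buffer scale, where
the resolution-stability tests show < 1% sensitivity.

What the generator does **not** emulate: realistic road topology learned
from maps, dasymetric covariates (land use, night lights), facility-type
taxonomies, or survey nonresponse. Passing tests therefore demonstrate the
*correctness of the computation* on data with realistic spatial structure,
not the accuracy of any particular country estimate.

## Numerical choices

- Interval merging and membership use 1e-9 m tolerances; node merging
  1 m; snap ties break to the lowest edge id, region assignment to the
  lowest region id.
- Shortest paths run on the multigraph with the minimum parallel-edge
  length; the Dijkstra is seeded directly with along-edge offsets rather
  than a virtual node, so mid-edge sources are exact.
- Counts in rasters are floats; conservation assertions compare exactly
  because synthetic populations are integers.
- Degenerate inputs: empty service areas buffer to an empty polygon;
  zero-cutoff areas are points; levels with no capable facility yield
  all-zero rows with a log entry; zero-population regions yield N/A.

## Testing strategy

Every stage has an independent oracle: a re-coded score-counting
classification predicate (10,000-vector random sweep plus worked
examples), an O(n²) pairwise segment-intersection planarizer, a pure-numpy
exhaustive nearest-point search, a lattice-graph Dijkstra (edges subdivided
at ≤ 1–5 m, routed by networkx) whose distances are exact at sample points,
and per-cell Python loops for zonal sums. End-to-end, pipeline
proportions must fall between oracle recomputations at buffer ∓/± the
sampling step (plus the buffer-sagitta allowance). Property tests cover
classification monotonicity, cutoff monotonicity, the source-union
property, Euclidean containment, partition conservation, UI bracketing and
generator determinism (byte-identical outputs at a fixed seed).

## Known limitations

- No reprojection: all inputs must already share a projected planar-meter
  CRS; the `crs` config field is declared metadata only.
- Raster I/O is single-band ESRI ASCII grid.
- Distance-based catchments ignore travel speed, mode, and barriers
  (rivers, closures); one-way and turn information is discarded by design.
- The cell-center rule can misassign up to one cell width of population at
  region/catchment boundaries; with 100–500 m cells against a 1,000 m
  buffer this is the dominant but small discretization term.
- Overlapping facility levels mean per-level results are not additive.
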