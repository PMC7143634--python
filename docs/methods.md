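# Methods

## Model

A street network is an undirected planar graph with metric polyline edge
geometry; all coordinates are assumed projected (metres). Facilities
("generators") and incidents live off-network and are projected to their
Euclidean-nearest location on an edge. A facility's projection becomes a
real graph node (its *anchor*), splitting the host edge; the network is then
*lixelized*: every edge is subdivided at fixed arc-length steps so that
graph nodes double as density sample points and partition boundaries land at
sub-edge resolution.

Incident risk is a network kernel density: at sample node `p`,

    f(p) = Σ_i (1/h²) · K(d(p, e_i)/h),   K(u) = ¾(1 − u²) for u ≤ 1, else 0,

with `d` the shortest-path network distance to the incident's projection
point `e_i` (incidents are *not* snapped to nodes; their partial offset
along the host edge is part of the distance) and `h` the search bandwidth.
Two conventions are worth flagging:

- The `1/h²` planar normalisation is kept although densities live on a
  1-D network (units m⁻²; a line-integral convention would use `1/h`).
  Only density *ratios* enter the cost blend, which renormalises by `ΣR`,
  so the convention has no downstream effect.
- The estimator is the naive kernel sum, without equal-split branch
  correction at intersections. The correction is a possible extension; the
  naive sum is what the cost model is defined on.

Per-segment risk `R_i` is the mean of `f` at the segment's two endpoint
nodes — deliberately scale-free, so `R_i` does not change when the lixel
size changes. Costs blend normalised length and risk:

    W_i = a · L_i/ΣL + (1 − a) · R_i/ΣR,   a ∈ [0, 1].

`Σ W_i = 1` by construction whenever `ΣR > 0`; with no incidents in range
anywhere the risk term is dropped (`W_i = L_i/ΣL`) and the run is flagged.

## Partitioning

Both network modes share a synchronized multi-source expansion: a single
priority queue over (cumulative cost, station id), every node claimed
exactly once by the first operator to pop it, ties to the lowest station id.
This is exactly the per-node argmin of single-source cumulative costs
(verified against an independent shortest-path oracle in the tests).

The constrained mode adds the response radius `D_max = speed·1000/60·time`
(defaults 32 km/h, 5 min → 2666.7 m, printed as "about 2667 m"):

- **Phase 1** — an operator may only claim a node whose cumulative
  *geometric* path length from its own anchor, measured along the expansion
  path (the claim tree), is ≤ `D_max`. Priority stays the blended cost
  `W_i`: competition is risk-weighted, the pause test is physical metres.
  An operator with no claimable frontier pauses.
- **Phase 2** — once every operator has paused, all resume synchronously:
  remaining nodes are claimed by cost accrued *beyond* each operator's
  phase-1 frontier (the priority clock resets at resumption). The
  alternative reading — keep total cumulative cost — is available as
  `PartitionConfig(phase2_cost_reset=False)`; the reset reading is the
  default because resuming "synchronously" implies operators restart on an
  equal footing regardless of how much cost they spent inside their radius.

Because every claim travels over an edge from the claimant's own territory,
each service area is a connected subgraph containing its anchor, in both
modes. Edges whose endpoints end up with different owners are split where
the two cumulative costs meet (`x = L(c_v − c_u + W)/(2W)` from the `u`
end, midpoint on exact ties), clamped strictly inside the edge.

Station projection offsets are ignored by default: the offsets are tens of
metres against kilometre-scale territories and largely cancel in the
competitive expansion. `include_projection_distance=True` starts each
operator with its projection distance as initial geometric debt and
`a·proj/ΣL` as initial cost; on the standard synthetic city this moves
per-station assigned length by well under 1% of network length.

## Evaluation machinery

- **Planar Thiessen baseline** assigns each lixel to the Euclidean-nearest
  station raw location by sub-edge midpoint. Midpoint containment is
  equivalent to polygon clipping at lixel resolution and avoids polygon
  robustness issues; the lixel size bounds the discretisation error.
- **Coverage length**: per station, a shortest-path sweep by metres from its
  anchor restricted to edges it owns (split edges are dead ends at the
  break). Covered length includes partial edge prefixes where `D_max` is
  exhausted mid-edge. Restricting the sweep to the station's own territory
  is the point: an enclave reachable only through another station's area
  does not count, which is why the planar baseline loses coverage despite
  assigning geometrically near streets.
- **Difference length**: total length of network whose owner differs between
  two partitions, on a common refinement of split offsets; symmetric, zero
  on identical partitions, and a pseudometric. Optional per-region breakdown
  by segment-midpoint point-in-polygon.
- **Enclave check**: connected components of each station's owned edge set
  via union-find; 1 = contiguous, ≥ 2 = enclaves, 0 = empty.
- **Dynamic runs**: one partition per (half-open) time window using only
  that window's incidents, compared against the all-data partition; empty
  windows fall back to pure length costs rather than failing.

## Synthetic data

No incident archive of this kind is publicly deposited, so a seeded
generator emulates the statistical structure the method operates on, at
reduced scale: a rows × cols grid street network (250 m spacing, 10%
position jitter, 8% edge dropout with connectivity enforced by redrawing),
stations near randomly chosen intersections offset ≤ 50 m off-network
(exercising projection) and pairwise separated, and incidents drawn monthly
per hotspot (Poisson counts; edges weighted by Gaussian decay of midpoint
distance to the hotspot centre; uniform offset along the edge; uniform date
within the month). All randomness derives from one seed through named
per-component streams, so regeneration is byte-identical and changing, say,
the station count does not perturb the incident draws.

The standard city configuration uses local hotspots (spread 400 m) *plus a
diffuse city-wide component* (spread 0.6× the grid extent, same monthly
rate). Urban fire incidents combine clusters with broad background
scatter; without the background, small NKDE bandwidths would leave most of
the network at exactly zero density, a regime real dense-city data does not
enter, and bandwidth-sensitivity behaviour would be dominated by that
artefact.

What the generator does **not** emulate: realistic road hierarchies and
block shapes, one-way streets, congestion, covariate-driven risk (land use,
building age), or seasonal trends in incident rates. Passing tests
demonstrate the algorithmic properties (oracle equivalence, continuity,
coverage dominance, trend directions) under these controlled conditions,
not calibration to any real city's absolute figures.

## Problem sizes and numerical choices

- Test suites use 10×10-grid city instances (3 stations, 2 hotspots,
  3 months, ≈ 60–70 incidents) across 50 seeds, and the full 20×20 /
  5-station / 12-month city (≈ 2100 lixel edges, ≈ 380 incidents) for the
  acceptance script and examples; these sizes keep a full pipeline run in
  the hundreds of milliseconds while leaving the response radius genuinely
  binding.
- Defaults: `a = 0.5`, `h = 1500 m`, lixel 100 m, 32 km/h, 5 min — the
  method's standard operating point. `h` and `a` are the values at which
  the underlying study found stable, balanced results; the lixel size is a
  declared default (fine enough that boundary-placement error ≤ 100 m),
  not an inferred one. Snap tolerance for topology building is 0.5 m
  (typical digitisation noise).
- Geometric tolerance is 1e-6 m throughout (length conservation, split
  interiority, densify idempotence); the expansion's radius test allows
  `D_max + 1e-6` to avoid excluding boundary nodes to float noise.
- Degenerate inputs: zero-length features are rejected with a warning;
  stations projecting onto an existing node reuse it; two stations sharing
  an anchor node is an error (ambiguous generators); components with no
  station stay unassigned and are reported, not errors.

## Known limitations

- The bandwidth-sensitivity trend (difference from the plain network
  Voronoi shrinking as `h` grows) is a property of the incident pattern,
  not of the algorithm: it holds on the standard fixture and for most
  seeds, but individual seeds at full scale can reverse it. The test
  asserts it where it is a stable consequence of the study conditions.
- Undirected edges, single speed, no turn penalties or congestion; capacity
  of stations (engines, staff) is not modelled.
- The naive NKDE over-weights dense intersections relative to equal-split
  corrected estimators; with `a = 0.5` the effect on boundaries is modest
  but nonzero.
- CLI-level `metrics` recomputes coverage from per-segment expansion-path
  distances recorded in the GeoJSON, which can differ slightly from the
  library's sweep-based coverage on territories where the claim tree is not
  the within-territory shortest path; the `partition` subcommand always
  emits the sweep-based CSV.
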