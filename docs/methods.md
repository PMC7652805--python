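# Methods

## Spatial units

All computations live on a regular lon/lat grid aligned to the global
c-squares lattice (supported cell sizes: 10, 5, 1, 0.5, 0.1, 0.05, 0.01,
0.005, 0.001°; default 0.05°, a typical VMS-effort mapping scale — the
resolution is a free choice and is exposed everywhere). Each cell is
identified by its c-squares string, rebuilt from the published notation
rules: a global-quadrant digit (1 NE, 3 SE, 5 SW, 7 NW), the 10° lat
digit and two lon digits, then colon-separated refinement cycles — an
intermediate-quadrant digit (1 low/low … 4 high/high) alone for a
halving step, or followed by a lat and a lon digit for a divide-by-ten
step. The implementation was checked against the scheme's canonical
Hobart example (`3414:227:3` at 0.5°) and, in the tests, against an
independent exact-rational re-derivation on random points.

Numerical conventions:

- Cells are half-open `[lo, hi)` in both axes; lat 90 / lon 180 clamp
  into the last cell; the equator and prime meridian belong to the
  non-negative quadrant. Deterministic, and consistent with raster
  conventions.
- Positions are snapped to a milli-degree integer lattice (±1e-9°)
  before cell indexing, so decimal coordinates that are not binary-exact
  (0.15, 41.77, …) land on the intended side of a lattice line.
- A cell belongs to the study grid iff its intersection with the
  boundary polygon has positive area (> 1e-9 of the cell's area): cells
  merely touching the boundary's edge are excluded, so an axis-aligned
  box tiles exactly.
- Cell areas use the closed-form lat/lon-rectangle area on the authalic
  sphere, A = R²·Δλ·(sin φ₂ − sin φ₁) with R = 6371.0088 km, so km²
  statistics are latitude-correct without a projection library.
- Cell ids are 0-based, ordered south→north then west→east; they are
  stable across runs for a fixed boundary and resolution.

## Fishing effort

Track points (vessel id, UTC timestamp, lon/lat, speed over ground) are
sorted, deduplicated, and classified as *fishing* iff lo ≤ speed ≤ hi
(default 2–4.5 kn). This speed filter is a deliberate simplification of
metier-aware track classification chains; it is the configurable
boundary of this package, not a claim about the best classifier.

- **Fishing hours** = fishing-ping count × interval/60 per cell and
  quarter. The interval defaults to 10 min and is not inferred from the
  data; totals therefore reconcile exactly with ping counts.
- **Fishing days**: FD(vessel, frame) = number of distinct UTC dates
  with ≥ 1 fishing ping. The gridding of a day-level quantity is
  underdetermined; we attribute each vessel-day to cells proportionally
  to that day's in-grid fishing-ping counts, which conserves the fleet
  total. A day fished entirely outside the grid still counts in the
  per-vessel FD table but has no cells to receive it.
- **Nominal effort** = FD × PW (kW·days), gridded with the same
  proportional attribution. Vessels missing from the register are
  skipped and reported in the QC summary.
- **Swept area**: OFS = a·LOA + b meters from the per-gear linear
  width model (defaults for the synthetic OTB fleet: a = 2, b = 10,
  generic values for a demersal otter trawl's wing-tip opening); TL is
  accumulated over consecutive fishing-ping pairs, with the haul broken
  by any intervening non-fishing ping or a gap > 30 min. Tracks are
  used at native ping rate — no resampling or interpolation; an
  interpolation hook would slot in before classification. Segment
  lengths are great-circle (haversine, authalic R); each segment's
  length is apportioned to cells by the fraction of the lon/lat chord
  inside each cell (ratios, so the spherical correction cancels).
  Non-towed gears (purse seine) produce no swept area by construction.

Quarters are calendar quarters (Q1 = Jan–Mar) of UTC dates; yearly
layers are sums of quarterly ones.

A note on monotonicity: widening the speed window can never decrease
fishing hours or swept area in any cell, nor any per-vessel FD. It *can*
decrease a day-based metric in a particular cell, because newly
classified pings shift the proportional day shares between cells. The
tests assert the per-cell property only for the metrics where it truly
holds.

## Persistence Index

Hotspot rule: a cell is a hotspot in a year iff its density strictly
exceeds the q-quantile (default 0.9, linear interpolation) of that
year's *positive*-density cells. Strictness makes a constant surface
hotspot-free; restricting to positive cells keeps large empty areas from
dragging the threshold down. This rule replaces survey-specific
geostatistical delineations (kriged-density thresholds), which need raw
survey data; it preserves the PI semantics and is pluggable. Externally
delineated UWC polygon layers carrying a `pi` attribute can be
rasterized onto the grid instead (each cell takes the PI of the polygon
covering the largest share of it).

PI(cell) = (# years flagged)/(# years) lies on the lattice {k/n} and is
invariant to year order. PI = 0 cells are exactly those never flagged.

Same-PI contiguous cells dissolve into polygons under the package-wide
adjacency convention (see below).

## Fuzzy overlay

Fuzzy Linear: μ(x) = 0 below min, 1 above max, linear between; by
continuity μ(min) = 0 and μ(max) = 1. Degenerate anchors (min = max)
arise for constant layers; memberships are then 1 where the value is
positive and 0 otherwise, with a warning — a constant positive layer is
"everywhere maximal".

Fuzzy Product: cellwise product of memberships; commutative,
associative, bounded above by the smallest input.

Pipeline: per quarter (or year), effort and the species' PI are each
fuzzified and multiplied. The PI layer is held constant across frames
(UWC maps are treated as stable relative to effort dynamics), and the PI
series must cover every effort year. Effort anchors default to the
min/max over the *whole* multi-year series (`global`), so overlay values
are comparable across frames; `per_frame` anchoring is available when
each frame should be judged against its own distribution. Anchors are
computed over grid cells only (absent cells count as 0 inside the grid;
the world outside the grid is ignored).

## Overlap analysis

Threshold ranges are closed on both ends (matching inclusive slider
semantics); cells without recorded effort count as effort 0. Contiguity
is 4-connectivity (shared edge) by default — "contiguous" is read as
sharing a boundary, and corner-touching cells share none — with
8-connectivity as a switch. Components are labelled deterministically by
their smallest cell id. The statistics table reports cell and component
counts, total km², min/mean/max of effort and PI within the selection,
and the selection's share of the frame's total effort; means of an empty
selection are reported as missing, not 0. With both ranges set to the
full data range, the selection provably contains every cell with a
positive fuzzy product — the two analyses answer different questions
(crisp area selection vs. graded coincidence) and the tests assert this
containment.

## Synthetic case study

The generator states a small trawl-fishery world: a 1°×1° open-water box
(centered near an isolated Pacific atoll), years 2012–2016, 10-minute
pings matching the fishing-hours constant, six trawlers (LOA uniform
12–30 m, power ≈ 20·LOA + noise kW) fishing 40 days a year, trawl speeds
3 ± 0.4 kn vs. steaming 9 ± 1 kn — comfortably separated across the
2–4.5 kn filter. Each vessel-day steams from port to a weight-sampled
effort patch, trawls for 36 pings in a mean-reverting correlated random
walk around the patch center (the reversion keeps ≥ 90 % of fishing
pings within 3 sd), and steams home. Species density surfaces are sums
of stationary Gaussian patches evaluated at cell centers plus additive
Gaussian noise truncated at zero (sd 0.5; lognormal multiplicative noise
as an alternative). One species patch coincides with an effort patch by
default, giving the pipeline a known ground-truth coincidence; stationary
patches make patch cores hotspots every year (PI = 1).

What a green test on this world does establish: unit conversions,
conservation laws, the formula chain effort → PI → overlay → overlap,
and that the overlay's argmax recovers a known coincident patch. What it
does not: realism of vessel behaviour (no bathymetry, economics, gear
interaction, port choice), survey noise structure (no spatial
autocorrelation in the noise), or classifier quality on real mixed-gear
tracks.

All randomness flows from one seed through named `SeedSequence`
children; identical configs give byte-identical CSVs.

## Known limitations

- Geographic I/O is GeoJSON-only (WGS84); no shapefile or GeoTIFF
  codecs. Grids, PI maps and overlap selections export as GeoJSON with
  the same attribute tables a shapefile would carry.
- The speed-filter classifier ignores gear and metier; hauls are
  reconstructed from ping adjacency, not from logbooks.
- Segment–cell apportionment treats pings' chords as straight in lon/lat;
  at the sub-km segment lengths of 10-minute pings the induced error is
  far below the cell size.
- The quantile hotspot rule is a stand-in; where kriged survey products
  exist, supply them as UWC polygons instead.
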