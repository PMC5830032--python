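# Methods

## The question

Protected areas (PAs) cover roughly 14% of land and are mostly small — far
smaller than the climatic shifts they will face. One practical response is
*partnering*: coordinated management across a PA and its neighbors (other
PAs, or any surrounding land) out to some maximum linear distance *r*, the
partnership scale. adaptscape quantifies what a PA gains from partnering at
scale *r* through five biodiversity adaptation indicators computed in a
circular moving window of radius *r* around each focal cell, contrasts
partnership scenarios against no-partnering null models, and combines the
indicators into a single adaptation-potential surface.

## Indicators

All are reductions over the *target* cells inside the focal window (target =
PA cells, or all land cells, depending on the scenario):

- **A — land and freshwater area** (km²): number of target cells × cell
  area. More area means more populations, more habitat, more room to move.
- **L — latitudinal range** (degrees): max − min latitude of target cells,
  irrespective of longitude. A proxy for the pole-ward displacement capacity
  of the partnership.
- **E — elevational range** (m): max − min elevation of target cells.
  Short up-slope moves substitute for long pole-ward ones.
- **H — relief-weighted hydrologic area** (km²): over target cells lying on
  the hydrologic network, Σ (eᵢ − min e), where min e is the minimum
  elevation over **all** target cells in the window (the window minimum, not
  the network minimum — this is the reading under which valley-bottom area
  grows with the elevational relief available to the whole partnership).
  The relief term is treated as a dimensionless weight on cell area, so H
  carries km². High H marks dense drainage with strong relief: valley-bottom
  and riparian area through which aquatic-associated biodiversity can adapt.
- **V — climate-area velocity** (yr⁻¹): |window mean of (future − now)/Δt|
  divided by (population s.d. of the baseline climate over target cells
  + 0.1). Computed separately for annual mean temperature (°C) and annual
  precipitation (mm). V is the factor by which partnership area would need
  to grow per year for the future to retain the current climate space;
  bigger windows hold more baseline climate variation and hence lower V.
  The classical local-gradient climate-change velocity is deliberately not
  used: its denominator is defined on a 3×3 neighborhood and does not
  generalize to windows of 10⁵–10⁶ km².

The 0.1 floor is added to σ unconditionally, so the no-partner limit
(σ = 0) is the continuous limit of the general formula rather than a special
case; `floor_constant` is exposed on every velocity entry point.

A Monte-Carlo companion (`simulate_climate_space_retention`) grounds the
interpretation of V: draw n current values from Normal(0, σ) and n future
values from Normal(shift, σ), and measure the fraction of future draws
inside the realized [min, max] of the current sample. Its reciprocal is the
area-growth factor; adding 1 additionally accounts for retaining the current
space itself.

## Scenarios and null models

- `pixel_null` — every cell acts alone (r = 0): A = cell area,
  L = E = H = 0, V = |rate| / 0.1. The floor of every comparison.
- `pa_null` — partnering only within one's own administratively distinct
  PA: each indicator is reduced once over each PA's full cell set and
  broadcast back to its cells.
- `pa_partnership` — targets are PA cells within r.
- `pa_nonpa_partnership` — targets are all land cells within r (the
  idealized scenario).

Scenario pairs are summarized as signed factors between mean indicator
values: a ratio ≥ 1 is reported as-is, a ratio < 1 as −1/ratio, so a
decrease by x prints −x and |factor| ≥ 1 always. Means are taken over PA
focal cells only (the per-PA benefit framing; configurable), equally
weighted — true cell areas vary with latitude on a geographic grid, but the
package treats grids as abstract equal-area lattices.

Partner composition asks, per focal cell, what percentage of the land in
the window is protected, summarized over PA and non-PA focal cells by the
mean percentage and by the share of cells exceeding 50% (an area share,
since cells are equal-area).

Partnership scales worth evaluating are taken from the size distribution of
established trans-boundary partnerships: the 5th/50th/95th percentiles of a
partnership-area table (km²), convertible to equivalent circular radii
√(area/π).

## Windows and the focal engine

Kernels are discrete circles under the cell-center rule: offset (i, j) is
included iff (i² + j²)·cell² ≤ r². At r = 3 km on a 1 km grid this gives
the canonical 29-cell window. (Published window areas at larger radii mix
discrete and continuous-circle conventions and are mutually inconsistent —
e.g. some are even numbers, impossible for a centrally symmetric discrete
kernel — so one rule is fixed and only the r = 3 count is treated as an
exact anchor.)

Windows truncate at grid edges; an empty window (no qualifying target cell)
yields a nodata sentinel, never zero, because zero is a meaningful value for
every indicator. The s.d. statistic is the population form (divisor n), the
raster focal-statistics convention, computed in two passes for numerical
robustness. The engine accumulates shifted array slices over kernel offsets
in sorted order, so its floating-point sums are bit-identical to a per-cell
loop over sorted offsets — the property the test suite's brute-force oracle
checks — and offsets that miss the grid entirely are skipped, bounding the
cost for arbitrarily large radii on small grids.

## Normalization and the adaptation potential

Each indicator is divided by its maximum over all computed cells (all
focal cells that received a value — the natural domain when the run is
restricted to PA focals). Velocity is inverted (1 − x) **after**
normalization, which keeps [0, 1] without a second pass; the temperature
and precipitation velocities are first averaged into one layer so exactly
five indicators enter the final cell-wise mean (a six-layer variant is
switchable). Nodata propagates through the mean. Zonal summaries report the
mean potential per nonzero zone id; zones with no valid cells are emitted
as flagged rows rather than dropped.

## Synthetic landscapes

The generator emulates the structure the indicators respond to, not any
real geography:

- **Terrain**: a sum of `n_hills` random Gaussian hills plus a gentle
  regional tilt, rescaled so the realized range equals `relief_m` exactly
  (default 1500 m — mid-mountain terrain). Simpler than spectral synthesis
  but still yields nested valleys for flow routing.
- **Hydrography**: D8 steepest-descent routing (drop per unit distance,
  diagonals √2) on the terrain after priority-flood depression filling
  (spill increment 10⁻⁹) and a deterministic tie-break of
  10⁻⁶·(row·n_cols + col); cells with upstream accumulation ≥
  `hydro_threshold` (default 20 cells) form the network.
- **Protected areas**: `n_pas` (default 12) blobs grown from random seeds
  by randomized frontier expansion to log-normally apportioned quotas
  totalling `pa_fraction` (default 0.14) of the grid; each PA is one
  connected component.
- **Climate**: T = 45 − 0.0065·elev − 0.7·lat + N(0, 0.5) °C (standard
  environmental lapse rate; at the default 45° N top latitude this gives
  ~13 °C sea-level means); P = 800 + 0.5·elev + N(0, 60) mm (orographic
  enhancement). Futures add a smooth delta (Gaussian-filtered white noise,
  filter scale one-eighth of the domain) with mean +4.75 °C / +40 mm and
  spatial s.d. 0.6 °C / 30 mm over `years_elapsed` = 95 years — i.e. a mean
  warming rate of 0.05 °C/yr, a high-emission trajectory from a mid-1970s
  baseline to a ~2070 horizon.
- **Latitude** is a per-row linear ramp (cell_km/111.32 degrees per row);
  no projection is modelled.
- **Partnership sizes**: log-normal with log-mean 12.1 and log-s.d. 1.3,
  placing the 5th/50th/95th percentiles in the 10⁴–10⁶ km² span of
  documented partnerships.

What the generator does **not** emulate: real PA size distributions, real
hypsometry, climate-model spatial covariance, coastlines/ocean nodata, or
any spatial autocorrelation target. Passing tests therefore demonstrate the
correctness and qualitative behavior of the method (monotone indicator
growth with scale, declining velocity, null-model limits), not quantitative
agreement with any real-world analysis.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on 128×128-cell landscapes
with radii 3–27 km (oracle equivalence uses ≤16×16 grids with radii ≤ 4),
sizes at which the full pipeline completes in seconds while exercising every
code path; the engine itself accepts arbitrary grids and radii. Comparison
factors in the acceptance report contrast the range-type indicators (L, E,
H) against the PA-null model because they are identically zero under the
pixel null (any finite value is an infinite factor increase). Degenerate
inputs fail loudly: empty partnership tables, non-positive scenario means,
all-zero indicator layers, PA-focal scenarios on PA-free landscapes and
non-divisible aggregation tilings all raise typed errors rather than
returning silent zeros.

## Known limitations

- Equal cell weighting everywhere; no geodesic kernels or great-circle
  distances.
- No vector (polygon) processing: PA input begins at the rasterized stage,
  coarsened with the any-presence rule.
- No reprojection or resampling beyond presence aggregation.
- The latitudinal range is reported in degrees, not km.
- Published global magnitudes (global indicator tables, global maps) depend
  on the real global rasters and are out of scope; the package reproduces
  the computational form, sign conventions and desk-scale geometry.
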