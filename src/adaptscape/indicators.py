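"""The five biodiversity adaptation indicators.

Each indicator is evaluated in a circular moving window of radius *r* (the
partnership scale) over *target* cells — the cells a focal protected area
could partner with:

* **A** — land and freshwater area: count of target cells x cell area (km²).
* **L** — latitudinal range: max − min latitude of target cells (degrees),
  irrespective of longitude.
* **E** — elevational range: max − min elevation of target cells (m).
* **H** — relief-weighted hydrologic area: for target cells on the
  hydrologic network, the sum of each cell's elevation above the window
  minimum (taken over *all* target cells in the window), treated as a
  dimensionless weight on cell area, so H carries km². A measure of valley-
  bottom area available to aquatic and riparian-associated biodiversity.
* **V** — climate-area velocity (yr⁻¹): |window mean of the per-cell climate
  change rate| divided by the spatial standard deviation of the baseline
  climate across target cells, plus a floor constant (default 0.1) that
  keeps the ratio finite as spatial variation vanishes. Interpretable as the
  factor by which partnership area must grow per year to retain the current
  climate space; computed once for temperature and once for precipitation.

Large windows raise A, L, E and H and — by increasing baseline spatial
climate variation — lower V, which is the adaptation rationale for
partnering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import CoRegistrationError, InvalidParameterError
from .focal import (
    Kernel,
    iter_window_slices,
    window_count,
    window_max,
    window_mean,
    window_min,
    window_sd,
)
from .grids import Grid

__all__ = [
    "ClimatePair",
    "IndicatorSet",
    "compute_area",
    "compute_lat_range",
    "compute_elev_range",
    "compute_relief_hydro",
    "compute_climate_area_velocity",
    "simulate_climate_space_retention",
    "RetentionResult",
]

INDICATOR_NAMES = ("area", "lat_range", "elev_range", "relief_hydro",
                   "velocity_t", "velocity_p")


@dataclass
class ClimatePair:
    """Current and future grids of one climate variable, Δt years apart."""

    now: Grid
    future: Grid
    years_elapsed: float

    def __post_init__(self) -> None:
        self.now.check_coregistered(self.future)
        if self.years_elapsed <= 0:
            raise CoRegistrationError("years_elapsed must be positive")

    @property
    def rate(self) -> np.ndarray:
        """Per-cell change rate (units/yr)."""
        return (self.future.values - self.now.values) / self.years_elapsed


@dataclass
class IndicatorSet:
    """The six indicator surfaces for one scenario x scale."""

    area: Grid            # A, km²
    lat_range: Grid       # L, degrees
    elev_range: Grid      # E, m
    relief_hydro: Grid    # H, km²
    velocity_t: Grid      # V for temperature, yr⁻¹
    velocity_p: Grid      # V for precipitation, yr⁻¹

    def items(self):
        for name in INDICATOR_NAMES:
            yield name, getattr(self, name)

    def __getitem__(self, name: str) -> Grid:
        if name not in INDICATOR_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _valid(grid: Grid, target: np.ndarray) -> np.ndarray:
    target = np.asarray(target, dtype=bool)
    if target.shape != grid.shape:
        raise CoRegistrationError("target mask shape must match the grid")
    return target & ~grid.nodata


def compute_area(template: Grid, target: np.ndarray, kernel: Kernel) -> Grid:
    """A = number of qualifying target cells x cell area (km²)."""
    valid = _valid(template, target)
    count = window_count(valid, kernel)
    empty = count == 0
    return template.like(count * template.cell_area_km2, nodata=empty)


def compute_lat_range(latitudes: Grid, target: np.ndarray, kernel: Kernel) -> Grid:
    """L = max − min latitude over qualifying target cells (degrees)."""
    valid = _valid(latitudes, target)
    lo = window_min(latitudes.values, valid, kernel)
    hi = window_max(latitudes.values, valid, kernel)
    empty = window_count(valid, kernel) == 0
    return latitudes.like(np.where(empty, 0.0, hi - lo), nodata=empty)


def compute_elev_range(elevation: Grid, target: np.ndarray, kernel: Kernel) -> Grid:
    """E = max − min elevation over qualifying target cells (m)."""
    valid = _valid(elevation, target)
    lo = window_min(elevation.values, valid, kernel)
    hi = window_max(elevation.values, valid, kernel)
    empty = window_count(valid, kernel) == 0
    return elevation.like(np.where(empty, 0.0, hi - lo), nodata=empty)


def compute_relief_hydro(elevation: Grid, hydro: np.ndarray, target: np.ndarray,
                         kernel: Kernel) -> Grid:
    """H = Σ over hydro-network target cells of (e_i − window min e) x cell area.

    The window minimum is taken over all qualifying target cells, not only
    network cells; windows holding target cells but no network cells score 0.
    """
    valid = _valid(elevation, target)
    hydro = np.asarray(hydro, dtype=bool)
    if hydro.shape != elevation.shape:
        raise CoRegistrationError("hydro mask shape must match the grid")
    minv = window_min(elevation.values, valid, kernel)
    empty = window_count(valid, kernel) == 0
    valid_h = valid & hydro
    acc = np.zeros(elevation.shape, dtype=np.float64)
    e = elevation.values
    for dst, src in iter_window_slices(elevation.shape, kernel):
        contrib = np.where(valid_h[src], e[src] - minv[dst], 0.0)
        acc[dst] += contrib
    out = np.where(empty, 0.0, acc * elevation.cell_area_km2)
    return elevation.like(out, nodata=empty)


def compute_climate_area_velocity(pair: ClimatePair, target: np.ndarray,
                                  kernel: Kernel, floor_constant: float = 0.1) -> Grid:
    """V = |window mean change rate| / (window s.d. of baseline + floor).

    The numerator averages the per-cell rate (future − now)/Δt over
    qualifying target cells and takes the absolute value; the denominator is
    the population standard deviation of the baseline values over the same
    cells, plus ``floor_constant``, which both avoids division by zero and
    defines the no-partner limit (σ = 0 → denominator = floor).
    """
    if floor_constant < 0:
        raise InvalidParameterError("floor_constant must be >= 0")
    valid = _valid(pair.now, target) & ~pair.future.nodata
    count = window_count(valid, kernel)
    empty = count == 0
    num = np.abs(window_mean(pair.rate, valid, kernel, count=count))
    den = window_sd(pair.now.values, valid, kernel, count=count) + floor_constant
    with np.errstate(invalid="ignore", divide="ignore"):
        v = num / den
    return pair.now.like(np.where(empty, 0.0, v), nodata=empty)


class RetentionResult(NamedTuple):
    """Outcome of the climate-space retention simulation."""

    retention: float            # fraction of future draws inside current range
    area_factor: float          # 1 / retention (inf when retention is 0)
    area_factor_adjusted: float  # area_factor + 1 (accounts for current space)


def simulate_climate_space_retention(
    mean_shift: float, sd: float, n: int = 1000, seed: int | None = None
) -> RetentionResult:
    """Monte-Carlo interpretation of climate-area velocity as an area factor.

    Draws ``n`` current values from Normal(0, sd) and ``n`` future values
    from Normal(mean_shift, sd), and measures the fraction of future values
    falling within the [min, max] range of the current sample. The
    reciprocal is the factor by which area must grow so the future still
    contains the current climate space; adding 1 additionally accounts for
    keeping the current space itself.
    """
    if sd <= 0:
        raise InvalidParameterError("sd must be > 0")
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    rng = np.random.default_rng(seed)
    current = rng.normal(0.0, sd, n)
    future = rng.normal(mean_shift, sd, n)
    inside = (future >= current.min()) & (future <= current.max())
    retention = float(inside.mean())
    factor = 1.0 / retention if retention > 0 else float("inf")
    adjusted = factor + 1.0 if np.isfinite(factor) else float("inf")
    return RetentionResult(retention, factor, adjusted)
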