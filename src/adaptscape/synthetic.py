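"""Synthetic landscapes with the statistical structure the analysis assumes.

Real inputs to the partnership analysis are a ~1 km DEM, a hydrologic
network, a rasterized protected-area (PA) inventory, and current/future
climate normals. This module generates stand-ins with the features the
indicators respond to: terrain with configurable relief, a drainage network
derived from that terrain by D8 flow accumulation, a mosaic of discrete PAs
covering a configurable land fraction (default 14%, the approximate global
terrestrial PA share), climate correlated with elevation and latitude plus
noise, and a spatially smooth future climate delta.

All generators are deterministic for a fixed seed; each draws from its own
seeded stream so layers can be regenerated independently.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CoRegistrationError, InvalidParameterError
from .grids import Grid
from .landscape import Landscape

__all__ = [
    "LandscapeParams",
    "generate_elevation",
    "derive_hydro_network",
    "flow_accumulation",
    "generate_pa_mosaic",
    "generate_climate",
    "generate_partnership_sizes",
    "generate_zones",
    "generate_landscape",
]

# degrees of latitude per km (spherical Earth, meridian arc)
_DEG_PER_KM = 1.0 / 111.32


@dataclass(frozen=True)
class LandscapeParams:
    """Knobs for the synthetic landscape.

    Climate follows a linear physical model: temperature decreases with
    elevation at ``lapse_rate`` (°C per m) and with latitude at
    ``lat_gradient`` (°C per degree), around ``t_intercept`` (°C at zero
    elevation and latitude). Precipitation increases with elevation
    (orographic effect) from ``precip_base``. The future climate is the
    current one plus a spatially smooth delta with mean ``delta_t_mean`` /
    ``delta_p_mean`` and spatial s.d. ``delta_t_sd`` / ``delta_p_sd``.
    The default temperature delta of 4.75 °C over 95 years corresponds to a
    warming rate of 0.05 °C/yr, a high-emission end-of-century trajectory.
    """

    n_rows: int = 128
    n_cols: int = 128
    cell_km: float = 1.0
    lat_top: float = 45.0                   # latitude of row 0 centers, deg
    relief_m: float = 1500.0
    n_hills: int = 30
    hydro_threshold: int = 20               # accumulation cells for network
    pa_fraction: float = 0.14
    n_pas: int = 12
    t_intercept: float = 45.0               # °C at elevation 0, latitude 0
    lapse_rate: float = -0.0065             # °C per m
    lat_gradient: float = -0.7              # °C per degree latitude
    precip_base: float = 800.0              # mm
    precip_relief_coeff: float = 0.5        # mm per m
    noise_sd_t: float = 0.5                 # °C
    noise_sd_p: float = 60.0                # mm
    delta_t_mean: float = 4.75              # °C over years_elapsed
    delta_p_mean: float = 40.0              # mm
    delta_t_sd: float = 0.6                 # spatial s.d. of ΔT, °C
    delta_p_sd: float = 30.0                # spatial s.d. of ΔP, mm
    years_elapsed: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InvalidParameterError("grid dimensions must be positive")
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise InvalidParameterError("pa_fraction must lie in [0, 1]")
        if self.n_pas < 0:
            raise InvalidParameterError("n_pas must be >= 0")
        if self.cell_km <= 0:
            raise InvalidParameterError("cell_km must be positive")
        if self.years_elapsed <= 0:
            raise InvalidParameterError("years_elapsed must be positive")

    @property
    def row_latitudes(self) -> np.ndarray:
        """Linear latitude ramp, decreasing southward from lat_top."""
        step = -self.cell_km * _DEG_PER_KM
        return self.lat_top + step * np.arange(self.n_rows, dtype=np.float64)


def _rng(params: LandscapeParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def generate_elevation(params: LandscapeParams) -> np.ndarray:
    """Terrain as a sum of random Gaussian hills plus a gentle regional tilt.

    The summed field is rescaled linearly so the realized range equals
    ``relief_m`` exactly; ``relief_m = 0`` yields a flat (all-zero) grid.
    The tilt prevents large exterior flats so D8 routing drains off-grid.
    """
    rng = _rng(params, 0)
    nr, nc = params.n_rows, params.n_cols
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    surface = np.zeros((nr, nc), dtype=np.float64)
    scale = min(nr, nc)
    for _ in range(params.n_hills):
        cy, cx = rng.uniform(0, nr), rng.uniform(0, nc)
        sigma = rng.uniform(0.05, 0.25) * scale
        amp = rng.uniform(0.2, 1.0)
        surface += amp * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2))
    sd = surface.std()
    if sd > 0:
        theta = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(theta) * rows + np.sin(theta) * cols) / scale
        surface = surface + 0.15 * sd * ramp
    span = surface.max() - surface.min()
    if span == 0 or params.relief_m == 0:
        return np.zeros((nr, nc), dtype=np.float64)
    return (surface - surface.min()) / span * params.relief_m


_D8_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_D8_DIST = [np.sqrt(2), 1.0, np.sqrt(2), 1.0, 1.0, np.sqrt(2), 1.0, np.sqrt(2)]


def _fill_depressions(z: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Priority-flood depression filling with a tiny gradient.

    Raises every interior pit/flat to just above its spill point so each
    cell has a strictly descending D8 path to the grid edge.
    """
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r in range(nr):
        for c in range(nc):
            if r in (0, nr - 1) or c in (0, nc - 1):
                filled[r, c] = z[r, c]
                visited[r, c] = True
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr, dc in _D8_NEIGHBORS:
            nr_, nc_ = r + dr, c + dc
            if 0 <= nr_ < nr and 0 <= nc_ < nc and not visited[nr_, nc_]:
                visited[nr_, nc_] = True
                filled[nr_, nc_] = max(z[nr_, nc_], zc + eps)
                heapq.heappush(heap, (filled[nr_, nc_], counter, nr_, nc_))
                counter += 1
    return filled


def _d8_downstream(z: np.ndarray) -> np.ndarray:
    """Flat index of each cell's steepest-descent neighbor, -1 for outlets.

    Steepness is drop per unit distance (diagonal distance sqrt(2))."""
    nr, nc = z.shape
    best_grad = np.zeros((nr, nc), dtype=np.float64)
    down = np.full((nr, nc), -1, dtype=np.int64)
    for (dr, dc), dist in zip(_D8_NEIGHBORS, _D8_DIST):
        grad = np.full((nr, nc), -np.inf)
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        grad[r0:r1, c0:c1] = (z[r0:r1, c0:c1] - z[r0 + dr:r1 + dr, c0 + dc:c1 + dc]) / dist
        take = grad > best_grad
        best_grad[take] = grad[take]
        rows, cols = np.nonzero(take)
        down[rows, cols] = (rows + dr) * nc + (cols + dc)
    return down


def flow_accumulation(elevation: np.ndarray) -> np.ndarray:
    """D8 flow accumulation (cells draining through each cell, inclusive).

    Exact elevation ties are broken by adding ``1e-6 * (row * n_cols + col)``
    before routing; depressions are filled by priority flood so all flow
    reaches the grid edge.
    """
    elevation = np.asarray(elevation, dtype=np.float64)
    if not np.all(np.isfinite(elevation)):
        raise InvalidParameterError("elevation must be finite")
    nr, nc = elevation.shape
    tie = 1e-6 * (np.arange(nr)[:, None] * nc + np.arange(nc)[None, :])
    z = _fill_depressions(elevation + tie)
    down = _d8_downstream(z).ravel()
    acc = np.ones(nr * nc, dtype=np.int64)
    order = np.argsort(z, axis=None, kind="stable")[::-1]  # high to low
    for idx in order:
        d = down[idx]
        if d >= 0:
            acc[d] += acc[idx]
    return acc.reshape(nr, nc)


def derive_hydro_network(elevation: np.ndarray, accumulation_threshold: int) -> np.ndarray:
    """Cells whose D8 upstream accumulation reaches the threshold."""
    if accumulation_threshold < 1:
        raise InvalidParameterError("accumulation_threshold must be >= 1")
    return flow_accumulation(elevation) >= accumulation_threshold


def generate_pa_mosaic(params: LandscapeParams) -> np.ndarray:
    """Discrete protected areas by seeded random blob growth.

    Returns an id grid: 0 = non-PA, 1..n_pas = distinct PAs, each a
    connected component. Total PA cells target ``pa_fraction`` of the grid;
    individual PA sizes vary log-normally.
    """
    nr, nc = params.n_rows, params.n_cols
    cells = nr * nc
    target = int(round(params.pa_fraction * cells))
    if params.pa_fraction * cells < params.n_pas:
        raise InvalidParameterError(
            f"pa_fraction * cells = {params.pa_fraction * cells:.1f} "
            f"cannot seat {params.n_pas} distinct PAs"
        )
    ids = np.zeros((nr, nc), dtype=np.int64)
    if target == 0 or params.n_pas == 0:
        return ids
    rng = _rng(params, 1)
    # per-PA quotas: lognormal proportions of the target, each at least 1
    weights = rng.lognormal(0.0, 0.8, params.n_pas)
    quotas = np.maximum(1, np.floor(weights / weights.sum() * target)).astype(int)
    while quotas.sum() > target:
        quotas[int(np.argmax(quotas))] -= 1
    while quotas.sum() < target:
        quotas[int(rng.integers(params.n_pas))] += 1
    seeds = rng.choice(cells, size=params.n_pas, replace=False)
    frontiers: list[list[int]] = [[] for _ in range(params.n_pas)]
    sizes = np.zeros(params.n_pas, dtype=int)
    flat = ids.ravel()
    for k, s in enumerate(seeds):
        if flat[s] == 0:
            flat[s] = k + 1
            sizes[k] = 1
            frontiers[k].append(int(s))
    active = [k for k in range(params.n_pas) if sizes[k] < quotas[k]]
    while active:
        k = active[int(rng.integers(len(active)))]
        grown = False
        while frontiers[k]:
            i = int(rng.integers(len(frontiers[k])))
            cell = frontiers[k][i]
            r, c = divmod(cell, nc)
            free = [(r + dr) * nc + (c + dc)
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= r + dr < nr and 0 <= c + dc < nc
                    and flat[(r + dr) * nc + (c + dc)] == 0]
            if not free:
                frontiers[k][i] = frontiers[k][-1]
                frontiers[k].pop()
                continue
            new = free[int(rng.integers(len(free)))]
            flat[new] = k + 1
            sizes[k] += 1
            frontiers[k].append(new)
            grown = True
            break
        if not grown or sizes[k] >= quotas[k]:
            active.remove(k)
    return ids


def generate_climate(
    elevation: np.ndarray,
    latitude: np.ndarray,
    params: LandscapeParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Current and future temperature (°C) and precipitation (mm) grids.

    Returns ``(t_now, t_future, p_now, p_future)``. The future equals the
    present plus a smooth delta surface (Gaussian-filtered noise scaled to
    ``delta_*_sd`` around ``delta_*_mean``).
    """
    elevation = np.asarray(elevation, dtype=np.float64)
    latitude = np.asarray(latitude, dtype=np.float64)
    if latitude.shape != (elevation.shape[0],):
        raise CoRegistrationError("latitude vector length must equal n_rows")
    lat2d = np.broadcast_to(latitude[:, None], elevation.shape)
    rng = _rng(params, 2)
    t_now = (params.t_intercept + params.lapse_rate * elevation
             + params.lat_gradient * lat2d
             + rng.normal(0.0, params.noise_sd_t, elevation.shape)
             if params.noise_sd_t > 0 else
             params.t_intercept + params.lapse_rate * elevation
             + params.lat_gradient * lat2d)
    p_now = params.precip_base + params.precip_relief_coeff * elevation
    if params.noise_sd_p > 0:
        p_now = p_now + rng.normal(0.0, params.noise_sd_p, elevation.shape)
    p_now = np.maximum(p_now, 0.0)
    dt = _smooth_delta(rng, elevation.shape, params.delta_t_mean, params.delta_t_sd)
    dp = _smooth_delta(rng, elevation.shape, params.delta_p_mean, params.delta_p_sd)
    return t_now, t_now + dt, p_now, np.maximum(p_now + dp, 0.0)


def _smooth_delta(rng: np.random.Generator, shape: tuple[int, int],
                  mean: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.full(shape, mean, dtype=np.float64)
    rough = rng.normal(0.0, 1.0, shape)
    smooth = gaussian_filter(rough, sigma=min(shape) / 8.0, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.full(shape, mean, dtype=np.float64)
    return mean + (smooth - smooth.mean()) / s * sd


def generate_partnership_sizes(
    n: int, log_mean: float = 12.1, log_sd: float = 1.3, seed: int = 0
) -> np.ndarray:
    """Log-normally distributed partnership areas, km².

    Defaults are calibrated so the 5th/50th/95th percentiles fall near the
    10^4–10^6 km² span of documented trans-boundary conservation
    partnerships (median ~1.8 x 10^5 km²).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng([seed, 3])
    return rng.lognormal(log_mean, log_sd, n)


def generate_zones(params: LandscapeParams, n_zones: int = 4) -> np.ndarray:
    """Latitudinal-band zone ids (1..n_zones), a stand-in biome zonation."""
    if n_zones < 1:
        raise InvalidParameterError("n_zones must be >= 1")
    rows = np.arange(params.n_rows)
    band = np.minimum(rows * n_zones // params.n_rows, n_zones - 1) + 1
    return np.broadcast_to(band[:, None], (params.n_rows, params.n_cols)).astype(np.int64).copy()


def generate_landscape(params: LandscapeParams | None = None, **overrides) -> Landscape:
    """Generate a complete co-registered landscape bundle."""
    if params is None:
        params = LandscapeParams()
    if overrides:
        params = replace(params, **overrides)
    elev = generate_elevation(params)
    hydro = derive_hydro_network(elev, params.hydro_threshold)
    pa_ids = generate_pa_mosaic(params)
    lats = params.row_latitudes
    t_now, t_fut, p_now, p_fut = generate_climate(elev, lats, params)

    def grid(values: np.ndarray) -> Grid:
        return Grid(values, nodata=np.zeros(values.shape, bool),
                    cell_km=params.cell_km, row_latitudes=lats.copy())

    return Landscape(
        elevation=grid(elev),
        hydro=hydro,
        pa_ids=pa_ids,
        t_now=grid(t_now),
        t_future=grid(t_fut),
        p_now=grid(p_now),
        p_future=grid(p_fut),
        years_elapsed=params.years_elapsed,
    )
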