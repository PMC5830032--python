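"""Discrete circular kernels and masked moving-window (focal) statistics.

Every indicator in the pipeline is a focal statistic: a reduction over the
cells of a circular window centered on each focal cell, restricted to a
target mask (e.g. protected-area cells). Windows are truncated at grid edges
(no wraparound, no padding) — the convention for continental rasters
surrounded by ocean nodata.

The engine iterates kernel offsets in sorted ``(Δrow, Δcol)`` order and
accumulates shifted slices, so floating-point sums are built per cell in
exactly the same order as a per-cell loop over sorted offsets. Offsets whose
shifted slice misses the grid entirely are skipped, which bounds the work at
``(2·n_rows − 1) · (2·n_cols − 1)`` offsets regardless of radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import InvalidParameterError
from .grids import Grid

__all__ = ["Kernel", "build_kernel", "focal_stat", "FOCAL_STATISTICS"]

FOCAL_STATISTICS = ("count", "min", "max", "mean", "sum", "sd")


@dataclass(frozen=True)
class Kernel:
    """A discrete circular window: integer cell offsets within radius_km.

    ``offsets`` is an (n, 2) int array of (Δrow, Δcol) pairs, sorted
    lexicographically. Contains (0, 0); centrally symmetric.
    """

    radius_km: float
    cell_km: float
    offsets: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.offsets)

    @property
    def area_km2(self) -> float:
        """Window area as cell count x cell area."""
        return self.n_cells * self.cell_km * self.cell_km


def build_kernel(radius_km: float, cell_km: float = 1.0) -> Kernel:
    """All integer offsets (i, j) whose cell-center distance is <= radius_km.

    Inclusion rule: ``(i² + j²) · cell_km² <= radius_km²``. At radius 3 km on
    a 1 km grid this yields the 29-cell window; radius 0 yields only (0, 0).
    """
    if radius_km < 0:
        raise InvalidParameterError(f"radius_km must be >= 0, got {radius_km}")
    if cell_km <= 0:
        raise InvalidParameterError(f"cell_km must be > 0, got {cell_km}")
    m = int(np.floor(radius_km / cell_km))
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    keep = (ii * ii + jj * jj) * cell_km * cell_km <= radius_km * radius_km
    offsets = np.stack([ii[keep], jj[keep]], axis=1)
    order = np.lexsort((offsets[:, 1], offsets[:, 0]))
    return Kernel(radius_km=radius_km, cell_km=cell_km, offsets=offsets[order])


def _overlap(shape: tuple[int, int], di: int, dj: int):
    """Destination/source slice pair for offset (di, dj), or None if empty.

    The destination cell (i, j) reads the source cell (i + di, j + dj).
    """
    nr, nc = shape
    r0, r1 = max(0, -di), min(nr, nr - di)
    c0, c1 = max(0, -dj), min(nc, nc - dj)
    if r0 >= r1 or c0 >= c1:
        return None
    return (slice(r0, r1), slice(c0, c1)), (slice(r0 + di, r1 + di), slice(c0 + dj, c1 + dj))


def iter_window_slices(shape: tuple[int, int], kernel: Kernel) -> Iterator[tuple]:
    """Yield (dst, src) slice pairs for kernel offsets overlapping the grid."""
    for di, dj in kernel.offsets:
        ov = _overlap(shape, int(di), int(dj))
        if ov is not None:
            yield ov


def window_count(valid: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Number of valid cells in each focal window."""
    count = np.zeros(valid.shape, dtype=np.int64)
    for dst, src in iter_window_slices(valid.shape, kernel):
        count[dst] += valid[src]
    return count


def window_sum(values: np.ndarray, valid: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Sum of valid values per window, accumulated in sorted-offset order."""
    acc = np.zeros(values.shape, dtype=np.float64)
    masked = np.where(valid, values, 0.0)
    for dst, src in iter_window_slices(values.shape, kernel):
        acc[dst] += masked[src]
    return acc


def window_min(values: np.ndarray, valid: np.ndarray, kernel: Kernel) -> np.ndarray:
    out = np.full(values.shape, np.inf)
    masked = np.where(valid, values, np.inf)
    for dst, src in iter_window_slices(values.shape, kernel):
        np.fmin(out[dst], masked[src], out=out[dst])
    return out


def window_max(values: np.ndarray, valid: np.ndarray, kernel: Kernel) -> np.ndarray:
    out = np.full(values.shape, -np.inf)
    masked = np.where(valid, values, -np.inf)
    for dst, src in iter_window_slices(values.shape, kernel):
        np.fmax(out[dst], masked[src], out=out[dst])
    return out


def window_mean(values: np.ndarray, valid: np.ndarray, kernel: Kernel,
                count: np.ndarray | None = None) -> np.ndarray:
    if count is None:
        count = window_count(valid, kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        return window_sum(values, valid, kernel) / count


def window_sd(values: np.ndarray, valid: np.ndarray, kernel: Kernel,
              count: np.ndarray | None = None) -> np.ndarray:
    """Population standard deviation (divisor n), two-pass.

    The second pass accumulates squared deviations from the per-window mean
    in sorted-offset order, mirroring a per-cell two-pass loop exactly.
    """
    if count is None:
        count = window_count(valid, kernel)
    mean = window_mean(values, valid, kernel, count=count)
    ssd = np.zeros(values.shape, dtype=np.float64)
    for dst, src in iter_window_slices(values.shape, kernel):
        dev = np.where(valid[src], values[src] - mean[dst], 0.0)
        ssd[dst] += dev * dev
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(ssd / count)


def focal_stat(value_grid: Grid, target: np.ndarray, kernel: Kernel,
               statistic: str) -> Grid:
    """Apply one moving-window statistic over target cells.

    Per focal cell the statistic reduces the value-grid cells at kernel
    offsets that are in-bounds, not nodata, and target-true. Focal cells
    whose window holds zero qualifying cells are nodata in the result (the
    empty-window sentinel; zero is a meaningful indicator value and is never
    used as a sentinel).
    """
    if statistic not in FOCAL_STATISTICS:
        raise InvalidParameterError(
            f"unknown statistic {statistic!r}; expected one of {FOCAL_STATISTICS}"
        )
    target = np.asarray(target, dtype=bool)
    if target.shape != value_grid.shape:
        raise InvalidParameterError("target mask shape must match the value grid")
    valid = target & ~value_grid.nodata
    count = window_count(valid, kernel)
    empty = count == 0
    if statistic == "count":
        out = count.astype(np.float64)
    elif statistic == "sum":
        out = window_sum(value_grid.values, valid, kernel)
    elif statistic == "mean":
        out = window_mean(value_grid.values, valid, kernel, count=count)
    elif statistic == "min":
        out = window_min(value_grid.values, valid, kernel)
    elif statistic == "max":
        out = window_max(value_grid.values, valid, kernel)
    else:  # sd
        out = window_sd(value_grid.values, valid, kernel, count=count)
    out = np.where(empty, 0.0, out)
    return value_grid.like(out, nodata=empty)
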