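"""Partnership scenarios, null models, and scenario summaries.

Four modes answer "what does my protected area stand to gain by partnering?":

* ``pixel_null`` — no partnering at all: every cell acts alone (radius 0).
* ``pa_null`` — partnering only within one's own administratively distinct
  PA: each indicator is reduced once over all cells of each PA id and
  broadcast back to that PA's cells.
* ``pa_partnership`` — partnering with any PA cell within radius r.
* ``pa_nonpa_partnership`` — partnering with any land cell within radius r
  (the idealized scenario, ignoring socio-political boundaries).

Scenario pairs are compared as signed factors (a decrease by x prints −x),
and partner composition asks how much of the available partnership area
around PAs and non-PAs is itself protected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDomainError, InvalidParameterError
from .focal import Kernel, build_kernel, window_count
from .grids import Grid
from .indicators import (
    ClimatePair,
    IndicatorSet,
    compute_area,
    compute_climate_area_velocity,
    compute_elev_range,
    compute_lat_range,
    compute_relief_hydro,
)
from .landscape import Landscape

__all__ = [
    "SCENARIO_MODES",
    "ScenarioSpec",
    "ComparisonFactor",
    "run_scenario",
    "comparison_factor",
    "partner_composition",
    "partnership_percentiles",
    "area_to_radius",
    "scenario_means",
]

SCENARIO_MODES = ("pixel_null", "pa_null", "pa_partnership", "pa_nonpa_partnership")


@dataclass(frozen=True)
class ScenarioSpec:
    """One partnership scenario: a mode plus (for partnership modes) a radius."""

    mode: str
    radius_km: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in SCENARIO_MODES:
            raise InvalidParameterError(
                f"unknown mode {self.mode!r}; expected one of {SCENARIO_MODES}"
            )
        if self.mode.endswith("partnership") and self.radius_km <= 0:
            raise InvalidParameterError("partnership modes require radius_km > 0")


@dataclass(frozen=True)
class ComparisonFactor:
    """Signed factor between two scenario means (|value| >= 1)."""

    value: float
    numerator: str = ""
    denominator: str = ""


def _climate_pairs(ls: Landscape) -> tuple[ClimatePair, ClimatePair]:
    return (
        ClimatePair(ls.t_now, ls.t_future, ls.years_elapsed),
        ClimatePair(ls.p_now, ls.p_future, ls.years_elapsed),
    )


def _mask_to_focal(grid: Grid, focal: np.ndarray) -> Grid:
    out = grid.like(np.where(focal, grid.values, 0.0),
                    nodata=grid.nodata | ~focal)
    return out


def _pixel_null(ls: Landscape, floor_constant: float) -> IndicatorSet:
    land = ls.land_mask
    shape = ls.shape
    t_pair, p_pair = _climate_pairs(ls)

    def layer(values: np.ndarray) -> Grid:
        return ls.elevation.like(np.where(land, values, 0.0), nodata=~land)

    zeros = np.zeros(shape)
    return IndicatorSet(
        area=layer(np.full(shape, ls.elevation.cell_area_km2)),
        lat_range=layer(zeros),
        elev_range=layer(zeros),
        relief_hydro=layer(zeros),
        velocity_t=layer(np.abs(t_pair.rate) / floor_constant),
        velocity_p=layer(np.abs(p_pair.rate) / floor_constant),
    )


def _pa_null(ls: Landscape, floor_constant: float) -> IndicatorSet:
    if not ls.pa_mask.any():
        raise EmptyDomainError("landscape has no PA cells")
    land = ls.land_mask
    ids = np.where(land, ls.pa_ids, 0)
    t_pair, p_pair = _climate_pairs(ls)
    lat2d = ls.latitude_grid.values
    e = ls.elevation.values
    out = {name: np.zeros(ls.shape) for name in
           ("area", "lat_range", "elev_range", "relief_hydro",
            "velocity_t", "velocity_p")}
    cell_area = ls.elevation.cell_area_km2
    for pid in np.unique(ids[ids > 0]):
        sel = ids == pid
        n = int(sel.sum())
        out["area"][sel] = n * cell_area
        out["lat_range"][sel] = lat2d[sel].max() - lat2d[sel].min()
        emin = e[sel].min()
        out["elev_range"][sel] = e[sel].max() - emin
        out["relief_hydro"][sel] = float(
            (e[sel & ls.hydro] - emin).sum()) * cell_area
        for key, pair in (("velocity_t", t_pair), ("velocity_p", p_pair)):
            num = abs(float(pair.rate[sel].mean()))
            den = float(pair.now.values[sel].std()) + floor_constant
            out[key][sel] = num / den
    focal = ids > 0
    return IndicatorSet(**{
        name: ls.elevation.like(np.where(focal, arr, 0.0), nodata=~focal)
        for name, arr in out.items()
    })


def run_scenario(
    ls: Landscape,
    spec: ScenarioSpec,
    floor_constant: float = 0.1,
    focal_domain: str = "pa",
) -> IndicatorSet:
    """Compute the six indicator surfaces for one scenario.

    ``focal_domain`` restricts where partnership-mode indicators are
    reported: ``"pa"`` (default — the per-PA benefit framing) keeps PA focal
    cells only; ``"land"`` keeps every land cell (for map products). Null
    modes define their own domains (all land for pixel_null, PA cells for
    pa_null).
    """
    if focal_domain not in ("pa", "land"):
        raise InvalidParameterError("focal_domain must be 'pa' or 'land'")
    if spec.mode == "pixel_null":
        return _pixel_null(ls, floor_constant)
    if spec.mode == "pa_null":
        return _pa_null(ls, floor_constant)

    land = ls.land_mask
    if spec.mode == "pa_partnership":
        target = ls.pa_mask & land
        if not target.any():
            raise EmptyDomainError("landscape has no PA cells")
    else:
        target = land
    focal = (ls.pa_mask & land) if focal_domain == "pa" else land
    if not focal.any():
        raise EmptyDomainError("no focal cells in the requested domain")
    kernel = build_kernel(spec.radius_km, ls.cell_km)
    t_pair, p_pair = _climate_pairs(ls)
    full = IndicatorSet(
        area=compute_area(ls.elevation, target, kernel),
        lat_range=compute_lat_range(ls.latitude_grid, target, kernel),
        elev_range=compute_elev_range(ls.elevation, target, kernel),
        relief_hydro=compute_relief_hydro(ls.elevation, ls.hydro, target, kernel),
        velocity_t=compute_climate_area_velocity(t_pair, target, kernel, floor_constant),
        velocity_p=compute_climate_area_velocity(p_pair, target, kernel, floor_constant),
    )
    return IndicatorSet(**{name: _mask_to_focal(g, focal) for name, g in full.items()})


def scenario_means(indicators: IndicatorSet, domain: np.ndarray | None = None
                   ) -> dict[str, float]:
    """Mean of each indicator over valid (optionally domain-restricted) cells."""
    means = {}
    for name, grid in indicators.items():
        sel = ~grid.nodata
        if domain is not None:
            sel &= np.asarray(domain, dtype=bool)
        means[name] = float(grid.values[sel].mean()) if sel.any() else float("nan")
    return means


def comparison_factor(mean_a: float, mean_b: float,
                      numerator: str = "", denominator: str = "") -> ComparisonFactor:
    """Signed factor between two scenario means.

    A ratio >= 1 is reported as-is (an increase by x); a ratio < 1 is
    reported as −1/ratio (a decrease by x prints −x), so |value| >= 1.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise InvalidParameterError("scenario means must be positive")
    ratio = mean_a / mean_b
    value = ratio if ratio >= 1 else -1.0 / ratio
    return ComparisonFactor(value=value, numerator=numerator, denominator=denominator)


def partner_composition(ls: Landscape, kernel: Kernel
                        ) -> tuple[Grid, pd.DataFrame]:
    """Percent of available partnership area that is protected.

    Per focal cell: ``100 x (PA cells in window) / (land cells in window)``.
    Summaries are computed separately over PA and non-PA focal cells: the
    mean percentage, and the share of cells (an area share, since cells are
    equal-area) whose percentage exceeds 50.
    """
    land = ls.land_mask
    pa = ls.pa_mask & land
    n_land = window_count(land, kernel)
    n_pa = window_count(pa, kernel)
    empty = n_land == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * n_pa / n_land
    pct_grid = ls.elevation.like(np.where(empty, 0.0, pct), nodata=empty | ~land)
    rows = []
    for cls_name, sel in (("pa", pa), ("non_pa", land & ~pa)):
        ok = sel & ~pct_grid.nodata
        vals = pct_grid.values[ok]
        rows.append({
            "focal_class": cls_name,
            "mean_pct_pa_partners": float(vals.mean()) if vals.size else float("nan"),
            "pct_cells_gt50": 100.0 * float((vals > 50.0).mean()) if vals.size else float("nan"),
            "n_cells": int(vals.size),
        })
    return pct_grid, pd.DataFrame(rows)


def partnership_percentiles(areas: Sequence[float]) -> tuple[float, float, float]:
    """5th, 50th and 95th percentiles of partnership areas (km², linear interp)."""
    areas = np.asarray(list(areas), dtype=np.float64)
    if areas.size == 0:
        raise InvalidParameterError("partnership size table is empty")
    if np.any(areas <= 0):
        raise InvalidParameterError("partnership areas must be positive")
    p5, p50, p95 = np.percentile(areas, [5, 50, 95], method="linear")
    return float(p5), float(p50), float(p95)


def area_to_radius(area_km2: float, rounded: bool = False) -> float:
    """Radius (km) of the circle with the given area: sqrt(area / π)."""
    if area_km2 <= 0:
        raise InvalidParameterError("area must be positive")
    r = float(np.sqrt(area_km2 / np.pi))
    return float(round(r)) if rounded else r
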