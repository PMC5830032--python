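"""Adaptation-potential surface: normalize, combine, summarize by zones.

Indicators carry incompatible units (km², degrees, m, yr⁻¹), so each is
normalized by its maximum value across all computed cells to [0, 1].
Climate-area velocity points the "wrong" way (low is good) and is inverted
after normalization. The adaptation potential is the cell-wise mean of five
normalized indicators — area, relief-weighted hydrologic area, latitudinal
range, elevational range, and inverted velocity (the two climate variables'
velocities are first averaged into a single layer, switchable to six-layer
averaging) — then summarized as means per zone (biome / ecoregion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError
from .grids import Grid, ZoneMap
from .indicators import IndicatorSet

__all__ = [
    "AdaptationPotential",
    "normalize_indicator",
    "combine_potential",
    "zonal_mean",
    "compute_adaptation_potential",
]


@dataclass
class AdaptationPotential:
    """The combined [0, 1] surface plus its zonal summary table."""

    potential: Grid
    zonal_table: pd.DataFrame


def normalize_indicator(grid: Grid, invert: bool = False) -> Grid:
    """Scale by the maximum over valid cells; optionally return 1 − scaled."""
    valid = ~grid.nodata
    if not valid.any():
        raise DegenerateInputError("indicator grid holds no valid cells")
    vmax = float(grid.values[valid].max())
    if vmax <= 0 or not np.isfinite(vmax):
        raise DegenerateInputError(
            f"indicator maximum must be positive and finite, got {vmax}"
        )
    scaled = grid.values / vmax
    if invert:
        scaled = 1.0 - scaled
    return grid.like(np.where(valid, scaled, 0.0), nodata=~valid)


def _mean_layers(layers: list[Grid]) -> Grid:
    if not layers:
        raise InvalidParameterError("no layers to combine")
    first = layers[0]
    for g in layers[1:]:
        first.check_coregistered(g)
    nodata = np.zeros(first.shape, dtype=bool)
    acc = np.zeros(first.shape, dtype=np.float64)
    for g in layers:
        nodata |= g.nodata
        acc += np.where(g.nodata, 0.0, g.values)
    out = np.where(nodata, 0.0, acc / len(layers))
    return first.like(out, nodata=nodata)


def combine_potential(indicators: IndicatorSet,
                      merge_velocities: bool = True) -> Grid:
    """Cell-wise mean of normalized indicators; nodata propagates.

    With ``merge_velocities`` (default) the temperature and precipitation
    velocities are averaged into one layer before normalization and
    inversion, so exactly five indicators enter the mean; otherwise both are
    normalized and inverted separately and six layers are averaged.
    """
    base = [normalize_indicator(indicators[name])
            for name in ("area", "relief_hydro", "lat_range", "elev_range")]
    if merge_velocities:
        v = _mean_layers([indicators.velocity_t, indicators.velocity_p])
        layers = base + [normalize_indicator(v, invert=True)]
    else:
        layers = base + [
            normalize_indicator(indicators.velocity_t, invert=True),
            normalize_indicator(indicators.velocity_p, invert=True),
        ]
    return _mean_layers(layers)


def zonal_mean(potential: Grid, zones: ZoneMap) -> pd.DataFrame:
    """Mean potential per nonzero zone id.

    Zones with no valid cells appear as flagged rows (NaN mean, n_cells 0)
    rather than being dropped.
    """
    if zones.zone_ids.shape != potential.shape:
        raise InvalidParameterError("zone map shape must match the potential grid")
    valid = ~potential.nodata
    rows = []
    all_ids = sorted(set(np.unique(zones.zone_ids).tolist()) | set(zones.labels))
    for zid in all_ids:
        if zid == 0:
            continue
        sel = (zones.zone_ids == zid) & valid
        n = int(sel.sum())
        rows.append({
            "zone_id": int(zid),
            "label": zones.labels.get(int(zid), f"zone_{zid}"),
            "mean_potential": float(potential.values[sel].mean()) if n else float("nan"),
            "n_cells": n,
        })
    return pd.DataFrame(rows)


def compute_adaptation_potential(indicators: IndicatorSet, zones: ZoneMap,
                                 merge_velocities: bool = True) -> AdaptationPotential:
    """Normalize, combine and zonally summarize in one step."""
    potential = combine_potential(indicators, merge_velocities=merge_velocities)
    return AdaptationPotential(potential=potential,
                               zonal_table=zonal_mean(potential, zones))
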