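"""The co-registered raster bundle the analysis runs on."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CoRegistrationError
from .grids import Grid, read_grid, write_grid

__all__ = ["Landscape"]

_LAYER_FILES = {
    "elevation": "elevation.asc",
    "hydro": "hydro.asc",
    "pa_ids": "pa_ids.asc",
    "t_now": "t_now.asc",
    "t_future": "t_future.asc",
    "p_now": "p_now.asc",
    "p_future": "p_future.asc",
}


@dataclass
class Landscape:
    """Elevation, hydrography, protected areas and climate on one lattice.

    All layers share shape, cell size and row latitudes. ``pa_ids`` uses
    0 for non-protected land and 1..n for administratively distinct
    protected areas (PAs); ``hydro`` flags cells on the hydrologic network.
    ``years_elapsed`` is the interval separating the current and future
    climate grids, in years.
    """

    elevation: Grid
    hydro: np.ndarray
    pa_ids: np.ndarray
    t_now: Grid
    t_future: Grid
    p_now: Grid
    p_future: Grid
    years_elapsed: float = 95.0

    def __post_init__(self) -> None:
        self.hydro = np.asarray(self.hydro, dtype=bool)
        self.pa_ids = np.asarray(self.pa_ids, dtype=np.int64)
        for name in ("t_now", "t_future", "p_now", "p_future"):
            self.elevation.check_coregistered(getattr(self, name))
        if self.hydro.shape != self.elevation.shape:
            raise CoRegistrationError("hydro mask shape mismatch")
        if self.pa_ids.shape != self.elevation.shape:
            raise CoRegistrationError("pa id grid shape mismatch")
        if self.years_elapsed <= 0:
            raise CoRegistrationError("years_elapsed must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def cell_km(self) -> float:
        return self.elevation.cell_km

    @property
    def row_latitudes(self) -> np.ndarray:
        return self.elevation.row_latitudes

    @property
    def pa_mask(self) -> np.ndarray:
        return self.pa_ids > 0

    @property
    def land_mask(self) -> np.ndarray:
        """Cells carrying data in every layer (the analysis domain)."""
        mask = ~self.elevation.nodata
        for name in ("t_now", "t_future", "p_now", "p_future"):
            mask &= ~getattr(self, name).nodata
        return mask

    @property
    def latitude_grid(self) -> Grid:
        """Row latitudes broadcast to a full layer (degrees)."""
        lats = np.broadcast_to(
            self.row_latitudes[:, None], self.shape
        ).astype(np.float64)
        return self.elevation.like(lats.copy(), nodata=np.zeros(self.shape, bool))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        layers = {
            "elevation": self.elevation,
            "hydro": self.elevation.like(self.hydro.astype(np.float64)),
            "pa_ids": self.elevation.like(self.pa_ids.astype(np.float64)),
            "t_now": self.t_now,
            "t_future": self.t_future,
            "p_now": self.p_now,
            "p_future": self.p_future,
        }
        for name, grid in layers.items():
            write_grid(grid, directory / _LAYER_FILES[name])
        with open(directory / "landscape.txt", "w") as fh:
            fh.write(f"years_elapsed {self.years_elapsed:.17g}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Landscape":
        directory = Path(directory)
        grids = {name: read_grid(directory / fname)
                 for name, fname in _LAYER_FILES.items()}
        years = 95.0
        meta = directory / "landscape.txt"
        if meta.exists():
            for line in meta.read_text().splitlines():
                parts = line.split()
                if len(parts) == 2 and parts[0] == "years_elapsed":
                    years = float(parts[1])
        return cls(
            elevation=grids["elevation"],
            hydro=grids["hydro"].values > 0.5,
            pa_ids=grids["pa_ids"].values.astype(np.int64),
            t_now=grids["t_now"],
            t_future=grids["t_future"],
            p_now=grids["p_now"],
            p_future=grids["p_future"],
            years_elapsed=years,
        )
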