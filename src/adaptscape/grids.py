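"""Raster grid container and I/O.

Grids are abstract regular lattices: a rectangular array of cells of edge
length ``cell_km`` (km), addressed row-major, 0-based, ``(row, col)`` with
cell (0, 0) at the north-west corner. Geographic position enters only through
a per-row latitude vector in decimal degrees — the analysis never needs a
full projection, only latitudes (for the latitudinal-range indicator) and a
cell area.

Two on-disk formats are supported:

* an ESRI-ASCII-style text dialect (header keys ``ncols``, ``nrows``,
  ``cellsize``, ``NODATA_value``, plus dialect keys ``lat_top`` and
  ``lat_step`` carrying the row-latitude ramp), written with 17 significant
  digits so float64 values round-trip bit-exactly;
* TIFF via :mod:`tifffile`, with cell size, nodata value and row latitudes
  stored as a JSON document in the image description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoRegistrationError, FormatError, TilingError

__all__ = [
    "Grid",
    "ZoneMap",
    "read_grid",
    "write_grid",
    "read_zone_labels",
    "write_zone_labels",
    "aggregate_presence",
]

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single raster layer.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values, float64. Units depend on the layer (m, °C, mm,
        degrees, id, or dimensionless).
    nodata : ndarray of bool, same shape
        True where the cell holds no data.
    cell_km : float
        Cell edge length in km; cell area is ``cell_km ** 2``.
    row_latitudes : ndarray, shape (n_rows,)
        Latitude of each row's cell centers, decimal degrees.
    """

    values: np.ndarray
    nodata: np.ndarray = None
    cell_km: float = 1.0
    row_latitudes: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise CoRegistrationError("grid values must be 2-D")
        if self.cell_km <= 0:
            raise CoRegistrationError("cell_km must be positive")
        if self.nodata is None:
            self.nodata = ~np.isfinite(self.values)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise CoRegistrationError(
                    f"nodata mask shape {self.nodata.shape} != values shape {self.values.shape}"
                )
        if self.row_latitudes is None:
            self.row_latitudes = np.zeros(self.values.shape[0], dtype=np.float64)
        else:
            self.row_latitudes = np.asarray(self.row_latitudes, dtype=np.float64)
            if self.row_latitudes.shape != (self.values.shape[0],):
                raise CoRegistrationError(
                    "row_latitudes length must equal the number of rows"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km * self.cell_km

    def like(self, values: np.ndarray, nodata: np.ndarray | None = None) -> "Grid":
        """A new grid sharing this grid's georeferencing."""
        return Grid(values, nodata=nodata, cell_km=self.cell_km,
                    row_latitudes=self.row_latitudes.copy())

    def check_coregistered(self, other: "Grid") -> None:
        if self.shape != other.shape:
            raise CoRegistrationError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.isclose(self.cell_km, other.cell_km):
            raise CoRegistrationError(
                f"cell size mismatch: {self.cell_km} vs {other.cell_km}"
            )


@dataclass
class ZoneMap:
    """Integer zone identifiers (0 = no zone) plus id → name labels."""

    zone_ids: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids, dtype=np.int64)
        if self.zone_ids.ndim != 2:
            raise CoRegistrationError("zone id grid must be 2-D")
        present = set(np.unique(self.zone_ids).tolist()) - {0}
        missing = present - set(self.labels)
        for zid in sorted(missing):
            self.labels[zid] = f"zone_{zid}"


def _parse_header_value(key: str, token: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"header field {key!r}: cannot parse {token!r}") from exc


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if not rows and not _is_number(parts[0]):
                if len(parts) != 2:
                    raise FormatError(f"header line {line.strip()!r}: expected key value")
                header[parts[0].lower()] = _parse_header_value(parts[0], parts[1])
            else:
                rows.append(np.array(parts, dtype=np.float64))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"header field {req!r}: missing")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if len(rows) != nrows or any(r.size != ncols for r in rows):
        raise FormatError(
            f"data block: expected {nrows}x{ncols}, "
            f"got {len(rows)} rows of widths {sorted({r.size for r in rows})}"
        )
    values = np.vstack(rows)
    nodata_value = header.get("nodata_value", _DEFAULT_NODATA)
    nodata = values == nodata_value
    lat_top = header.get("lat_top", 0.0)
    lat_step = header.get("lat_step", 0.0)
    lats = lat_top + lat_step * np.arange(nrows, dtype=np.float64)
    return Grid(values, nodata=nodata, cell_km=header["cellsize"], row_latitudes=lats)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _write_ascii(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    lats = grid.row_latitudes
    lat_top = float(lats[0])
    lat_step = float(lats[1] - lats[0]) if nrows > 1 else 0.0
    vals = np.where(grid.nodata, _DEFAULT_NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"cellsize {grid.cell_km:.17g}\n")
        fh.write(f"NODATA_value {_DEFAULT_NODATA:.17g}\n")
        fh.write(f"lat_top {lat_top:.17g}\n")
        fh.write(f"lat_step {lat_step:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _write_tiff(grid: Grid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_km": grid.cell_km,
        "nodata_value": _DEFAULT_NODATA,
        "row_latitudes": grid.row_latitudes.tolist(),
    }
    vals = np.where(grid.nodata, _DEFAULT_NODATA, grid.values)
    tifffile.imwrite(path, vals, description=json.dumps(meta))


def _read_tiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        try:
            meta = json.loads(desc.value) if desc is not None else {}
        except json.JSONDecodeError as exc:
            raise FormatError("ImageDescription: not valid JSON metadata") from exc
    nodata_value = meta.get("nodata_value", _DEFAULT_NODATA)
    lats = meta.get("row_latitudes")
    lats = np.asarray(lats, dtype=np.float64) if lats is not None else None
    return Grid(values, nodata=values == nodata_value,
                cell_km=meta.get("cell_km", 1.0), row_latitudes=lats)


def read_grid(path: str | Path) -> Grid:
    """Read a raster layer; format chosen by suffix (.asc/.txt text, .tif TIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_tiff(path)
    return _read_ascii(path)


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write a raster layer; format chosen by suffix (.asc/.txt text, .tif TIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_tiff(grid, path)
    else:
        _write_ascii(grid, path)


def read_zone_labels(path: str | Path) -> dict[int, str]:
    """Read a two-column (id, name) delimited label table."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "name"} <= set(df.columns):
        raise FormatError("zone label table: expected columns 'id' and 'name'")
    return dict(zip(df["id"].astype(int), df["name"].astype(str)))


def write_zone_labels(labels: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"id": sorted(labels), "name": [labels[k] for k in sorted(labels)]}
    ).to_csv(path, sep="\t", index=False)


def aggregate_presence(fine: np.ndarray, factor: int) -> np.ndarray:
    """Coarsen a boolean presence grid by an any-presence rule.

    A coarse cell (covering ``factor x factor`` fine cells) is present iff at
    least one of its fine cells is present. This is the aggregation rule that
    retains small protected areas when coarsening a fine rasterization (e.g.
    one presence cell of 16 at 250 m suffices for presence at 1 km).
    """
    fine = np.asarray(fine, dtype=bool)
    if factor < 1:
        raise TilingError("aggregation factor must be >= 1")
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise TilingError(
            f"fine grid {nr}x{nc} not divisible by factor {factor}"
        )
    blocks = fine.reshape(nr // factor, factor, nc // factor, factor)
    return blocks.any(axis=(1, 3))
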