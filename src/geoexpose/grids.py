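"""Reference-grid raster container and plain-text raster I/O.

Everything downstream of the spatialization steps lives on a single planar
reference grid of square cells (3 x 3 km by default, i.e. 9 km^2 cells).
Coordinates are kilometres on a synthetic planar system; cells are
georeferenced by their centres.  Rasters are persisted as ESRI ASCII grids,
a plain-text format readable by standard GIS software.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclasses.dataclass
class RasterField:
    """Values on the reference grid with missing/invalid masks.

    ``values`` is indexed ``[row, col]`` with row 0 at the *south* edge, so
    ``values[j, i]`` sits at centre ``((i + 0.5) * cell, (j + 0.5) * cell)``
    relative to ``origin``.

    ``mask_missing`` flags cells with no data (e.g. municipalities without
    water measurements); ``mask_invalid`` flags cells where an estimate
    exists but is outside the validity domain of the model that produced it
    (e.g. high-altitude, unpopulated areas for the air model).  Valid cells
    must hold finite values.
    """

    values: np.ndarray
    cell_size_km: float = 3.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask_missing: np.ndarray | None = None
    mask_invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.mask_missing is None:
            self.mask_missing = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask_missing = np.asarray(self.mask_missing, dtype=bool)
        if self.mask_invalid is None:
            self.mask_invalid = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask_invalid = np.asarray(self.mask_invalid, dtype=bool)
        for m in (self.mask_missing, self.mask_invalid):
            if m.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
        ok = ~(self.mask_missing | self.mask_invalid)
        if not np.all(np.isfinite(self.values[ok])):
            raise ValueError("non-finite values outside the masked area")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinates of every cell centre, flattened C-order."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_size_km
        ys = y0 + (np.arange(self.ny) + 0.5) * self.cell_size_km
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup of raster values at point coordinates (km)."""
        i, j = self.cell_index(x, y)
        return self.values[j, i]

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        i = np.clip(((x - self.origin[0]) / self.cell_size_km).astype(int), 0, self.nx - 1)
        j = np.clip(((y - self.origin[1]) / self.cell_size_km).astype(int), 0, self.ny - 1)
        return i, j

    def copy_with(self, values: np.ndarray, **masks) -> "RasterField":
        return RasterField(
            values=np.asarray(values, dtype=float),
            cell_size_km=self.cell_size_km,
            origin=self.origin,
            mask_missing=masks.get("mask_missing", self.mask_missing.copy()),
            mask_invalid=masks.get("mask_invalid", self.mask_invalid.copy()),
        )


def write_ascii_grid(path: str | Path, raster: RasterField) -> None:
    """Write the value band as an ESRI ASCII grid (missing cells -> NODATA)."""
    vals = raster.values.copy()
    vals[raster.mask_missing] = NODATA
    vals = np.where(np.isfinite(vals), vals, NODATA)
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.origin[0] * 1000.0}\n"
        f"yllcorner {raster.origin[1] * 1000.0}\n"
        f"cellsize {raster.cell_size_km * 1000.0}\n"
        f"NODATA_value {NODATA}\n"
    )
    # ESRI convention: first row of the file is the northernmost row
    body = "\n".join(" ".join(f"{v:.8g}" for v in row) for row in vals[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> RasterField:
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    vals = np.loadtxt(lines[i:], dtype=float)
    vals = np.atleast_2d(vals)[::-1]  # back to south-up indexing
    nodata = hdr.get("nodata_value", NODATA)
    missing = vals == nodata
    vals = np.where(missing, np.nan, vals)
    vals[missing] = 0.0
    return RasterField(
        values=vals,
        cell_size_km=hdr["cellsize"] / 1000.0,
        origin=(hdr["xllcorner"] / 1000.0, hdr["yllcorner"] / 1000.0),
        mask_missing=missing,
    )


def save_raster_bundle(directory: str | Path, name: str, raster: RasterField) -> list[Path]:
    """Persist value band plus (only if non-trivial) the invalid mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / f"{name}.asc"]
    write_ascii_grid(paths[0], raster)
    if raster.mask_invalid.any():
        inv = RasterField(
            raster.mask_invalid.astype(float),
            cell_size_km=raster.cell_size_km,
            origin=raster.origin,
        )
        p = directory / f"{name}_invalid.asc"
        write_ascii_grid(p, inv)
        paths.append(p)
    return paths


def load_raster_bundle(directory: str | Path, name: str) -> RasterField:
    directory = Path(directory)
    r = read_ascii_grid(directory / f"{name}.asc")
    inv_path = directory / f"{name}_invalid.asc"
    if inv_path.exists():
        r.mask_invalid = read_ascii_grid(inv_path).values.astype(bool)
    return r
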