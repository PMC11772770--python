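"""Raster containers and TIFF I/O.

A :class:`Raster` is a single-band, north-up, row-major grid with a square
cell size in metres, an optional nodata code, and an (x, y) origin at the
upper-left corner. Rasters are the single spatial interchange format of the
package; categorical grids are integer typed, fraction/probability grids are
float typed.

Files are written as single-band TIFF with the grid metadata (cell size,
nodata, origin) serialized as JSON into the ImageDescription tag, so a
write/read round trip is lossless for integer grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


class GridError(ValueError):
    """Invalid grid input (empty raster, bad cell size, ...)."""


class GeometryError(ValueError):
    """Co-registration failure between rasters that must align."""


@dataclass
class Raster:
    values: np.ndarray
    cell_size: float
    nodata: int | float | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridError("raster must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (and not NaN for floats)."""
        mask = np.ones(self.values.shape, dtype=bool)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        return mask

    def with_values(self, values: np.ndarray, **kwargs) -> "Raster":
        """New raster sharing this one's geometry unless overridden."""
        out = replace(self, values=values)
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out


def check_aligned(*rasters: Raster) -> None:
    """Raise GeometryError unless all rasters share shape, cell size and origin."""
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape:
            raise GeometryError(f"shape mismatch: {r.shape} vs {ref.shape}")
        if not np.isclose(r.cell_size, ref.cell_size):
            raise GeometryError(
                f"cell size mismatch: {r.cell_size} vs {ref.cell_size}"
            )
        if not np.allclose(r.origin, ref.origin):
            raise GeometryError(f"origin mismatch: {r.origin} vs {ref.origin}")


def write_raster(raster: Raster, path) -> None:
    meta = {
        "cell_size": float(raster.cell_size),
        "nodata": None if raster.nodata is None else float(raster.nodata),
        "origin": [float(raster.origin[0]), float(raster.origin[1])],
    }
    tifffile.imwrite(path, raster.values, description=json.dumps(meta))


def read_raster(path) -> Raster:
    try:
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description or "{}"
    except (OSError, tifffile.TiffFileError) as exc:
        raise GridError(f"cannot read raster {path}: {exc}") from exc
    meta = json.loads(desc) if desc.strip().startswith("{") else {}
    nodata = meta.get("nodata")
    if nodata is not None and np.issubdtype(values.dtype, np.integer):
        nodata = int(nodata)
    return Raster(
        values=values,
        cell_size=float(meta.get("cell_size", 1.0)),
        nodata=nodata,
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )
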