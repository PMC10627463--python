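"""Minimal georeferenced raster container.

A raster is a 2-D numpy grid plus a square-cell georeference: the world
coordinate of the top-left corner and the cell size in metres. Row 0 is the
northernmost row, so y decreases with increasing row index. Files are plain
TIFFs with the georeference embedded as a JSON description tag, readable by
any TIFF tool; cell values are float32 (suitability, resistance) or uint8
(masks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Raster", "read_raster", "write_raster"]


@dataclass
class Raster:
    """A grid of values with a square-cell georeference.

    Parameters
    ----------
    data:
        2-D array (rows, cols); rows run north to south.
    cell_size:
        Cell edge length in metres (> 0).
    origin:
        (x, y) world coordinate of the top-left corner of cell (0, 0).
    nodata:
        Value marking missing cells, or None.
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_center(self, row, col):
        """World (x, y) of cell centres; accepts scalars or arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_at(self, x, y):
        """(row, col) of the cell containing world point(s) (x, y)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if np.isnan(self.nodata):
            return ~np.isnan(self.data)
        return self.data != self.nodata


def write_raster(raster: Raster, path) -> None:
    meta = {
        "cell_size": raster.cell_size,
        "origin": list(raster.origin),
        "nodata": raster.nodata,
    }
    tifffile.imwrite(path, raster.data, description=json.dumps(meta))


def read_raster(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return Raster(
        data=data,
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=meta.get("nodata"),
    )
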