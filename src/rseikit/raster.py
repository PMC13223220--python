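"""Raster grid model and GeoTIFF-style I/O.

Layers are plain 2-D :class:`numpy.ndarray` objects on a shared planar
grid.  Float layers use NaN as nodata; integer (categorical) layers use
an explicit sentinel recorded in the sidecar metadata.  Files are
written as TIFF with a JSON sidecar carrying grid metadata, which
round-trips bit-exactly for integer types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

INT_NODATA = -9999


class CongruenceError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """A planar raster grid: ``shape`` in pixels, ``pixel_size`` in metres.

    Pixel centre coordinates are ``x = (col + 0.5) * pixel_size`` and
    ``y = (row + 0.5) * pixel_size`` with the origin at the top-left
    corner of pixel (0, 0).
    """

    shape: tuple[int, int]
    pixel_size: float = 500.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError(f"invalid grid shape {self.shape!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate layers for pixel centres, in metres."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        x = (cols + 0.5) * self.pixel_size
        y = (rows + 0.5) * self.pixel_size
        return x, y


def check_congruent(*layers: np.ndarray) -> tuple[int, int]:
    """Assert all layers share one shape; return it."""
    shapes = {np.asarray(l).shape for l in layers}
    if len(shapes) != 1:
        raise CongruenceError(f"layers are not congruent: shapes {sorted(shapes)}")
    return shapes.pop()


def valid_mask(*layers: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels finite in every input layer."""
    check_congruent(*layers)
    mask = np.ones(np.asarray(layers[0]).shape, dtype=bool)
    for layer in layers:
        arr = np.asarray(layer)
        if np.issubdtype(arr.dtype, np.floating):
            mask &= np.isfinite(arr)
        else:
            mask &= arr != INT_NODATA
    return mask


def write_raster(path: str | Path, layer: np.ndarray, grid: Grid, **meta) -> Path:
    """Write a layer as TIFF plus a JSON sidecar with grid metadata."""
    path = Path(path)
    arr = np.asarray(layer)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
        nodata: float | int = float("nan")
    else:
        arr = arr.astype(np.int32)
        nodata = INT_NODATA
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr)
    sidecar = {
        "grid": asdict(grid),
        "dtype": str(arr.dtype),
        "nodata": None if isinstance(nodata, float) and np.isnan(nodata) else nodata,
        **meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path, scale: float = 1.0, offset: float = 0.0):
    """Read a TIFF layer and its sidecar; returns ``(layer, grid)``.

    ``scale`` and ``offset`` implement product profiles (e.g. DN-to-unit
    conversion): the returned layer is ``raw * scale + offset``, applied
    only when either differs from the identity.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = Grid(tuple(sidecar["grid"]["shape"]), sidecar["grid"]["pixel_size"])
    if arr.shape != grid.shape:
        raise CongruenceError(f"{path}: data shape {arr.shape} != sidecar {grid.shape}")
    if scale != 1.0 or offset != 0.0:
        out = arr.astype(np.float64) * scale + offset
        if not np.issubdtype(arr.dtype, np.floating):
            out[arr == INT_NODATA] = np.nan
        arr = out
    return arr, grid
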