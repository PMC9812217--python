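"""Grayscale image reading and writing for the screening pipeline.

One coordinate convention is used everywhere: 0-based, ``x`` is the column
index, ``y`` is the row index, and the origin is the centre of the top-left
pixel.  Intensities are kept exactly as stored in the file; detectors
normalise internally.

Supported containers: MRC2014 (2D real modes only, via gemmi), TIFF
(tifffile) and grayscale PNG (imageio).  PNG stores unsigned integers only,
so float data must be quantised by the caller before writing.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import gemmi
import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ImageParseError, UnsupportedFormatError

__all__ = ["ImageGrid", "read_image", "write_image"]

_FORMATS = {"mrc": (".mrc",), "tiff": (".tif", ".tiff"), "png": (".png",)}


@dataclass
class ImageGrid:
    """A 2D grayscale image plus pixel-size metadata.

    Parameters
    ----------
    pixels
        2D array of intensities in arbitrary linear units.
    pixel_size
        Physical length per pixel (Å at micrograph magnifications, metadata
        only — no operation rescales by it).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels.astype(np.float64, copy=False))):
            raise ValueError("pixels must be finite")
        if not (math.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError("pixel_size must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns)."""
        return self.pixels.shape

    @property
    def center(self) -> tuple[float, float]:
        """Image centre (x, y) in pixel-centre coordinates."""
        h, w = self.pixels.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)


def _resolve_format(path: str, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt == "tif":
            fmt = "tiff"
        if fmt not in _FORMATS:
            raise UnsupportedFormatError(f"unknown format {format!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    for fmt, exts in _FORMATS.items():
        if ext in exts:
            return fmt
    raise UnsupportedFormatError(
        f"unsupported image extension {ext!r} (expected .mrc, .tif/.tiff or .png)"
    )


def read_image(path: str, format: str | None = None) -> ImageGrid:
    """Read a 2D grayscale image from ``path``.

    ``format`` forces a reader ("mrc", "tiff" or "png") regardless of the
    extension.  MRC pixel size is taken from the header cell when present,
    otherwise 1.0.  Image stacks (nz > 1) are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "mrc":
        return _read_mrc(path)
    try:
        if fmt == "tiff":
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise ImageParseError(f"could not parse {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ImageParseError(f"{path} is not a single 2D grayscale image")
    return ImageGrid(pixels=arr)


def write_image(grid: ImageGrid, path: str, format: str | None = None) -> None:
    """Write ``grid`` to ``path``; the container is chosen by extension.

    MRC is written as mode-2 float32 with the pixel size in the header
    cell.  PNG requires integer-valued data in [0, 65535] (written as
    uint16/uint8); TIFF preserves the array dtype.
    """
    fmt = _resolve_format(path, format)
    if fmt == "mrc":
        _write_mrc(grid, path)
    elif fmt == "tiff":
        tifffile.imwrite(path, grid.pixels)
    else:
        arr = grid.pixels
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.array_equal(arr, np.round(arr)) or arr.min() < 0 or arr.max() > 65535:
                raise UnsupportedFormatError(
                    "PNG stores unsigned integers; quantise float data before writing"
                )
            arr = arr.astype(np.uint16)
        iio.imwrite(path, arr)


def _read_mrc(path: str) -> ImageGrid:
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except Exception as exc:  # noqa: BLE001
        raise ImageParseError(f"could not parse MRC header of {path}: {exc}") from exc
    arr = np.asarray(ccp4.grid.array)  # indexed [u, v, w] = [col, row, section]
    if arr.ndim != 3:
        raise ImageParseError(f"{path}: unexpected MRC grid rank {arr.ndim}")
    if arr.shape[2] != 1:
        raise ImageParseError(
            f"{path} is an image stack/volume (nz={arr.shape[2]}); only 2D images are supported"
        )
    nx = ccp4.grid.nu
    cell_a = ccp4.grid.unit_cell.a
    pixel_size = cell_a / nx if cell_a > 0 and nx > 0 else 1.0
    return ImageGrid(pixels=arr[:, :, 0].T.copy(), pixel_size=pixel_size)


def _write_mrc(grid: ImageGrid, path: str) -> None:
    h, w = grid.pixels.shape
    g = gemmi.FloatGrid(w, h, 1)
    g.array[:] = grid.pixels.astype(np.float32).T[:, :, None]
    g.unit_cell = gemmi.UnitCell(
        w * grid.pixel_size, h * grid.pixel_size, grid.pixel_size, 90, 90, 90
    )
    g.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(path)
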