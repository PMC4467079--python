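"""Raster input/output in plain-text formats.

Two single-band formats are supported: ESRI ASCII grid (``.asc``, carries
the pixel size in its ``cellsize`` header) and headerless CSV matrices
(``.csv``, pixel size supplied by the caller).  Round trips preserve
values to float precision and the pixel size exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .field_generator import RasterGrid

__all__ = ["read_raster", "write_raster"]

FORMATS = ("asc", "csv")
NODATA = -9999.0


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown raster format {fmt!r}; supported: {FORMATS}")
    return fmt


def write_raster(
    grid: RasterGrid, path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write a grid to ``path`` as ESRI ASCII or headerless CSV."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "asc":
        n_rows, n_cols = grid.shape
        header = (
            f"ncols {n_cols}\n"
            f"nrows {n_rows}\n"
            "xllcorner 0.0\n"
            "yllcorner 0.0\n"
            f"cellsize {grid.pixel_size!r}\n"
            f"NODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, grid.values, fmt="%.10g")
    else:
        np.savetxt(path, grid.values, fmt="%.10g", delimiter=",")


def read_raster(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    pixel_size: Optional[float] = None,
    units: str = "",
) -> RasterGrid:
    """Read a grid from ESRI ASCII or headerless CSV.

    For ``.asc`` the pixel size comes from the ``cellsize`` header (an
    explicit ``pixel_size`` argument overrides it); for ``.csv`` it must be
    supplied (default 1.0).  Ragged CSV rows raise an error.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        for key in ("ncols", "nrows", "cellsize"):
            if key not in header:
                raise ValueError(f"ESRI ASCII grid {path} is missing header {key!r}")
        values = np.loadtxt(lines[n_header:], ndmin=2)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(
                f"ESRI ASCII grid {path}: data shape {values.shape} does not "
                f"match header ({int(header['nrows'])}, {int(header['ncols'])})"
            )
        cell = pixel_size if pixel_size is not None else header["cellsize"]
        return RasterGrid(values=values, pixel_size=cell, units=units)

    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            rows.append([float(tok) for tok in line.strip().split(",")])
    if not rows:
        raise ValueError(f"CSV raster {path} is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"CSV raster {path} has ragged rows (widths {sorted(widths)})")
    return RasterGrid(
        values=np.asarray(rows, dtype=float),
        pixel_size=pixel_size if pixel_size is not None else 1.0,
        units=units,
    )
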