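"""ESRI ASCII grid reading and writing.

Concentration and risk fields are exported in the plain-text ASCII grid
format (six header lines, then rows of values starting at the NORTH
edge) so that any GIS can render them.  Internally arrays are stored
south-row-first, matching the grid's (0, 0)-at-south-west convention,
so writers flip the row order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meteo import GridSpec

__all__ = ["write_ascii_grid", "read_ascii_grid"]

NODATA = -9999.0


def write_ascii_grid(field: np.ndarray, grid_spec: GridSpec, path) -> None:
    """Write a field congruent with ``grid_spec`` as an ESRI ASCII grid."""
    field = np.asarray(field, dtype=float)
    if field.shape != grid_spec.shape:
        raise ValueError(
            f"field shape {field.shape} does not match grid {grid_spec.shape}"
        )
    if grid_spec.dx != grid_spec.dy:
        raise ValueError("ASCII grids require square cells (dx == dy)")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid_spec.nx}\n")
        fh.write(f"nrows {grid_spec.ny}\n")
        fh.write(f"xllcorner {grid_spec.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid_spec.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid_spec.dx:.6f}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in field[::-1]:            # north row first
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns the field south-row-first plus the parsed header dict.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        body = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = np.atleast_2d(body)
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    return body[::-1].copy(), header
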