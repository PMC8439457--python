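"""Minimal single-band raster container with ESRI ASCII grid I/O.

Grids are stored as 2-D arrays with row 0 at the *top* of the map (the
order rows appear in an ``.asc`` file); the georeferenced origin is the
lower-left corner. Grid indices are ``(row, col)``, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular single-band grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    cell_size_m
        Edge length of the square cells in metres.
    origin
        ``(x, y)`` of the lower-left corner of the grid.
    nodata
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size_m: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=DEFAULT_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def mask_valid(self) -> np.ndarray:
        """Boolean grid of cells that are not nodata and not NaN."""
        return ~np.isnan(self.values) & (self.values != self.nodata)

    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def cell_of_point(self, x: float, y: float) -> tuple[int, int] | None:
        """Return the ``(row, col)`` containing ``(x, y)``.

        Cells are half-open intervals ``[edge, edge + cell)`` in both axes;
        points outside the grid return ``None``.
        """
        x0, y0 = self.origin
        col = math.floor((x - x0) / self.cell_size_m)
        row_from_bottom = math.floor((y - y0) / self.cell_size_m)
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size_m, other.cell_size_m)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(
            values=np.asarray(values, dtype=float),
            cell_size_m=self.cell_size_m,
            origin=self.origin,
            nodata=self.nodata,
        )


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (``ncols/nrows/xllcorner/yllcorner/cellsize``)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"missing ASCII grid header field: {required}")
    values = np.array(rows, dtype=float)
    flat = values.reshape(-1)
    expected = int(header["nrows"]) * int(header["ncols"])
    if flat.size != expected:
        raise ValueError(f"grid has {flat.size} cells, header promises {expected}")
    values = flat.reshape(int(header["nrows"]), int(header["ncols"]))
    return Raster(
        values=values,
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def write_ascii_grid(raster: Raster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size_m:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
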