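"""Minimal single-band raster on a regular planar grid, with ESRI
ASCII-grid text I/O (ncols/nrows/xllcorner/yllcorner/cellsize header).

Coordinates are planar metres in a local frame; row 0 of ``values`` is the
northernmost row, following the ASCII-grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Raster:
    values: np.ndarray  # (nrows, ncols); row 0 = top (max y)
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 30.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of x and y coordinates of cell centres."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        y = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll}\n"
            f"yllcorner {self.yll}\n"
            f"cellsize {self.cellsize}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            xll=meta.get("xllcorner", 0.0),
            yll=meta.get("yllcorner", 0.0),
            cellsize=meta.get("cellsize", 30.0),
        )
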