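"""Inverse-distance-weighted interpolation onto a regular raster grid.

Each cell value is the convex combination Σ w_i v_i / Σ w_i with
w_i = d_i^(−power) over the chosen neighbor set; a cell closer than
ε = 1e−9 × cellsize to a data point takes that point's value exactly.
Grids serialize to the ESRI ASCII ``.asc`` format, which GIS tools ingest
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, IntegrityError

__all__ = ["RasterGrid", "idw_interpolate", "write_ascii_grid", "read_ascii_grid"]

COINCIDENCE_EPS_FACTOR = 1e-9


@dataclass
class RasterGrid:
    """A regular grid: origin at the lower-left corner, square cells.

    ``values`` is (n_rows, n_cols) with row 0 the *top* row, matching the
    ESRI ASCII layout.
    """

    x0: float
    y0: float
    cellsize: float
    n_cols: int
    n_rows: int
    values: np.ndarray | None = None
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if not self.cellsize > 0:
            raise DomainError("cellsize must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise DomainError("grid must have at least one cell")
        if self.values is None:
            self.values = np.full((self.n_rows, self.n_cols), self.nodata)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (self.n_rows, self.n_cols):
                raise DomainError(
                    f"values shape {self.values.shape} does not match "
                    f"({self.n_rows}, {self.n_cols})"
                )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, shaped like ``values``."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cellsize
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cellsize
        X, Y = np.meshgrid(xs, ys[::-1])  # row 0 on top
        return X, Y

    @classmethod
    def from_bbox(cls, bbox, cellsize, nodata=-9999.0) -> "RasterGrid":
        x0, y0, x1, y1 = bbox
        n_cols = max(1, int(np.ceil((x1 - x0) / cellsize)))
        n_rows = max(1, int(np.ceil((y1 - y0) / cellsize)))
        return cls(x0, y0, cellsize, n_cols, n_rows, nodata=nodata)


def idw_interpolate(points, grid: RasterGrid, power: float = 2.0,
                    neighbors: int | None = None) -> RasterGrid:
    """Interpolate scattered (x, y, value) points onto ``grid``.

    ``neighbors`` limits the weighting to the k nearest points (default: all
    points).  Duplicate coordinates with conflicting values are rejected;
    exact duplicates collapse to one point.
    """
    pts = [(float(x), float(y), float(v)) for x, y, v in points]
    if not pts:
        raise DomainError("at least one data point is required")
    if not power > 0:
        raise DomainError("power must be positive")
    dedup: dict[tuple[float, float], float] = {}
    for x, y, v in pts:
        if (x, y) in dedup and dedup[(x, y)] != v:
            raise IntegrityError(
                f"conflicting values at duplicate coordinates ({x}, {y})"
            )
        dedup[(x, y)] = v
    px = np.array([k[0] for k in dedup])
    py = np.array([k[1] for k in dedup])
    pv = np.array(list(dedup.values()))

    X, Y = grid.cell_centers()
    qx, qy = X.ravel(), Y.ravel()
    # (n_query, n_points) distance matrix; study grids are small
    d = np.hypot(qx[:, None] - px[None, :], qy[:, None] - py[None, :])
    eps = COINCIDENCE_EPS_FACTOR * grid.cellsize

    k = len(pv) if neighbors is None else min(int(neighbors), len(pv))
    if k < 1:
        raise DomainError("neighbors must be >= 1")
    if k < len(pv):
        idx = np.argpartition(d, k - 1, axis=1)[:, :k]
        rows = np.arange(d.shape[0])[:, None]
        d_k, v_k = d[rows, idx], pv[idx]
    else:
        d_k, v_k = d, np.broadcast_to(pv, d.shape)

    with np.errstate(divide="ignore", over="ignore"):
        w = d_k ** (-power)
    out = np.empty(d.shape[0])
    coincident = d_k.min(axis=1) < eps
    if np.any(coincident):
        nearest = np.argmin(d_k[coincident], axis=1)
        out[coincident] = v_k[coincident, nearest]
    free = ~coincident
    if np.any(free):
        wf = w[free]
        # guard against inf weights just outside the eps ball
        wf = np.where(np.isfinite(wf), wf, np.finfo(float).max / len(pv))
        out[free] = (wf * v_k[free]).sum(axis=1) / wf.sum(axis=1)

    result = RasterGrid(grid.x0, grid.y0, grid.cellsize, grid.n_cols,
                        grid.n_rows, out.reshape(X.shape), grid.nodata)
    return result


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc): 6 header lines, row-major values."""
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.x0!r}",
        f"yllcorner {grid.y0!r}",
        f"cellsize {grid.cellsize!r}",
        f"NODATA_value {grid.nodata!r}",
    ]
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    for row in vals:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header = {}
    for line in text[:6]:
        key, val = line.split(None, 1)
        header[key.lower()] = float(val)
    values = np.array([[float(tok) for tok in line.split()] for line in text[6:]])
    return RasterGrid(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cellsize=header["cellsize"], n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]), values=values,
        nodata=header.get("nodata_value", -9999.0),
    )
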