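"""Land-cover class proportions and edge density in circular buffers.

The land-cover map is a categorical raster at 10 m resolution.  Around
each nest, metrics are computed within circular buffers of increasing
radius: the percentage of each cover class among buffer cells and the
total length of edges (shared boundaries between 4-adjacent cells of
differing class), a habitat-fragmentation proxy.

Membership rule: a cell belongs to a buffer iff its *center* lies within
the Euclidean radius of the nest point.  Edge pairs count only when both
cell centers are inside the buffer.  These rules are deterministic and
standard for categorical rasters; area-weighted polygon clipping is not
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .field_data import NestRecord

#: Buffer radii (meters) used in the study design.
DEFAULT_RADII = (10, 20, 30, 40, 70, 100, 200, 500)

#: Default legend: the four analysis classes plus a catch-all.
DEFAULT_LEGEND = {
    1: "arable",
    2: "vegetated_open",
    3: "deciduous_forest",
    4: "artificial",
    5: "other",
}


@dataclass
class LandCoverGrid:
    """Categorical raster with planar coordinates.

    ``codes[0, 0]`` is the **north-west** cell (ESRI ASCII row order);
    ``origin`` is the (x, y) of the lower-left corner.
    """

    codes: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D array")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        present = set(np.unique(self.codes))
        unknown = present - set(self.legend)
        if unknown:
            raise ValidationError(f"codes {sorted(unknown)} missing from legend")

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, shaped like ``codes``."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        cx = x0 + (cols + 0.5) * self.cell_size
        cy = y0 + (self.nrows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(cx, cy)


def read_ascii_grid(
    path: str | Path,
    legend: Mapping[int, str] | None = None,
) -> LandCoverGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        codes = np.loadtxt(fh, dtype=int, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValidationError(f"ASCII grid header missing {key!r}")
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"grid body shape {codes.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandCoverGrid(
        codes,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        legend=dict(legend) if legend is not None
        else {int(c): DEFAULT_LEGEND.get(int(c), f"class_{int(c)}") for c in np.unique(codes)},
    )


def write_ascii_grid(grid: LandCoverGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:g}\n")
        fh.write(f"yllcorner {grid.origin[1]:g}\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        np.savetxt(fh, grid.codes, fmt="%d")


def _buffer_mask(grid: LandCoverGrid, point: tuple[float, float], radius: float):
    cx, cy = grid.cell_centers()
    dist2 = (cx - point[0]) ** 2 + (cy - point[1]) ** 2
    mask = dist2 <= radius ** 2
    # expected cell count on an unbounded grid with the same alignment,
    # for reporting partial coverage near the raster boundary
    cs = grid.cell_size
    x0, y0 = grid.origin
    jmin = int(np.floor((point[0] - radius - x0) / cs)) - 1
    jmax = int(np.ceil((point[0] + radius - x0) / cs)) + 1
    imin = int(np.floor((point[1] - radius - y0) / cs)) - 1
    imax = int(np.ceil((point[1] + radius - y0) / cs)) + 1
    xs = x0 + (np.arange(jmin, jmax + 1) + 0.5) * cs
    ys = y0 + (np.arange(imin, imax + 1) + 0.5) * cs
    gx, gy = np.meshgrid(xs, ys)
    n_expected = int(((gx - point[0]) ** 2 + (gy - point[1]) ** 2 <= radius ** 2).sum())
    return mask, n_expected


def class_proportions(
    grid: LandCoverGrid,
    point: tuple[float, float],
    radius: float,
) -> dict[str, float]:
    """Percentage of each legend class among cells in the buffer.

    Percentages are reported over covered cells; when the buffer extends
    past the raster a warning is issued and the result carries the
    covered fraction under the key ``"coverage"`` (1.0 when complete).

    Raises
    ------
    CoverageError
        If no cell center falls inside the buffer.
    """
    mask, n_expected = _buffer_mask(grid, point, radius)
    n_in = int(mask.sum())
    if n_in == 0:
        raise CoverageError(f"buffer at {point} with radius {radius} is entirely off-grid")
    coverage = n_in / n_expected if n_expected else 1.0
    if coverage < 1.0 - 1e-12:
        warnings.warn(
            f"buffer at {point} (r={radius}) only {coverage:.1%} covered by the grid",
            stacklevel=2,
        )
    values = grid.codes[mask]
    out = {name: 0.0 for name in grid.legend.values()}
    codes, counts = np.unique(values, return_counts=True)
    for code, count in zip(codes, counts):
        out[grid.legend[int(code)]] += 100.0 * count / n_in
    out["coverage"] = coverage
    return out


def edge_length(
    grid: LandCoverGrid,
    point: tuple[float, float],
    radius: float,
) -> float:
    """Total boundary length between differing classes within the buffer.

    Counts 4-adjacent cell pairs with differing class where both centers
    are inside the buffer; each pair contributes one cell side.
    """
    mask, _ = _buffer_mask(grid, point, radius)
    if not mask.any():
        raise CoverageError(f"buffer at {point} with radius {radius} is entirely off-grid")
    codes = grid.codes
    horiz = (codes[:, :-1] != codes[:, 1:]) & mask[:, :-1] & mask[:, 1:]
    vert = (codes[:-1, :] != codes[1:, :]) & mask[:-1, :] & mask[1:, :]
    return float((horiz.sum() + vert.sum()) * grid.cell_size)


@dataclass(frozen=True)
class BufferMetrics:
    """Land-cover metrics for one nest at one buffer radius."""

    nest_id: str
    radius: float
    class_percent: Mapping[str, float]
    edge_length: float
    coverage: float


def metrics_table(
    grid: LandCoverGrid,
    nests: Sequence[NestRecord],
    radii: Sequence[float] = DEFAULT_RADII,
) -> list[BufferMetrics]:
    """Buffer metrics for every nest at every radius, in deterministic order.

    Nests without coordinates are skipped with a warning.
    """
    out = []
    for nest in nests:
        if nest.x is None or nest.y is None:
            warnings.warn(f"nest {nest.nest_id} has no coordinates; skipped", stacklevel=2)
            continue
        for radius in radii:
            props = class_proportions(grid, (nest.x, nest.y), radius)
            coverage = props.pop("coverage")
            out.append(BufferMetrics(
                nest_id=nest.nest_id,
                radius=float(radius),
                class_percent=props,
                edge_length=edge_length(grid, (nest.x, nest.y), radius),
                coverage=coverage,
            ))
    return out


def metrics_frame(metrics: Sequence[BufferMetrics]) -> pd.DataFrame:
    """Flatten buffer metrics to one row per nest × radius."""
    rows = []
    for m in metrics:
        row = {"nest_id": m.nest_id, "radius": m.radius,
               "edge_length": m.edge_length, "coverage": m.coverage}
        row.update({f"pct_{k}": v for k, v in m.class_percent.items()})
        rows.append(row)
    return pd.DataFrame(rows)
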