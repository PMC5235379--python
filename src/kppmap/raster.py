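"""Raster grids, habitability masks and the row/column segment index.

Grids live on a uniform Cartesian lattice with square cells; arrays are
row-major with row 0 at the *bottom* (origin lower-left).  The segment index
stores, for every row and every column, the maximal runs of habitable cells;
these runs are the unit on which all 1-D solver sweeps act.  Externally the
runs are reported 1-based inclusive; internally everything is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "RasterGrid",
    "RasterFormatError",
    "SegmentIndex",
    "PopulationState",
    "read_capacity_grid",
    "write_capacity_grid",
    "habitability_mask",
    "segment_mask",
    "apply_mask_transition",
]


class RasterFormatError(ValueError):
    """Raised when a grid file violates the ESRI ASCII grid format."""


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class RasterGrid:
    """A rectangular raster of non-negative real values on square cells.

    ``values`` has shape ``(n_rows, n_cols)`` with row 0 the southernmost
    row (origin at the lower-left corner).  Cells equal to ``nodata_value``
    are treated as missing (water, for capacity rasters).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        finite = self.values[~self.nodata_mask]
        if finite.size and np.any(finite < 0):
            raise ValueError("non-nodata grid values must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata_value

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata cells replaced by ``fill`` (default water)."""
        return np.where(self.nodata_mask, fill, self.values)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())


def read_capacity_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc) file.

    The six-line header (``ncols nrows xllcorner yllcorner cellsize
    [NODATA_value]``) is parsed case-insensitively; the body is whitespace
    separated, top row first, and is flipped so that row 0 of the returned
    array is the bottom row.  ``dx``/``dy`` headers (non-square cells) are
    rejected.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            key = tok[0].lower()
            if not data_lines and key.replace("_", "").isalpha():
                if key in ("dx", "dy"):
                    raise RasterFormatError(
                        "non-square cells (dx/dy headers) are unsupported"
                    )
                if len(tok) != 2:
                    raise RasterFormatError(f"malformed header line: {line!r}")
                try:
                    header[key] = float(tok[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"non-numeric header value in {line!r}"
                    ) from exc
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"missing header keys: {missing}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if n_cols < 1 or n_rows < 1:
        raise RasterFormatError("ncols and nrows must be >= 1")
    nodata = header.get("nodata_value", -9999.0)
    try:
        body = np.loadtxt(data_lines, dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"malformed grid body: {exc}") from exc
    flat = body.ravel()
    if flat.size != n_rows * n_cols:
        raise RasterFormatError(
            f"expected {n_rows * n_cols} values, found {flat.size}"
        )
    values = flat.reshape(n_rows, n_cols)[::-1].copy()  # top row first on disk
    return RasterGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata_value=nodata,
    )


def write_capacity_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write ``grid`` as an ESRI ASCII grid; inverse of :func:`read_capacity_grid`."""
    if grid.values.size == 0:
        raise ValueError("refusing to write an empty grid")
    path = Path(path)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin[0]!r}",
        f"yllcorner {grid.origin[1]!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {grid.nodata_value!r}",
    ]
    body = grid.values[::-1]  # disk layout is top row first
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in body:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def habitability_mask(grid: RasterGrid, water_threshold: float = 0.0) -> np.ndarray:
    """Boolean land mask: habitable iff K > water_threshold and not nodata."""
    return (grid.values > water_threshold) & ~grid.nodata_mask


def _runs(line: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array, 1-based inclusive."""
    idx = np.flatnonzero(line)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]


@dataclass
class SegmentIndex:
    """Habitable runs per row and per column (1-based inclusive bounds).

    ``row_segments[j]`` lists ``(xstart, xend)`` column runs of row ``j``;
    ``col_segments[i]`` lists ``(ystart, yend)`` row runs of column ``i``.
    """

    shape: tuple[int, int]
    row_segments: list[list[tuple[int, int]]]
    col_segments: list[list[tuple[int, int]]]

    def nxsegs(self, j: int) -> int:
        return len(self.row_segments[j])

    def nysegs(self, i: int) -> int:
        return len(self.col_segments[i])

    def row_slices(self, j: int) -> Iterator[slice]:
        """0-based column slices of the habitable runs in row ``j``."""
        for s, e in self.row_segments[j]:
            yield slice(s - 1, e)

    def col_slices(self, i: int) -> Iterator[slice]:
        for s, e in self.col_segments[i]:
            yield slice(s - 1, e)

    def covered_cells_by_rows(self) -> set[tuple[int, int]]:
        return {
            (j, i)
            for j, segs in enumerate(self.row_segments)
            for s, e in segs
            for i in range(s - 1, e)
        }

    def covered_cells_by_cols(self) -> set[tuple[int, int]]:
        return {
            (j, i)
            for i, segs in enumerate(self.col_segments)
            for s, e in segs
            for j in range(s - 1, e)
        }


def segment_mask(mask: np.ndarray) -> SegmentIndex:
    """Build the row/column segment index of a boolean habitability mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D boolean array")
    rows = [_runs(mask[j, :]) for j in range(mask.shape[0])]
    cols = [_runs(mask[:, i]) for i in range(mask.shape[1])]
    return SegmentIndex(shape=mask.shape, row_segments=rows, col_segments=cols)


@dataclass
class PopulationState:
    """Density field ``u`` on the grid plus the simulation clock (years).

    ``u`` is zero on non-habitable cells; after every full step
    ``0 <= u <= K(x, t)`` holds everywhere.  The named stage fields of the
    split step (u*, uE, u**) are transient and kept only when requested.
    """

    u: np.ndarray
    time: float = 0.0
    u_star: Optional[np.ndarray] = field(default=None, repr=False)
    u_E: Optional[np.ndarray] = field(default=None, repr=False)
    u_doublestar: Optional[np.ndarray] = field(default=None, repr=False)

    def copy(self) -> "PopulationState":
        return PopulationState(u=self.u.copy(), time=self.time)


def apply_mask_transition(
    state: PopulationState, old: np.ndarray, new: np.ndarray
) -> PopulationState:
    """Carry a population field across a coastline change.

    Cells that left the habitable set lose their population (flooding);
    newly habitable cells start empty; cells habitable in both masks keep
    their value.  Idempotent for fixed ``(old, new)``.
    """
    old = np.asarray(old, dtype=bool)
    new = np.asarray(new, dtype=bool)
    if old.shape != new.shape or old.shape != state.u.shape:
        raise ValueError("mask/state shapes do not match")
    u = np.where(old & new, state.u, 0.0)
    return PopulationState(u=u, time=state.time)
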