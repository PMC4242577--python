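"""Regular lon/lat grids, ESRI ASCII I/O, and occurrence thinning.

Grids follow the ESRI ASCII convention: row 0 is the northernmost row,
``(x_origin, y_origin)`` is the lower-left corner, and all coordinates
are WGS84 decimal degrees.  Pixel assignment is half-open: a point at
longitude ``x``, latitude ``y`` belongs to column
``floor((x - x_origin) / cell_size)`` and row
``floor((y_top - y) / cell_size)``; points on the east or south outer
edge are out of bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from cphylo.errors import ArgumentError, FormatError, OutOfBoundsError

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class RasterGrid:
    """One environmental variable on a regular lon/lat grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; ``values`` must match.
    x_origin, y_origin
        Lower-left corner, decimal degrees.
    cell_size
        Cell edge, decimal degrees (> 0).
    nodata_value
        Sentinel for missing cells; cells equal to it are excluded from
        all statistics.
    values
        2-D array, row 0 = northernmost row.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0
    values: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ArgumentError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ArgumentError(
                f"values shape {self.values.shape} != (n_rows, n_cols) = "
                f"({self.n_rows}, {self.n_cols})"
            )

    # -- geometry -----------------------------------------------------

    @property
    def y_top(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where data are valid."""
        with np.errstate(invalid="ignore"):
            return ~(np.isclose(self.values, self.nodata_value) | np.isnan(self.values))

    def same_geometry(self, other: "RasterGrid", *, tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.x_origin, other.x_origin, abs_tol=tol)
            and math.isclose(self.y_origin, other.y_origin, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, abs_tol=tol)
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Half-open (row, col) of a point; raises if outside the extent."""
        col = math.floor((lon - self.x_origin) / self.cell_size)
        row = math.floor((self.y_top - lat) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise OutOfBoundsError(
                f"point ({lon}, {lat}) outside grid extent "
                f"[{self.x_origin}, {self.x_origin + self.n_cols * self.cell_size}) x "
                f"[{self.y_origin}, {self.y_top})"
            )
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_top - (row + 0.5) * self.cell_size
        return lon, lat

    def value_at(self, lon: float, lat: float) -> float:
        row, col = self.cell_index(lon, lat)
        return float(self.values[row, col])

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """A copy sharing this grid's geometry with new cell values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def __eq__(self, other: object) -> bool:  # round-trip identity
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return self.same_geometry(other) and np.array_equal(
            self.values, other.values, equal_nan=True
        )


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one taxon."""

    taxon: str
    points: list[tuple[float, float]]  # (longitude, latitude)

    def __post_init__(self) -> None:
        self.points = [(float(x), float(y)) for x, y in self.points]
        if len(self.points) < 1:
            raise ArgumentError(f"OccurrenceSet for {self.taxon!r} needs >= 1 point")

    def __len__(self) -> int:
        return len(self.points)


# -- ESRI ASCII grid I/O ----------------------------------------------


def read_ascii_grid(path) -> RasterGrid:
    """Parse an ESRI ASCII grid file.

    The header must contain ncols/nrows/xllcorner/yllcorner/cellsize
    (case-insensitive); NODATA_value is optional and defaults to -9999.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        key = parts[0].lower()
        if key in _HEADER_KEYS + ("nodata_value",) and len(parts) == 2:
            header[key] = float(parts[1])
            i += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    for row_idx, line in enumerate(lines[i:]):
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in data row {row_idx}") from exc
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: row {row_idx} has {len(row)} values, expected {n_cols}"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise FormatError(f"{path}: {len(rows)} data rows, header says {n_rows}")
    return RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=header.get("nodata_value", -9999.0),
        values=np.array(rows, dtype=float),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write ``grid`` so that :func:`read_ascii_grid` round-trips it."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata_value!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# -- occurrence handling ----------------------------------------------


def thin_occurrences(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Keep one record per occupied grid cell (first in input order).

    Idempotent; raises :class:`OutOfBoundsError` naming the offending
    point index if any record falls outside the grid extent.
    """
    seen: set[tuple[int, int]] = set()
    kept: list[tuple[float, float]] = []
    for idx, (lon, lat) in enumerate(occ.points):
        try:
            cell = grid.cell_index(lon, lat)
        except OutOfBoundsError as exc:
            raise OutOfBoundsError(f"point {idx} of {occ.taxon!r}: {exc}") from exc
        if cell not in seen:
            seen.add(cell)
            kept.append((lon, lat))
    return OccurrenceSet(taxon=occ.taxon, points=kept)


def read_occurrences(path) -> list[OccurrenceSet]:
    """Read a (taxon, longitude, latitude) CSV into per-taxon sets."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"taxon", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: occurrence CSV needs columns {sorted(required)}")
    out = []
    for taxon, sub in df.groupby("taxon", sort=False):
        out.append(
            OccurrenceSet(
                taxon=str(taxon),
                points=list(zip(sub["longitude"], sub["latitude"])),
            )
        )
    return out


def write_occurrences(sets: Iterable[OccurrenceSet], path) -> None:
    import pandas as pd

    rows = [
        {"taxon": s.taxon, "longitude": x, "latitude": y}
        for s in sets
        for x, y in s.points
    ]
    pd.DataFrame(rows, columns=["taxon", "longitude", "latitude"]).to_csv(
        path, index=False
    )


def extract_climate(
    stack: Sequence[RasterGrid], points: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Sample every layer of a climate stack at the given points.

    Returns an (n_points, n_layers) array; nodata cells become NaN.
    """
    out = np.empty((len(points), len(stack)))
    for j, grid in enumerate(stack):
        for i, (lon, lat) in enumerate(points):
            r, c = grid.cell_index(lon, lat)
            v = grid.values[r, c]
            out[i, j] = np.nan if not grid.mask[r, c] else v
    return out


def stack_table(stack: Sequence[RasterGrid]) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a climate stack to a (n_valid_cells, n_vars) table.

    Returns ``(table, flat_index)`` where ``flat_index`` holds the
    row-major cell index of each table row; only cells valid in every
    layer are included.
    """
    if not stack:
        raise ArgumentError("empty climate stack")
    base = stack[0]
    for g in stack[1:]:
        if not g.same_geometry(base):
            raise ArgumentError("climate stack layers have mismatched geometry")
    valid = np.logical_and.reduce([g.mask for g in stack])
    flat = np.flatnonzero(valid.ravel())
    table = np.column_stack([g.values.ravel()[flat] for g in stack])
    return table, flat
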