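"""Grid, raster and vector data model used by every analysis stage.

All coordinates are planar metric (a projected CRS is assumed); CRS metadata
is an opaque string never used in computation.  Raster rows run top-down:
row 0 holds the maximum-y cells, matching common geospatial raster layout.
Cell membership is half-open with ties going to the cell to the right/below,
so sampling at any cell center always returns that cell's own value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InvalidArgumentError, OutOfBoundsError, ValidationError

RasterKind = Literal["continuous", "score", "class", "categorical", "binary"]

#: nodata sentinels by raster kind (class rasters use codes 1-3, so 0 is free)
NODATA_CONTINUOUS = -9999.0
NODATA_CLASS = 0


@dataclass(frozen=True)
class GridSpec:
    """Regular metric grid anchored at its top-left corner.

    The center of cell (row i, col j) is
    ``(x_min + (j + 0.5) * cell_size, y_max - (i + 0.5) * cell_size)``.
    """

    x_min: float
    y_max: float
    n_rows: int
    n_cols: int
    cell_size: float
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidArgumentError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid must have at least one row and column")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_min + (col + 0.5) * self.cell_size,
            self.y_max - (row + 0.5) * self.cell_size,
        )

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center x (per column) and y (per row)."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_grid(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of all cell centers, row-major."""
        xs, ys = self.center_coords()
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open membership: a point on a shared edge belongs to the cell
        to its right (x) / below (y)."""
        col = np.floor((np.asarray(x, float) - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def make_grid(bounds: tuple[float, float, float, float], cell_size: float,
              crs: str = "local-metric") -> GridSpec:
    """Build the smallest grid of ``cell_size`` cells covering ``bounds``.

    Column/row counts are ceilinged so the grid always covers the requested
    extent (it may overhang on the right/bottom when bounds are not multiples
    of the cell size).
    """
    x_min, y_min, x_max, y_max = bounds
    if cell_size <= 0:
        raise InvalidArgumentError(f"cell_size must be > 0, got {cell_size}")
    if x_max <= x_min or y_max <= y_min:
        raise InvalidArgumentError(f"inverted or empty bounds {bounds}")
    n_cols = int(np.ceil((x_max - x_min) / cell_size))
    n_rows = int(np.ceil((y_max - y_min) / cell_size))
    return GridSpec(x_min=x_min, y_max=y_max, n_rows=n_rows, n_cols=n_cols,
                    cell_size=cell_size, crs=crs)


@dataclass
class Raster:
    """Single-band raster on a :class:`GridSpec`.

    ``kind`` declares the value semantics: score rasters lie in [1, 3],
    class rasters take codes {1, 2, 3}, categorical rasters hold arbitrary
    integer codes.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA_CONTINUOUS
    kind: RasterKind = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, kind: RasterKind | None = None,
                    nodata: float | None = None) -> "Raster":
        return Raster(grid=self.grid, values=values,
                      nodata=self.nodata if nodata is None else nodata,
                      kind=self.kind if kind is None else kind)


@dataclass
class FeatureSet:
    """Plain container for point / polyline / polygon geometries in meters.

    ``geometries`` holds (k, 2) float arrays; polygons are closed rings
    (first vertex repeated last).  ``attributes`` is a per-feature list of
    dicts, parallel to ``geometries``.
    """

    geometry_type: Literal["point", "polyline", "polygon"]
    geometries: list[np.ndarray]
    attributes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        geoms = []
        for g in self.geometries:
            a = np.atleast_2d(np.asarray(g, dtype=float))
            if not np.all(np.isfinite(a)):
                raise ValidationError("non-finite coordinate in feature geometry")
            if self.geometry_type == "point" and a.shape != (1, 2):
                raise ValidationError("point features must be single coordinates")
            if self.geometry_type == "polyline" and a.shape[0] < 2:
                raise ValidationError("polylines need at least 2 vertices")
            if self.geometry_type == "polygon":
                if a.shape[0] < 4 or not np.allclose(a[0], a[-1]):
                    raise ValidationError("polygons must be closed rings (>=4 vertices)")
            geoms.append(a)
        self.geometries = geoms
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValidationError("attributes length must match geometries")

    def __len__(self) -> int:
        return len(self.geometries)

    def points(self) -> np.ndarray:
        """(n, 2) coordinate array; only valid for point feature sets."""
        if self.geometry_type != "point":
            raise InvalidArgumentError("points() requires a point FeatureSet")
        if not self.geometries:
            return np.empty((0, 2))
        return np.vstack(self.geometries)


@dataclass(frozen=True)
class ResidenceRecord:
    """One georeferenced case or control residence.

    Residences are located at shared postal-code centroids, so many records
    carry identical coordinates; ``birth_day`` is an integer day index used
    by the systematic control-sampling emulation.
    """

    id: str
    x: float
    y: float
    group: Literal["case", "control"]
    birth_day: int
    postal_centroid_id: str

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValidationError(f"record {self.id}: bad group label {self.group!r}")


def residence_xy(residences: Sequence[ResidenceRecord]) -> np.ndarray:
    return np.array([[r.x, r.y] for r in residences], dtype=float).reshape(-1, 2)


def case_indicator(residences: Sequence[ResidenceRecord]) -> np.ndarray:
    """Binary mark vector: case = 1, control = 0."""
    return np.array([1.0 if r.group == "case" else 0.0 for r in residences])


def sample_raster(r: Raster, pts: Iterable[tuple[float, float]],
                  ids: Sequence[str] | None = None,
                  return_nodata_mask: bool = False):
    """Value of the cell containing each point (half-open membership).

    Out-of-extent points raise :class:`OutOfBoundsError` naming the point;
    points landing on nodata cells propagate the raster's nodata sentinel
    (additionally flagged via ``return_nodata_mask=True``).
    """
    pts = np.atleast_2d(np.asarray(list(pts), dtype=float))
    if pts.size == 0:
        out = np.empty(0, dtype=r.values.dtype)
        return (out, np.zeros(0, bool)) if return_nodata_mask else out
    row, col = r.grid.xy_to_rowcol(pts[:, 0], pts[:, 1])
    bad = (row < 0) | (row >= r.grid.n_rows) | (col < 0) | (col >= r.grid.n_cols)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        name = ids[i] if ids is not None else f"index {i}"
        raise OutOfBoundsError(
            f"point {name} at ({pts[i, 0]}, {pts[i, 1]}) lies outside the grid extent")
    vals = r.values[row, col]
    if return_nodata_mask:
        return vals, vals == r.nodata
    return vals
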