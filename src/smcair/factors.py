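"""The five susceptibility factors: distance and density of polluting
activities, land use, road proximity, and fog-prone areas.

Each factor ends up as a raster with values in [1, 3] (1 = low, 3 = high
susceptibility): distances are classified by literature breakpoints
(moderate owns both endpoints, since "high" is the strict open interval
below the first break), the density surface is min-max rescaled onto the
continuous [1, 3] scale, land use maps categorically, and fog is binary
{1, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, SmcairError
from .geo_core import FeatureSet, GridSpec, Raster, NODATA_CLASS, NODATA_CONTINUOUS
from .synth_region import LANDUSE_CODES, Region


@dataclass
class ClassBreaks:
    """Two ordered thresholds cutting a continuous surface into 3 classes.

    With ``near_is_high`` (distance factors): value < b1 -> 3 (high),
    b1 <= value <= b2 -> 2 (moderate), value > b2 -> 1 (low).  The moderate
    class owns both endpoints.
    """

    breaks: tuple[float, float]
    orientation: Literal["near_is_high", "far_is_high"] = "near_is_high"

    def __post_init__(self) -> None:
        b1, b2 = self.breaks
        if not b1 < b2:
            raise InvalidArgumentError(f"breaks must be strictly increasing, got {self.breaks}")


#: literature breakpoints: polluting activities impact up to ~2 km, roads ~100/300 m
PRTR_BREAKS = ClassBreaks(breaks=(2000.0, 4000.0))
ROAD_BREAKS = ClassBreaks(breaks=(100.0, 300.0))


@dataclass
class KDEConfig:
    """Kernel density settings; 2 km bandwidth mirrors the emission-impact radius."""

    bandwidth: float = 2000.0
    kernel: Literal["quartic", "gaussian"] = "quartic"

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise InvalidArgumentError("bandwidth must be > 0")


@dataclass
class LandUseScoreMap:
    """Category -> susceptibility score (1 low, 2 moderate, 3 high)."""

    mapping: dict[int, int] = field(default_factory=lambda: {
        LANDUSE_CODES["natural"]: 1,
        LANDUSE_CODES["residential"]: 2,
        LANDUSE_CODES["industrial"]: 3,
    })


def _segments(features: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """Stack all polyline segments as (start, end) coordinate arrays."""
    starts, ends = [], []
    for geom in features.geometries:
        starts.append(geom[:-1])
        ends.append(geom[1:])
    return np.vstack(starts), np.vstack(ends)


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to any of the segments a[k]->b[k]."""
    ab = b - a                                   # (m, 2)
    denom = np.einsum("kd,kd->k", ab, ab)        # (m,)
    denom = np.where(denom == 0, 1.0, denom)
    ap = pts[:, None, :] - a[None, :, :]         # (n, m, 2)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def distance_raster(features: FeatureSet, grid: GridSpec,
                    chunk_cells: int = 200_000) -> Raster:
    """Exact Euclidean distance from every cell center to the nearest feature.

    Points go through a KD-tree; polylines are evaluated point-to-segment
    over all segments (chunked over cells to bound memory).
    """
    if len(features) == 0:
        raise SmcairError(
            "empty feature set; use the degenerate all-low classification instead")
    centers = grid.center_grid()
    if features.geometry_type == "point":
        tree = cKDTree(features.points())
        d, _ = tree.query(centers, k=1)
    elif features.geometry_type == "polyline":
        a, b = _segments(features)
        d = np.empty(len(centers))
        for s in range(0, len(centers), chunk_cells):
            d[s:s + chunk_cells] = _point_segment_distance(centers[s:s + chunk_cells], a, b)
    else:
        raise InvalidArgumentError("distance_raster supports point or polyline features")
    return Raster(grid=grid, values=d.reshape(grid.shape), kind="continuous")


def classify_by_breaks(r: Raster, cb: ClassBreaks) -> Raster:
    if r.kind != "continuous":
        raise InvalidArgumentError("classify_by_breaks expects a continuous raster")
    b1, b2 = cb.breaks
    v = r.values
    out = np.where(v < b1, 3, np.where(v <= b2, 2, 1)).astype(np.int64)
    if cb.orientation == "far_is_high":
        out = 4 - out
    out[~r.valid_mask] = NODATA_CLASS
    return Raster(grid=r.grid, values=out, nodata=NODATA_CLASS, kind="class")


def kde_raster(points: FeatureSet, cfg: KDEConfig, grid: GridSpec) -> Raster:
    """Kernel density of point events, reported per km².

    Quartic kernel: f(x) = sum_p 3/(pi h^2) (1 - (d_p/h)^2)^2 for d_p < h
    (per m²), scaled by 1e6; total mass integrates to the number of points
    whose kernel support lies inside the grid.  Gaussian kernels are
    truncated at 4h.
    """
    if len(points) > 0 and points.geometry_type != "point":
        raise InvalidArgumentError("kde_raster expects a point FeatureSet")
    h = cfg.bandwidth
    density = np.zeros(grid.shape)
    if len(points) == 0:
        import warnings
        warnings.warn("kde_raster called with zero points; returning all-zero density")
        return Raster(grid=grid, values=density, kind="continuous")
    xs, ys = grid.center_coords()
    support = h if cfg.kernel == "quartic" else 4.0 * h
    for px, py in points.points():
        c0 = max(0, int(np.floor((px - support - grid.x_min) / grid.cell_size)))
        c1 = min(grid.n_cols, int(np.ceil((px + support - grid.x_min) / grid.cell_size)) + 1)
        r0 = max(0, int(np.floor((grid.y_max - py - support) / grid.cell_size)))
        r1 = min(grid.n_rows, int(np.ceil((grid.y_max - py + support) / grid.cell_size)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - px
        dy = ys[r0:r1] - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        if cfg.kernel == "quartic":
            u2 = d2 / (h * h)
            k = np.where(u2 < 1.0, 3.0 / (np.pi * h * h) * (1.0 - u2) ** 2, 0.0)
        else:
            k = np.exp(-0.5 * d2 / (h * h)) / (2.0 * np.pi * h * h)
        density[r0:r1, c0:c1] += k
    return Raster(grid=grid, values=density * 1e6, kind="continuous")


def rescale_minmax_1_3(r: Raster) -> Raster:
    """Linear min-max rescale onto [1, 3]; a constant surface maps to all-1
    (lowest susceptibility)."""
    mask = r.valid_mask
    if not mask.any():
        raise SmcairError("cannot rescale an all-nodata raster")
    v = r.values.astype(float)
    vmin, vmax = v[mask].min(), v[mask].max()
    if vmax == vmin:
        out = np.ones_like(v)
    else:
        out = 1.0 + 2.0 * (v - vmin) / (vmax - vmin)
    out[~mask] = NODATA_CONTINUOUS
    return Raster(grid=r.grid, values=out, nodata=NODATA_CONTINUOUS, kind="score")


def landuse_scores(lu: Raster, m: LandUseScoreMap | None = None) -> Raster:
    if m is None:
        m = LandUseScoreMap()
    mask = lu.valid_mask
    present = np.unique(lu.values[mask])
    unmapped = [int(c) for c in present if int(c) not in m.mapping]
    if unmapped:
        raise SmcairError(f"land-use categories without a score mapping: {unmapped}")
    out = np.full(lu.values.shape, NODATA_CLASS, dtype=np.int64)
    for code, score in m.mapping.items():
        out[(lu.values == code) & mask] = score
    return Raster(grid=lu.grid, values=out, nodata=NODATA_CLASS, kind="class")


def fog_scores(fog_zones: FeatureSet, grid: GridSpec) -> Raster:
    """Binary fog factor: cell centers inside any fog polygon score 3
    (high), all others 1, so "high" means 3 across every factor."""
    out = np.ones(grid.shape, dtype=np.int64)
    if len(fog_zones) > 0:
        if fog_zones.geometry_type != "polygon":
            raise InvalidArgumentError("fog_scores expects polygon features")
        centers = grid.center_grid()
        inside = np.zeros(len(centers), dtype=bool)
        for ring in fog_zones.geometries:
            poly = shapely.Polygon(ring)
            inside |= shapely.contains_xy(poly, centers[:, 0], centers[:, 1])
        out[inside.reshape(grid.shape)] = 3
    return Raster(grid=grid, values=out, nodata=NODATA_CLASS, kind="class")


def compute_factor_scores(region: Region, kde: KDEConfig | None = None,
                          landuse_map: LandUseScoreMap | None = None
                          ) -> dict[str, Raster]:
    """All five factor rasters for a region, keyed by canonical factor name.

    Degenerate layers take the all-low path: with no facilities both the
    distance and density factors are uniformly 1.
    """
    grid = region.grid
    kde = kde or KDEConfig()
    out: dict[str, Raster] = {}

    if len(region.facilities) == 0:
        all_low = Raster(grid=grid, values=np.ones(grid.shape, dtype=np.int64),
                         nodata=NODATA_CLASS, kind="class")
        out["prtr_distance"] = all_low
        out["prtr_density"] = rescale_minmax_1_3(
            Raster(grid=grid, values=np.zeros(grid.shape), kind="continuous"))
    else:
        out["prtr_distance"] = classify_by_breaks(
            distance_raster(region.facilities, grid), PRTR_BREAKS)
        out["prtr_density"] = rescale_minmax_1_3(
            kde_raster(region.facilities, kde, grid))

    out["landuse"] = landuse_scores(region.landuse, landuse_map)

    if len(region.roads) == 0:
        out["roads"] = Raster(grid=grid, values=np.ones(grid.shape, dtype=np.int64),
                              nodata=NODATA_CLASS, kind="class")
    else:
        out["roads"] = classify_by_breaks(
            distance_raster(region.roads, grid), ROAD_BREAKS)

    out["fog"] = fog_scores(region.fog, grid)
    return out
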