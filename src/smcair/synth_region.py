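"""Synthetic study region and case-control cohort generator.

Emulates the data a riverside industrial study area provides: polluting
point sources (a pollutant-register style inventory), a sparse network of
major roads, a categorical land-use surface, a low-lying fog-prone band
along one edge, postal-code centroids, and georeferenced case/control
residences snapped to those centroids.  Everything is driven by one root
seed with independent per-layer streams, so changing e.g. the number of
facilities never perturbs the road layer.

The cohort generator can plant a spatial excess of cases (a disk where the
case intensity is multiplied) to exercise cluster detection; with
``cluster_excess = 1`` cases and controls are drawn from the identical
centroid distribution and are exchangeable — the planted-null property the
cluster-scan calibration tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, SmcairError
from .geo_core import FeatureSet, GridSpec, Raster, ResidenceRecord, make_grid, NODATA_CLASS

#: integer codes for land-use categories (raster values)
LANDUSE_CODES = {"natural": 1, "residential": 2, "industrial": 3}

# per-layer offsets mixed into the root seed so streams are independent
_STREAM = {"landuse": 1, "facilities": 2, "roads": 3, "centroids": 4, "cohort": 5}


def _rng(seed: int, layer: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[layer]]))


@dataclass
class RegionConfig:
    """Layout of the synthetic study region (defaults: 20 km x 15 km)."""

    bounds: tuple[float, float, float, float] = (0.0, 0.0, 20000.0, 15000.0)
    cell_size: float = 10.0          # meters; 50 m is the fast test profile
    n_facilities: int = 25
    n_roads: int = 8
    landuse_fractions: dict = field(default_factory=lambda: {
        "industrial": 0.08, "residential": 0.32, "natural": 0.60})
    fog_band_fraction: float = 0.20  # southern share of the region that is fog-prone
    landuse_smoothness_m: float = 800.0
    n_postal_centroids: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        if x1 <= x0 or y1 <= y0:
            raise InvalidArgumentError(f"zero-area or inverted bounds {self.bounds}")
        total = sum(self.landuse_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"landuse_fractions must sum to 1, got {total}")
        if self.n_facilities < 0 or self.n_roads < 0 or self.n_postal_centroids < 0:
            raise InvalidArgumentError("counts must be >= 0")
        if not 0.0 <= self.fog_band_fraction < 1.0:
            raise InvalidArgumentError("fog_band_fraction must be in [0, 1)")


@dataclass
class CohortConfig:
    """Case-control cohort drawn over the region's postal centroids.

    Defaults match the study-area sample scale (164 cases, 209 controls).
    ``cluster_excess`` multiplies the case intensity inside the disk of
    ``cluster_radius`` around ``cluster_center``; 1 means no planted cluster.
    """

    n_cases: int = 164
    n_controls: int = 209
    cluster_center: Optional[tuple[float, float]] = None
    cluster_radius: float = 2000.0
    cluster_excess: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise InvalidArgumentError("cohort counts must be >= 0")
        if self.cluster_excess < 1.0:
            raise InvalidArgumentError("cluster_excess must be >= 1")


@dataclass
class Region:
    grid: GridSpec
    facilities: FeatureSet
    roads: FeatureSet
    landuse: Raster
    fog: FeatureSet
    postal_centroids: FeatureSet
    config: RegionConfig


def _landuse_raster(cfg: RegionConfig, grid: GridSpec,
                    rng: np.random.Generator) -> Raster:
    """Spatially coherent categorical surface with exact class fractions.

    A white-noise field is smoothed to the configured correlation length,
    cells are ranked by field value, and categories are allocated exact cell
    counts (largest-remainder rounding) along that ranking — natural land on
    the low tail, industrial on the high tail.  Fractions are therefore
    realized exactly (to one cell) while patches stay contiguous.
    """
    field_vals = rng.standard_normal(grid.shape)
    sigma = cfg.landuse_smoothness_m / grid.cell_size
    field_vals = ndimage.gaussian_filter(field_vals, sigma=sigma, mode="nearest")
    order = np.argsort(field_vals, axis=None, kind="stable")

    n_cells = order.size
    cats = sorted(cfg.landuse_fractions, key=lambda c: LANDUSE_CODES.get(c, 99))
    quotas = np.array([cfg.landuse_fractions[c] * n_cells for c in cats])
    counts = np.floor(quotas).astype(int)
    rem = n_cells - counts.sum()
    for i in np.argsort(-(quotas - np.floor(quotas)))[:rem]:
        counts[i] += 1

    codes = np.empty(n_cells, dtype=np.int64)
    start = 0
    for cat, cnt in zip(cats, counts):
        codes[order[start:start + cnt]] = LANDUSE_CODES.get(cat, 0)
        start += cnt
    return Raster(grid=grid, values=codes.reshape(grid.shape),
                  nodata=NODATA_CLASS, kind="categorical")


def _sample_in_cells(grid: GridSpec, cell_idx: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform coordinates within the given flat cell indices."""
    rows, cols = np.unravel_index(cell_idx, grid.shape)
    u = rng.random((cell_idx.size, 2))
    x = grid.x_min + (cols + u[:, 0]) * grid.cell_size
    y = grid.y_max - (rows + u[:, 1]) * grid.cell_size
    return np.column_stack([x, y])


def _facilities(cfg: RegionConfig, grid: GridSpec, landuse: Raster,
                rng: np.random.Generator) -> FeatureSet:
    """Point sources, 85% placed inside industrial land when any exists."""
    n = cfg.n_facilities
    if n == 0:
        return FeatureSet(geometry_type="point", geometries=[], attributes=[])
    industrial = np.flatnonzero(landuse.values.ravel() == LANDUSE_CODES["industrial"])
    all_cells = np.arange(grid.n_rows * grid.n_cols)
    pick_ind = rng.random(n) < 0.85 if industrial.size else np.zeros(n, bool)
    cells = np.where(pick_ind,
                     industrial[rng.integers(0, max(industrial.size, 1), n)],
                     all_cells[rng.integers(0, all_cells.size, n)])
    xy = _sample_in_cells(grid, cells, rng)
    return FeatureSet(
        geometry_type="point",
        geometries=[xy[i:i + 1] for i in range(n)],
        attributes=[{"id": f"fac{i:03d}"} for i in range(n)])


def _roads(cfg: RegionConfig, rng: np.random.Generator) -> FeatureSet:
    """Polylines crossing the full region, alternating orientation, with
    jittered intermediate vertices."""
    x0, y0, x1, y1 = cfg.bounds
    w, h = x1 - x0, y1 - y0
    geoms, attrs = [], []
    for i in range(cfg.n_roads):
        horizontal = rng.random() < 0.5
        if horizontal:
            level = y0 + rng.random() * h
            xs = np.linspace(x0, x1, 5)
            ys = level + rng.uniform(-0.05, 0.05, 5) * h
            ys[0] = ys[0]  # endpoints keep their jitter; road still spans edges in x
            coords = np.column_stack([xs, np.clip(ys, y0, y1)])
        else:
            level = x0 + rng.random() * w
            ys = np.linspace(y0, y1, 5)
            xs = level + rng.uniform(-0.05, 0.05, 5) * w
            coords = np.column_stack([np.clip(xs, x0, x1), ys])
        geoms.append(coords)
        attrs.append({"id": f"road{i:02d}", "class": "major"})
    return FeatureSet(geometry_type="polyline", geometries=geoms, attributes=attrs)


def _fog_zone(cfg: RegionConfig) -> FeatureSet:
    """Low-lying fog-prone band along the southern (riverside) edge."""
    if cfg.fog_band_fraction <= 0:
        return FeatureSet(geometry_type="polygon", geometries=[], attributes=[])
    x0, y0, x1, y1 = cfg.bounds
    top = y0 + cfg.fog_band_fraction * (y1 - y0)
    ring = np.array([[x0, y0], [x1, y0], [x1, top], [x0, top], [x0, y0]])
    return FeatureSet(geometry_type="polygon", geometries=[ring],
                      attributes=[{"id": "fog0", "prone": True}])


#: postal-centroid placement weight by land-use code: postal codes follow
#: settlement, so residential land dominates, with some industrial-area codes
_PLACEMENT_WEIGHT = {2: 10.0, 3: 2.0}  # residential, industrial; natural = 1


def _postal_centroids(cfg: RegionConfig, grid: GridSpec, landuse: Raster,
                      rng: np.random.Generator) -> FeatureSet:
    n = cfg.n_postal_centroids
    if n == 0:
        return FeatureSet(geometry_type="point", geometries=[], attributes=[])
    codes = landuse.values.ravel()
    w = np.ones(codes.size)
    for code, wt in _PLACEMENT_WEIGHT.items():
        w[codes == code] = wt
    cells = rng.choice(codes.size, size=n, p=w / w.sum())
    xy = _sample_in_cells(grid, cells, rng)
    return FeatureSet(
        geometry_type="point",
        geometries=[xy[i:i + 1] for i in range(n)],
        attributes=[{"id": f"pc{i:04d}"} for i in range(n)])


def generate_region(cfg: RegionConfig) -> Region:
    """Generate all five input layers, georegistered to one grid.

    Deterministic given ``cfg.seed``; each layer draws from its own derived
    RNG stream.
    """
    grid = make_grid(cfg.bounds, cfg.cell_size)
    landuse = _landuse_raster(cfg, grid, _rng(cfg.seed, "landuse"))
    facilities = _facilities(cfg, grid, landuse, _rng(cfg.seed, "facilities"))
    roads = _roads(cfg, _rng(cfg.seed, "roads"))
    fog = _fog_zone(cfg)
    centroids = _postal_centroids(cfg, grid, landuse, _rng(cfg.seed, "centroids"))
    return Region(grid=grid, facilities=facilities, roads=roads, landuse=landuse,
                  fog=fog, postal_centroids=centroids, config=cfg)


#: residence-assignment weight by land-use code (residential favoured 3:1)
_CENTROID_WEIGHT = {LANDUSE_CODES["residential"]: 3.0}


def densest_centroid(region: Region, radius: float) -> tuple[float, float]:
    """Postal centroid with the most other centroids within ``radius``.

    The canonical anchor for a planted case cluster: a cluster is planted
    where the population actually concentrates (an unpopulated disk has
    nothing to detect), mirroring how real residential clusters sit in the
    densest urban parishes.  Ties break toward the lowest centroid index.
    """
    from scipy.spatial import cKDTree

    xy = region.postal_centroids.points()
    if len(xy) == 0:
        raise SmcairError("region has no postal centroids")
    tree = cKDTree(xy)
    counts = np.array([len(v) for v in tree.query_ball_point(xy, radius)])
    best = int(np.argmax(counts))
    return (float(xy[best, 0]), float(xy[best, 1]))


def generate_residences(region: Region, cfg: CohortConfig) -> list[ResidenceRecord]:
    """Draw case and control residences over the postal centroids.

    Both groups share one centroid weighting (residential land favoured);
    cases additionally have their intensity multiplied by ``cluster_excess``
    inside the planted disk.  Controls inherit birth days from the case
    multiset, emulating same-day systematic sampling.
    """
    centroids = region.postal_centroids
    if len(centroids) == 0:
        raise SmcairError("region has no postal centroids; cannot place residences")
    xy = centroids.points()
    ids = [a["id"] for a in centroids.attributes]

    from .geo_core import sample_raster
    codes = sample_raster(region.landuse, xy)
    base_w = np.array([_CENTROID_WEIGHT.get(int(c), 1.0) for c in codes])

    case_w = base_w.copy()
    if cfg.cluster_center is not None and cfg.cluster_excess > 1.0:
        cx, cy = cfg.cluster_center
        inside = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= cfg.cluster_radius
        case_w = np.where(inside, case_w * cfg.cluster_excess, case_w)

    rng = _rng(cfg.seed, "cohort")
    case_idx = rng.choice(len(ids), size=cfg.n_cases, p=case_w / case_w.sum())
    ctrl_idx = rng.choice(len(ids), size=cfg.n_controls, p=base_w / base_w.sum())

    case_days = rng.integers(0, 2160, size=cfg.n_cases)  # ~6-year window in days
    if cfg.n_cases > 0:
        ctrl_days = case_days[rng.integers(0, cfg.n_cases, size=cfg.n_controls)]
    else:
        ctrl_days = rng.integers(0, 2160, size=cfg.n_controls)

    records: list[ResidenceRecord] = []
    for i, (ci, day) in enumerate(zip(case_idx, case_days)):
        records.append(ResidenceRecord(
            id=f"C{i + 1:04d}", x=float(xy[ci, 0]), y=float(xy[ci, 1]),
            group="case", birth_day=int(day), postal_centroid_id=ids[ci]))
    for i, (ci, day) in enumerate(zip(ctrl_idx, ctrl_days)):
        records.append(ResidenceRecord(
            id=f"N{i + 1:04d}", x=float(xy[ci, 0]), y=float(xy[ci, 1]),
            group="control", birth_day=int(day), postal_centroid_id=ids[ci]))
    return records
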