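"""Indicator kriging of the case/control mark and the derived odds-ratio
surface.

The case indicator (case = 1, control = 0) is interpolated by ordinary
kriging with a fitted semivariogram, yielding a local case-probability
surface p̂; the odds-ratio surface is (p̂/(1-p̂)) divided by the study-wide
odds n_cases/n_controls, so OR = 1 reads "no local excess of cases".

Conventions: the exponential and spherical models use the effective-range
parameterisation (gamma reaches ~95% of the sill at ``range_``); for two
distinct records at identical coordinates (shared postal centroids) the
semivariance is the nugget, which regularizes the kriging system, and a
documented 0.1 m jitter is applied when the nugget is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ConvergenceError, InvalidArgumentError, SmcairError
from .geo_core import GridSpec, Raster


@dataclass
class VariogramModel:
    model: Literal["exponential", "spherical"]
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise InvalidArgumentError("variogram needs nugget, sill >= 0 and range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at lag h; gamma(0) = 0 exactly (measurement-free),
        rising through the nugget immediately for h > 0."""
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / self.range_)
        else:
            u = np.minimum(h / self.range_, 1.0)
            struct = 1.5 * u - 0.5 * u ** 3
        g = self.nugget + self.partial_sill * struct
        return np.where(h > 0, g, 0.0)


@dataclass
class EmpiricalVariogram:
    lags: np.ndarray          # bin-mean lag distance
    semivariance: np.ndarray
    pair_counts: np.ndarray


def empirical_variogram(pts: np.ndarray, values: np.ndarray,
                        n_bins: int = 15,
                        max_lag: float | None = None) -> EmpiricalVariogram:
    """Binned semivariance gamma(h) = (1 / 2N(h)) sum (v_i - v_j)^2 over
    point pairs; empty bins are omitted.  ``max_lag`` defaults to half the
    largest pairwise distance."""
    pts = np.asarray(pts, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(pts) < 2:
        raise InvalidArgumentError("need at least 2 points")
    d = pdist(pts)
    if d.max() == 0:
        raise SmcairError("all points coincident; variogram undefined")
    if max_lag is None:
        max_lag = d.max() / 2.0
    if max_lag <= 0:
        raise InvalidArgumentError("max_lag must be > 0")
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_lag
    lags, gammas, counts = [], [], []
    for b in range(n_bins):
        m = keep & (which == b)
        n_pairs = int(m.sum())
        if n_pairs == 0:
            continue
        lags.append(d[m].mean())
        gammas.append(0.5 * dv2[m].mean())
        counts.append(n_pairs)
    return EmpiricalVariogram(lags=np.array(lags), semivariance=np.array(gammas),
                              pair_counts=np.array(counts))


def fit_variogram(emp: EmpiricalVariogram,
                  model: Literal["exponential", "spherical"] = "exponential"
                  ) -> VariogramModel:
    """Weighted least squares (weights = pair counts) over (nugget,
    partial_sill, range) from a fixed multi-start grid; deterministic."""
    if len(emp.lags) < 3:
        raise InvalidArgumentError("need at least 3 non-empty bins to fit")
    lags, gam, cnt = emp.lags, emp.semivariance, emp.pair_counts
    sqrt_w = np.sqrt(cnt.astype(float))
    gmax = max(gam.max(), 1e-12)
    lmax = lags.max()

    def residuals(theta):
        vg = VariogramModel(model=model, nugget=theta[0], partial_sill=theta[1],
                            range_=theta[2])
        return sqrt_w * (vg(lags) - gam)

    lb = [0.0, 0.0, lags.min() / 10.0]
    ub = [2.0 * gmax, 4.0 * gmax, 10.0 * lmax]
    best, best_cost = None, np.inf
    for r0 in (0.25 * lmax, 0.5 * lmax, lmax, 2.0 * lmax):
        for nug_frac in (0.0, 0.25, 0.5):
            x0 = [nug_frac * gmax, max(gmax * (1 - nug_frac), 1e-9), r0]
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    if best is None or not best.success and best_cost == np.inf:
        raise ConvergenceError("variogram fit failed from every start")
    nug, sill, rng = best.x
    return VariogramModel(model=model, nugget=float(nug),
                          partial_sill=float(sill), range_=float(max(rng, 1e-9)))


def _gamma_matrix(vg: VariogramModel, pts: np.ndarray) -> np.ndarray:
    """Pairwise semivariance with nugget (not 0) for distinct coincident
    points, which keeps duplicate records from making the system singular."""
    d = squareform(pdist(pts))
    g = vg(d)
    off_diag_zero = (d == 0) & ~np.eye(len(pts), dtype=bool)
    g[off_diag_zero] = vg.nugget
    return g


def ordinary_krige(pts: np.ndarray, values: np.ndarray, vg: VariogramModel,
                   grid: GridSpec, max_neighbors: int = 16,
                   on_singular: Literal["jitter", "fail"] = "jitter") -> Raster:
    """Ordinary kriging of ``values`` onto every cell center.

    Per cell, the semivariance system over the ``max_neighbors`` nearest
    points (with the unbiasedness constraint sum(lambda) = 1 via a Lagrange
    multiplier) is solved; cells sharing a neighbor set share one factorized
    solve.  Zero-nugget duplicate coordinates are jittered by 0.1 m (or the
    call fails, per ``on_singular``).
    """
    pts = np.asarray(pts, dtype=float).copy()
    values = np.asarray(values, dtype=float)
    if len(pts) < 2:
        raise InvalidArgumentError("need at least 2 points")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < len(pts) and vg.nugget == 0.0:
        if on_singular == "fail":
            raise SmcairError("duplicate coordinates with zero nugget: singular system")
        rng = np.random.default_rng(0)
        _, first = np.unique(pts, axis=0, return_index=True)
        dup = np.ones(len(pts), dtype=bool)
        dup[first] = False
        pts[dup] += rng.uniform(-0.1, 0.1, size=(int(dup.sum()), 2))
    if len(np.unique(pts, axis=0)) < 2:
        raise InvalidArgumentError("need at least 2 distinct points")

    k = min(max_neighbors, len(pts))
    centers = grid.center_grid()
    tree = cKDTree(pts)
    _, nbr = tree.query(centers, k=k)
    if nbr.ndim == 1:
        nbr = nbr[:, None]
    nbr_sorted = np.sort(nbr, axis=1)
    groups, inverse = np.unique(nbr_sorted, axis=0, return_inverse=True)

    pred = np.empty(len(centers))
    for gi, idx in enumerate(groups):
        cells = np.flatnonzero(inverse == gi)
        sub = pts[idx]
        m = len(idx)
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = _gamma_matrix(vg, sub)
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        # rhs per cell in this group
        d0 = np.linalg.norm(centers[cells][:, None, :] - sub[None, :, :], axis=2)
        B = np.empty((m + 1, len(cells)))
        B[:m] = vg(d0).T
        B[m] = 1.0
        try:
            lam = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            lam, *_ = np.linalg.lstsq(A, B, rcond=None)
        pred[cells] = lam[:m].T @ values[idx]
    return Raster(grid=grid, values=pred.reshape(grid.shape), kind="continuous")


@dataclass
class ORSurface:
    p_hat: Raster
    OR: Raster
    baseline_odds: float


def odds_ratio_surface(p_hat: Raster, n_cases: int, n_controls: int,
                       eps: float = 1e-6) -> ORSurface:
    """OR = (p̂/(1-p̂)) / baseline odds, with p̂ clipped to [eps, 1-eps]."""
    if n_controls <= 0:
        raise InvalidArgumentError("n_controls must be > 0")
    baseline = n_cases / n_controls
    mask = p_hat.valid_mask
    p = np.clip(p_hat.values, eps, 1.0 - eps)
    orv = (p / (1.0 - p)) / baseline
    clipped = p_hat.with_values(np.where(mask, p, p_hat.nodata))
    or_raster = p_hat.with_values(np.where(mask, orv, p_hat.nodata))
    return ORSurface(p_hat=clipped, OR=or_raster, baseline_odds=baseline)
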