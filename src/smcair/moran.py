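"""Anselin Local Moran's I over case/control points with a fixed
distance-band neighborhood and conditional permutation inference.

The analysed variable is the binary case indicator over all residence
points, so a significant High-High label reads "local excess of cases".
The neighborhood is a 4 km band by default — the maximum plausible
pollutant-emission reach of an industrial source — and coincident points
(records sharing a postal centroid) are mutual neighbors at distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iterperms

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, ZeroVarianceError

DEFAULT_BAND = 4000.0


@dataclass
class SpatialWeights:
    """Row-standardized distance-band weights: each of a point's k neighbors
    gets weight 1/k; isolated points have empty neighbor lists."""

    neighbors: list[np.ndarray]
    band: float

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Row-standardized spatial lag; 0 for isolated points."""
        out = np.zeros(self.n)
        for i, nb in enumerate(self.neighbors):
            if len(nb):
                out[i] = z[nb].mean()
        return out


def distance_band_weights(pts: np.ndarray, band: float = DEFAULT_BAND) -> SpatialWeights:
    """j neighbors i iff dist(i, j) <= band and i != j (coincident points
    are therefore mutual neighbors)."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        raise InvalidArgumentError("need at least 2 points")
    if band <= 0:
        raise InvalidArgumentError("band must be > 0")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=band, output_type="ndarray")
    lists: list[list[int]] = [[] for _ in range(len(pts))]
    for i, j in pairs:
        lists[i].append(j)
        lists[j].append(i)
    neighbors = [np.array(sorted(nb), dtype=int) for nb in lists]
    return SpatialWeights(neighbors=neighbors, band=band)


@dataclass
class LocalMoranResult:
    I: np.ndarray          # local statistic; NaN for isolated points
    z_score: np.ndarray    # permutation z-score
    p_value: np.ndarray    # conditional permutation p (NaN for isolated)
    label: list[str]       # HH / LL / HL / LH / ns / isolated
    alpha: float
    n_perm: int


def _labels(z: np.ndarray, lag_z: np.ndarray, p: np.ndarray,
            isolated: np.ndarray, alpha: float) -> list[str]:
    # p is the folded (observed-tail) permutation p; a two-sided test at
    # level alpha therefore thresholds it at alpha / 2
    out = []
    for i in range(len(z)):
        if isolated[i]:
            out.append("isolated")
        elif not (p[i] <= alpha / 2.0):
            out.append("ns")
        else:
            hi = z[i] > 0
            lag_hi = lag_z[i] > 0
            out.append("HH" if hi and lag_hi else
                       "LL" if not hi and not lag_hi else
                       "HL" if hi else "LH")
    return out


def local_morans_i(values: np.ndarray, w: SpatialWeights, n_perm: int = 999,
                   seed: int | None = None, alpha: float = 0.05,
                   permutation: str = "sampled") -> LocalMoranResult:
    """Local Moran's I with conditional permutation inference.

    I_i = (z_i / m2) * sum_j w_ij z_j with z the mean deviations and
    m2 = sum z^2 / n.  Inference holds point i fixed and permutes the
    remaining values into its neighbor positions; the p-value is
    (1 + #{permuted I at least as extreme, same tail}) / (1 + n_perm) and
    the z-score uses the permutation mean and sd.

    ``permutation="exhaustive"`` enumerates every ordered assignment of
    held-out values to neighbor slots (small n only), making p exact.
    """
    x = np.asarray(values, dtype=float)
    n = w.n
    if len(x) != n:
        raise InvalidArgumentError("values length must match weights")
    if np.all(x == x[0]):
        raise ZeroVarianceError("analysed variable is constant; I undefined")
    if permutation == "sampled" and n_perm < 99:
        raise InvalidArgumentError("n_perm must be >= 99")

    z = x - x.mean()
    m2 = float(z @ z) / n
    card = w.cardinalities()
    isolated = card == 0
    lag_z = w.lag(z)
    I_obs = np.where(isolated, np.nan, z * lag_z / m2)

    p = np.full(n, np.nan)
    zs = np.full(n, np.nan)

    if permutation == "sampled":
        rng = np.random.default_rng(seed)
        max_k = int(card.max()) if n else 0
        # one bank of permutations of the n-1 held-out slots, truncated to
        # the largest cardinality; reused across points (standard practice)
        bank = np.empty((n_perm, max_k), dtype=int)
        for t in range(n_perm):
            bank[t] = rng.permutation(n - 1)[:max_k]
        for i in range(n):
            k = card[i]
            if k == 0:
                continue
            idx = bank[:, :k]
            idx_adj = idx + (idx >= i)          # skip self among held-out ids
            lag_perm = z[idx_adj].mean(axis=1)
            I_perm = z[i] * lag_perm / m2
            p[i], zs[i] = _tail_p(I_obs[i], I_perm)
    elif permutation == "exhaustive":
        if n > 8:
            raise InvalidArgumentError("exhaustive permutation only for n <= 8")
        others_all = np.arange(n)
        for i in range(n):
            k = card[i]
            if k == 0:
                continue
            others = np.delete(others_all, i)
            draws = np.array(list(_iterperms(others, int(k))), dtype=int)
            I_perm = z[i] * z[draws].mean(axis=1) / m2
            p[i], zs[i] = _tail_p(I_obs[i], I_perm)
    else:
        raise InvalidArgumentError(f"unknown permutation mode {permutation!r}")

    labels = _labels(z, lag_z, p, isolated, alpha)
    return LocalMoranResult(I=I_obs, z_score=zs, p_value=p, label=labels,
                            alpha=alpha, n_perm=n_perm)


def _tail_p(i_obs: float, i_perm: np.ndarray) -> tuple[float, float]:
    # tolerance so exact ties (obs == perm mean, or perm stats equal to obs
    # up to summation-order noise) resolve identically for any input order
    mean = i_perm.mean()
    sd = i_perm.std()
    tol = 1e-9 * max(1.0, abs(i_obs), abs(mean))
    if i_obs >= mean - tol:
        count = int(np.sum(i_perm >= i_obs - tol))
    else:
        count = int(np.sum(i_perm <= i_obs + tol))
    p = (1.0 + count) / (1.0 + len(i_perm))
    zscore = (i_obs - mean) / sd if sd > 0 else np.nan
    return p, zscore


def global_moran_from_local(result: LocalMoranResult) -> float:
    """Average of the local statistics; equals global Moran's I under
    row-standardized weights (Anselin decomposition)."""
    return float(np.nanmean(np.where(np.isnan(result.I), np.nan, result.I)))
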