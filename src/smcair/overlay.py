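"""Weighted linear combination of factor scores into the susceptibility
index S = sum_i w_i x_i, and its classification into low/moderate/high."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import AlignmentError, InvalidArgumentError
from .geo_core import Raster, NODATA_CLASS, NODATA_CONTINUOUS
from .ahp import default_weights


@dataclass
class WLCConfig:
    weights: dict[str, float] = field(default_factory=default_weights)
    class_method: Literal["equal_interval", "quantile"] = "equal_interval"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise InvalidArgumentError("weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(f"weights must sum to 1, got {total}")


@dataclass
class SusceptibilityMap:
    S: Raster
    classes: Raster
    config: WLCConfig


def wlc(factors: dict[str, Raster], cfg: WLCConfig) -> Raster:
    """Cell-wise S = sum w_i * x_i over factor score rasters sharing one
    grid; nodata in any factor propagates to S."""
    if set(cfg.weights) != set(factors):
        raise InvalidArgumentError(
            f"weights cover {sorted(cfg.weights)} but factors are {sorted(factors)}")
    total = sum(cfg.weights.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidArgumentError(f"weights must sum to 1, got {total}")
    rasters = list(factors.values())
    grid = rasters[0].grid
    for name, r in factors.items():
        if r.grid != grid:
            raise AlignmentError(f"factor {name!r} is on a different grid")
    S = np.zeros(grid.shape)
    invalid = np.zeros(grid.shape, dtype=bool)
    for name, r in factors.items():
        invalid |= ~r.valid_mask
        S += cfg.weights[name] * r.values.astype(float)
    S[invalid] = NODATA_CONTINUOUS
    return Raster(grid=grid, values=S, nodata=NODATA_CONTINUOUS, kind="continuous")


#: equal-interval boundaries on the theoretical [1, 3] index range
EQUAL_INTERVAL_BREAKS = (5.0 / 3.0, 7.0 / 3.0)


def classify_susceptibility(S: Raster, cfg: WLCConfig) -> Raster:
    """Cut S into classes 1/2/3.

    equal_interval (default, data-independent): [1, 5/3) -> 1,
    [5/3, 7/3) -> 2, [7/3, 3] -> 3.  quantile: tertiles of the valid cells.
    """
    mask = S.valid_mask
    v = S.values
    if mask.any() and ((v[mask] < 1.0 - 1e-9).any() or (v[mask] > 3.0 + 1e-9).any()):
        raise InvalidArgumentError(
            f"index values outside [1, 3]: range ({v[mask].min()}, {v[mask].max()})")
    if cfg.class_method == "equal_interval":
        b1, b2 = EQUAL_INTERVAL_BREAKS
    elif cfg.class_method == "quantile":
        b1, b2 = np.quantile(v[mask], [1 / 3, 2 / 3])
    else:
        raise InvalidArgumentError(f"unknown class_method {cfg.class_method!r}")
    out = np.where(v < b1, 1, np.where(v < b2, 2, 3)).astype(np.int64)
    out[~mask] = NODATA_CLASS
    return Raster(grid=S.grid, values=out, nodata=NODATA_CLASS, kind="class")


def susceptibility_map(factors: dict[str, Raster],
                       cfg: WLCConfig | None = None) -> SusceptibilityMap:
    cfg = cfg or WLCConfig()
    S = wlc(factors, cfg)
    return SusceptibilityMap(S=S, classes=classify_susceptibility(S, cfg), config=cfg)
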