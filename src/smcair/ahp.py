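"""Analytic hierarchy process: criterion weights and consistency ratio from
a pairwise comparison matrix on the Saaty scale.

Two weight extraction methods are provided: Saaty's approximate eigenvector
(normalize each column to sum 1, then average across columns within each
row — the package default) and the principal eigenvector by power iteration.
For both, lambda_max is computed from the consistency vector,
``(1/n) * sum_i (A w)_i / w_i``, giving CI = (lambda_max - n)/(n - 1) and
CR = CI / RI(n) with RI the Saaty random index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ConvergenceError, InvalidArgumentError

#: Saaty random consistency index by matrix order (0 for n <= 2)
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

#: canonical factor order used throughout the pipeline
FACTOR_NAMES = ["prtr_distance", "prtr_density", "landuse", "roads", "fog"]


@dataclass
class PairwiseMatrix:
    """n x n positive comparison judgments; a[i, j] = importance of i over j."""

    labels: list[str]
    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.labels)
        if n < 2:
            raise InvalidArgumentError("need at least 2 criteria")
        if self.a.shape != (n, n):
            raise InvalidArgumentError(
                f"matrix shape {self.a.shape} does not match {n} labels")
        if np.any(self.a <= 0) or not np.all(np.isfinite(self.a)):
            raise InvalidArgumentError("all pairwise judgments must be positive finite")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class AHPResult:
    weights: np.ndarray
    labels: list[str]
    lambda_max: float
    CI: float
    CR: float
    method: str
    warnings: list[str] = field(default_factory=list)

    def weight_map(self) -> dict[str, float]:
        return dict(zip(self.labels, self.weights))


def default_factor_matrix() -> PairwiseMatrix:
    """Bundled expert judgment matrix for the five air-pollution factors.

    Distance to and density of registered polluting activities dominate;
    land use is judged above road proximity, and fog-proneness is weakest.
    """
    a = np.array([
        [1, 1, 5, 5, 7],
        [1, 1, 5, 5, 7],
        [1 / 5, 1 / 5, 1, 3, 5],
        [1 / 5, 1 / 5, 1 / 5, 1, 5],
        [1 / 7, 1 / 7, 1 / 5, 1 / 5, 1],
    ])
    return PairwiseMatrix(labels=list(FACTOR_NAMES), a=a)


def default_weights() -> dict[str, float]:
    """Bundled canonical factor weights used by the overlay pipeline.

    Note the land-use/roads pair: recomputing weights from the bundled
    judgment matrix assigns 0.13 to land use and 0.09 to roads, while this
    canonical assignment carries the transposed values.  Both are internally
    consistent weight sets (they sum to 1 and share one multiset); the
    canonical one is kept for continuity and the discrepancy is surfaced by
    :func:`validate_matrix` warnings.  Pass ``ahp_weights(...).weight_map()``
    to the overlay instead to use the recomputed assignment.
    """
    return {"prtr_distance": 0.37, "prtr_density": 0.37, "landuse": 0.09,
            "roads": 0.13, "fog": 0.04}


def validate_matrix(m: PairwiseMatrix, tol: float = 1e-9) -> list[str]:
    """Diagnostics: diagonal != 1 and reciprocity deviations warn (returned
    and emitted as warnings); non-positive entries raise on construction."""
    msgs: list[str] = []
    diag = np.diag(m.a)
    for i, d in enumerate(diag):
        if abs(d - 1.0) > tol:
            msgs.append(f"diagonal entry for {m.labels[i]!r} is {d}, expected 1")
    for i in range(m.n):
        for j in range(i + 1, m.n):
            dev = abs(m.a[i, j] * m.a[j, i] - 1.0)
            if dev > tol:
                msgs.append(
                    f"reciprocity violated for ({m.labels[i]!r}, {m.labels[j]!r}): "
                    f"a_ij={m.a[i, j]:g}, a_ji={m.a[j, i]:g} (product {m.a[i, j] * m.a[j, i]:g})")
    for msg in msgs:
        warnings.warn(msg, stacklevel=2)
    return msgs


def _lambda_max(a: np.ndarray, w: np.ndarray) -> float:
    return float(np.mean((a @ w) / w))


def ahp_weights(m: PairwiseMatrix,
                method: Literal["column_normalization", "power_iteration"]
                = "column_normalization",
                max_iter: int = 500, tol: float = 1e-12) -> AHPResult:
    """Derive the weight vector, lambda_max, CI and CR.

    ``column_normalization`` is Saaty's approximate eigenvector;
    ``power_iteration`` iterates ``w <- A w / ||A w||_1`` to the principal
    eigenvector and raises :class:`ConvergenceError` if the residual does
    not fall below ``tol`` within ``max_iter``.
    """
    msgs = validate_matrix(m)
    a = m.a
    if method == "column_normalization":
        w = (a / a.sum(axis=0)).mean(axis=1)
    elif method == "power_iteration":
        w = np.full(m.n, 1.0 / m.n)
        for _ in range(max_iter):
            nxt = a @ w
            nxt /= nxt.sum()
            if np.max(np.abs(nxt - w)) < tol:
                w = nxt
                break
            w = nxt
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(residual {np.max(np.abs(a @ w / (a @ w).sum() - w)):.3e})")
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    w = w / w.sum()
    lam = _lambda_max(a, w)
    n = m.n
    ci = (lam - n) / (n - 1) if n > 1 else 0.0
    if n <= 2:
        cr = 0.0
    else:
        try:
            ri = RANDOM_INDEX[n]
        except KeyError:
            raise InvalidArgumentError(f"no random index tabulated for n={n}")
        cr = ci / ri
    return AHPResult(weights=w, labels=list(m.labels), lambda_max=lam,
                     CI=ci, CR=cr, method=method, warnings=msgs)


def read_matrix_csv(path: str | Path) -> PairwiseMatrix:
    """Read a labelled pairwise matrix from CSV; fractions like ``1/5`` are
    accepted in cells.  First row and first column carry the labels."""
    rows = [line.rstrip("\n").split(",") for line in
            Path(path).read_text().strip().splitlines()]
    labels = [c.strip() for c in rows[0][1:]]
    vals = []
    for row in rows[1:]:
        vals.append([float(Fraction(c.strip())) for c in row[1:]])
    return PairwiseMatrix(labels=labels, a=np.array(vals))
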