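"""First-order structured antedependence (SAD(1)) residual covariance.

Residuals around the genotype mean curve follow the antedependence process

    e_1 = eps_1,    e_t = phi * e_{t-1} + eps_t,    eps_t ~ N(0, nu2)

indexed by position in the individual's time grid (ordinal lag).  The
implied covariance has exact closed forms: writing Sigma = L D L' with L
unit lower-triangular (L[t, s] = phi^{t-s}) and D = nu2 * I,

    det Sigma  = nu2^T
    Sigma^{-1} = L'^{-1} D^{-1} L^{-1}   (tridiagonal)

so the log-determinant is T*log(nu2) and quadratic forms reduce to sums of
squared innovations (e_t - phi*e_{t-1})^2 / nu2 — an O(T) evaluation that
needs no stationarity assumption (variance grows along the grid whenever
|phi| >= 1, which is permitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .growth import TimeGrid

__all__ = [
    "SADParams",
    "sad1_covariance",
    "sad1_logdet_and_inverse",
    "sad1_innovations",
    "sad1_mvn_loglik",
]


@dataclass(frozen=True)
class SADParams:
    """Antedependence parameter ``phi`` and innovation variance ``nu2``.

    ``phi`` is unconstrained (the process is nonstationary for |phi| >= 1);
    ``nu2`` must be strictly positive.
    """

    phi: float
    nu2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.phi) and np.isfinite(self.nu2)):
            raise ValueError("SAD parameters must be finite")
        if self.nu2 <= 0:
            raise ValueError(f"innovation variance must be > 0, got {self.nu2}")


def _grid_len(grid: TimeGrid | int) -> int:
    if isinstance(grid, TimeGrid):
        return len(grid)
    t = int(grid)
    if t < 1:
        raise ValueError("grid length must be >= 1")
    return t


def sad1_covariance(grid: TimeGrid | int, p: SADParams) -> NDArray[np.float64]:
    """Dense T x T covariance of the SAD(1) process on ``grid``.

    Var(e_t) = nu2 * (1 + phi^2 + ... + phi^{2(t-1)}) and
    Cov(e_t, e_s) = phi^{|t-s|} * Var(e_min(t,s)) with t the 1-based
    position in the grid.
    """
    T = _grid_len(grid)
    phi, nu2 = p.phi, p.nu2
    # cumulative geometric sums give the diagonal; works at phi = +-1 too
    powers = phi ** (2 * np.arange(T))
    var = nu2 * np.cumsum(powers)
    idx = np.arange(T)
    lag = np.abs(idx[:, None] - idx[None, :])
    vmin = var[np.minimum(idx[:, None], idx[None, :])]
    return (phi ** lag) * vmin


def sad1_logdet_and_inverse(
    grid: TimeGrid | int, p: SADParams
) -> tuple[float, NDArray[np.float64]]:
    """Closed-form log-determinant and tridiagonal inverse of the SAD(1) covariance.

    log det Sigma = T * log(nu2); the inverse follows from the unit-bidiagonal
    factor L^{-1} (ones on the diagonal, -phi on the subdiagonal):
    Sigma^{-1} = L'^{-1} L^{-1} / nu2.
    """
    T = _grid_len(grid)
    phi, nu2 = p.phi, p.nu2
    logdet = T * float(np.log(nu2))
    inv = np.zeros((T, T))
    d = np.full(T, (1.0 + phi * phi) / nu2)
    d[-1] = 1.0 / nu2
    np.fill_diagonal(inv, d)
    if T > 1:
        off = -phi / nu2
        rows = np.arange(T - 1)
        inv[rows, rows + 1] = off
        inv[rows + 1, rows] = off
    return logdet, inv


def sad1_innovations(e: NDArray[np.float64], phi: float) -> NDArray[np.float64]:
    """Innovations w_t = e_t - phi*e_{t-1} (w_1 = e_1) along the last axis."""
    w = np.array(e, dtype=float, copy=True)
    w[..., 1:] -= phi * e[..., :-1]
    return w


def sad1_mvn_loglik(e: NDArray[np.float64], p: SADParams) -> float:
    """Gaussian log-density of residual vectors under the SAD(1) covariance.

    ``e`` is (T,) or (n, T); rows are independent individuals sharing a grid
    length.  Uses the innovation form: each row contributes
    -0.5 * (T log(2 pi nu2) + sum_t w_t^2 / nu2).
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    n, T = e.shape
    w = sad1_innovations(e, p.phi)
    ss = float(np.sum(w * w))
    return -0.5 * (n * T * np.log(2.0 * np.pi * p.nu2) + ss / p.nu2)
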