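"""Legendre orthogonal polynomial (LOP) smoothing basis.

Mean curves and the smoothing functions of the ODE decomposition are
expanded in Legendre polynomials P_0..P_K on [-1, 1], with arguments mapped
affinely onto that interval.  The basis is generated by the Bonnet
recurrence

    (k+1) P_{k+1}(x) = (2k+1) x P_k(x) - k P_{k-1}(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from numpy.typing import ArrayLike, NDArray

__all__ = ["lop_basis", "lop_design", "map_to_unit", "LopFit", "fit_lop"]


def lop_basis(x: ArrayLike, order: int) -> NDArray[np.float64]:
    """Evaluate (P_0(x), ..., P_order(x)) by the Bonnet recurrence.

    ``x`` may be scalar or an array; the basis index is the trailing axis of
    the result.  Callers are responsible for mapping their argument into
    [-1, 1] (see :func:`map_to_unit`); values outside are extrapolated.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape + (order + 1,))
    out[..., 0] = 1.0
    if order >= 1:
        out[..., 1] = x
    for k in range(1, order):
        out[..., k + 1] = ((2 * k + 1) * x * out[..., k] - k * out[..., k - 1]) / (k + 1)
    return out


def map_to_unit(t: ArrayLike, lo: float, hi: float) -> NDArray[np.float64]:
    """Affine map of [lo, hi] onto [-1, 1]."""
    if hi <= lo:
        raise ValueError("domain must satisfy hi > lo")
    return (2.0 * (np.asarray(t, dtype=float) - lo) / (hi - lo)) - 1.0


def lop_design(t: ArrayLike, order: int, domain: tuple[float, float]) -> NDArray[np.float64]:
    """Design matrix of Legendre basis values at ages ``t`` over ``domain``."""
    return lop_basis(map_to_unit(t, *domain), order)


@dataclass(frozen=True)
class LopFit:
    """A Legendre series y(t) = sum_k c_k P_k(x(t)) with its domain map."""

    coef: NDArray[np.float64]
    domain: tuple[float, float]

    @property
    def order(self) -> int:
        return self.coef.size - 1

    def __call__(self, t: ArrayLike) -> NDArray[np.float64]:
        return npleg.legval(map_to_unit(t, *self.domain), self.coef)

    def derivative(self, t: ArrayLike) -> NDArray[np.float64]:
        """Analytic dy/dt (chain rule supplies the 2/(hi-lo) factor)."""
        lo, hi = self.domain
        dcoef = npleg.legder(self.coef)
        return npleg.legval(map_to_unit(t, lo, hi), dcoef) * (2.0 / (hi - lo))


def fit_lop(
    t: ArrayLike,
    y: ArrayLike,
    order: int,
    domain: tuple[float, float] | None = None,
) -> LopFit:
    """Least-squares Legendre fit of y(t) over the (default pooled) time range."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if domain is None:
        domain = (float(t.min()), float(t.max()))
    X = lop_design(t, order, domain)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LopFit(coef=coef, domain=domain)
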