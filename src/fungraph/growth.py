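"""Logistic growth curve and time-grid primitives.

The mean trajectory of a growing trait is modelled by the three-parameter
logistic equation

    mu(t) = a / (1 + b * exp(-r * t))

where ``a`` is the asymptotic trait value, ``b`` sets the initial condition
(mu(0) = a / (1 + b)) and ``r`` is the relative growth rate.  Genotype
classes at a marker differ only through their (a, b, r) triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["GrowthParams", "TimeGrid", "logistic_mean"]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a logistic growth curve.

    Attributes
    ----------
    a : float
        Asymptotic trait value (trait units, > 0).
    b : float
        Initial-condition shape parameter (dimensionless, > 0);
        the curve starts at ``a / (1 + b)`` at t = 0.
    r : float
        Relative growth rate (1 / time units, > 0).
    """

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and np.isfinite(self.r)):
            raise ValueError("growth parameters must be finite")
        if self.a <= 0 or self.b <= 0 or self.r <= 0:
            raise ValueError(f"growth parameters must be positive, got {self}")

    def as_array(self) -> NDArray[np.float64]:
        return np.array([self.a, self.b, self.r], dtype=float)


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing sequence of measurement ages.

    Individuals may carry grids of different lengths; positions in the grid
    (not raw ages) index the antedependence recursion, so unequal spacing is
    handled ordinally.
    """

    times: NDArray[np.float64]

    def __init__(self, times: ArrayLike) -> None:
        arr = np.asarray(times, dtype=float)
        if arr.ndim != 1:
            raise ValueError("time grid must be one-dimensional")
        if arr.size == 0:
            raise ValueError("time grid must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time grid contains non-finite ages")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "times", arr)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def logistic_mean(t: ArrayLike, p: GrowthParams) -> NDArray[np.float64] | float:
    """Evaluate the logistic mean curve a / (1 + b e^{-rt}).

    Parameters
    ----------
    t : scalar, array or TimeGrid
        Age(s) at which to evaluate the curve.
    p : GrowthParams
        Curve parameters.

    Returns
    -------
    Trait value(s), same shape as ``t`` (scalar in, scalar out).
    """
    if isinstance(t, TimeGrid):
        t = t.times
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ages must be finite")
    out = p.a / (1.0 + p.b * np.exp(-p.r * arr))
    if np.isscalar(t) or arr.ndim == 0:
        return float(out)
    return out


def logistic_mean_arr(t: NDArray[np.float64], a: float, b: float, r: float) -> NDArray[np.float64]:
    """Unchecked fast path used inside optimizer loops."""
    return a / (1.0 + b * np.exp(-r * t))
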