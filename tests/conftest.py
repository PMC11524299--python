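import numpy as np
import pytest

from fungraph.funmap import EffectCurve
from fungraph.growth import GrowthParams, TimeGrid
from fungraph.ode import rk4_integrate
from fungraph.sad import SADParams
from fungraph.simulate import SimulationSpec, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """n=120 mapping population with one planted QTL at marker 0 (J=2)."""
    spec = SimulationSpec(n=120, m=6, seed=11)
    geno, trait = simulate_population(spec)
    return spec, geno, trait


@pytest.fixture(scope="session")
def planted_switch_system():
    """10-node noise-free system: node 1 driven by node 4 only, rest isolated.

    Bistable-cubic intrinsic dynamics give every node an S-shaped switch at
    its own onset time; the single anchored-linear coupling is strong.
    """
    times = np.linspace(0, 10, 50)
    rng = np.random.default_rng(3)
    m = 10
    c = rng.uniform(1.5, 2.5, m)
    K = c + rng.uniform(1.5, 3.0, m)
    mid = c + rng.uniform(0.3, 0.6, m) * (K - c)
    k = rng.uniform(2.0, 5.0, m) / ((K - c) * (K - mid))
    rise = rng.random(m) < 0.55
    z0 = np.where(rise, mid + rng.uniform(0.08, 0.45, m) * (K - mid),
                  mid - rng.uniform(0.08, 0.45, m) * (mid - c))
    W = np.zeros((m, m))
    W[0, 3] = 2.0

    def rhs(t, z):
        return -k * (z - c) * (z - mid) * (z - K) + W @ (z - z0)

    Z = rk4_integrate(rhs, z0, times, 6).T
    grid = TimeGrid(times)
    curves = [EffectCurve(curve_id=f"N{j + 1}", grid=grid,
                          values=np.maximum(Z[j], 0.0)) for j in range(m)]
    return curves, Z


@pytest.fixture
def simple_grid():
    return TimeGrid(np.linspace(0.0, 10.0, 11))


@pytest.fixture
def default_growth():
    return GrowthParams(a=10.0, b=9.0, r=0.5)


@pytest.fixture
def default_sad():
    return SADParams(phi=0.5, nu2=1.0)
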