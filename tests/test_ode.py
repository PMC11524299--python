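"""ODE decomposition: RK4, derivatives, regulator selection, conservation."""

import numpy as np
import pytest

from fungraph.funmap import EffectCurve
from fungraph.growth import GrowthParams, TimeGrid, logistic_mean_arr
from fungraph.ode import (CurveSystem, decompose, estimate_derivatives,
                          fit_node_ode, rk4_integrate, select_regulators)


class TestRK4:
    def test_exponential_decay_value(self):
        t = np.linspace(0, 1, 101)  # h = 0.01
        y = rk4_integrate(lambda ti, yi: -yi, 1.0, t)
        assert y[-1, 0] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_fourth_order_convergence(self):
        t2 = np.linspace(0, 1, 11)

        def err(substeps):
            y = rk4_integrate(lambda ti, yi: -yi, 1.0, t2, substeps)
            return abs(y[-1, 0] - np.exp(-1.0))

        assert err(1) / err(2) >= 8.0

    def test_vector_system(self):
        # harmonic oscillator preserves energy to RK4 accuracy
        t = np.linspace(0, 2 * np.pi, 200)
        y = rk4_integrate(lambda ti, yi: np.array([yi[1], -yi[0]]),
                          np.array([1.0, 0.0]), t, substeps=2)
        energy = y[:, 0] ** 2 + y[:, 1] ** 2
        assert np.max(np.abs(energy - 1.0)) < 1e-6


class TestDerivatives:
    def _curve(self, t, v):
        return EffectCurve(curve_id="c", grid=TimeGrid(t), values=v)

    def test_constant_curve(self):
        t = np.linspace(0, 5, 20)
        d = estimate_derivatives(self._curve(t, np.full(20, 2.0)))
        assert np.allclose(d, 0.0, atol=1e-10)

    def test_linear_curve(self):
        t = np.linspace(0, 5, 20)
        d = estimate_derivatives(self._curve(t, 3.0 + 2.0 * t))
        assert np.allclose(d, 2.0, atol=1e-7)

    def test_logistic_matches_closed_form(self):
        p = GrowthParams(a=10.0, b=9.0, r=0.7)
        t = np.linspace(0, 12, 40)
        z = logistic_mean_arr(t, p.a, p.b, p.r)
        d = estimate_derivatives(self._curve(t, z))
        truth = p.r * z * (1.0 - z / p.a)
        assert np.max(np.abs(d - truth)) < 0.01 * np.max(np.abs(truth))

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            estimate_derivatives(self._curve(np.array([0., 1., 2., 3.]),
                                             np.zeros(4)))


class TestSelectRegulators:
    def test_planted_single_regulator_included(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves)
        sel = select_regulators(system, "N1")
        assert "N4" in sel

    def test_flat_target_empty(self, planted_switch_system):
        curves, _ = planted_switch_system
        flat = EffectCurve(curve_id="FLAT", grid=curves[0].grid,
                           values=np.full(len(curves[0].grid), 1.7))
        system = CurveSystem(curves + [flat])
        assert select_regulators(system, "FLAT") == []

    def test_d_max_truncation(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves)
        sel = select_regulators(system, "N1", d_max=1)
        assert len(sel) <= 1

    def test_too_few_candidates_rejected(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves[:2])
        with pytest.raises(ValueError):
            select_regulators(system, "N1")


class TestFitNodeODE:
    def test_constant_slope_no_regulators(self):
        t = np.linspace(0, 5, 30)
        z = 1.0 + 0.5 * t
        curves = [EffectCurve(curve_id="a", grid=TimeGrid(t), values=z),
                  EffectCurve(curve_id="b", grid=TimeGrid(t),
                              values=np.full(30, 2.0))]
        system = CurveSystem(curves)
        node = fit_node_ode(system, "a", [])
        assert node.rmse <= 1e-3 * np.ptp(z)
        # Q_s evaluates ~0.5 along the whole trajectory
        qs = np.array([node.q_self(v) for v in z])
        assert np.allclose(qs, 0.5, atol=0.02)

    def test_driven_node_reconstruction_and_sign(self, planted_switch_system):
        curves, Z = planted_switch_system
        system = CurveSystem(curves)
        node = fit_node_ode(system, "N1", ["N4"])
        assert node.rmse < 0.05 * np.ptp(node.z_obs)
        dec = decompose(node)
        # sign of the accumulated dependent effect matches the planted
        # coupling 2.0 * (z4 - z4(0)) integrated over the horizon
        t = system.grid.times
        truth = np.trapezoid(2.0 * (Z[3] - Z[3][0]), t)
        assert np.sign(dec.dependent["N4"][-1]) == np.sign(truth)
        assert dec.dependent["N4"][-1] == pytest.approx(truth, rel=0.15)

    def test_conservation_identity(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves)
        for target, regs in [("N1", ["N4"]), ("N2", []), ("N3", ["N1", "N5"])]:
            node = fit_node_ode(system, target, regs)
            dec = decompose(node)
            rng_ = max(np.ptp(dec.net_fitted), 1e-8)
            assert dec.conservation_error <= 1e-6 * rng_

    def test_no_regulator_decomposition_trivial(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves)
        node = fit_node_ode(system, "N7", [])
        dec = decompose(node)
        assert dec.dependent == {}
        assert np.allclose(dec.independent, dec.net_fitted)

    def test_dependent_starts_at_zero(self, planted_switch_system):
        curves, _ = planted_switch_system
        system = CurveSystem(curves)
        node = fit_node_ode(system, "N1", ["N4"])
        dec = decompose(node)
        assert dec.dependent["N4"][0] == 0.0
        assert dec.independent[0] == pytest.approx(dec.net_fitted[0])
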