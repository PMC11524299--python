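"""Core primitives: logistic mean, SAD(1) covariance closed forms."""

import numpy as np
import pytest
from scipy import stats

from fungraph.growth import GrowthParams, TimeGrid, logistic_mean
from fungraph.sad import (SADParams, sad1_covariance, sad1_logdet_and_inverse,
                          sad1_mvn_loglik)


class TestLogisticMean:
    @pytest.mark.parametrize("t,expected", [
        (0.0, 1.0),                  # a/(1+b)
        (np.log(9.0) / 0.5, 5.0),    # half-asymptote where b*exp(-rt)=1
        (1e6, 10.0),                 # asymptote
    ])
    def test_known_values(self, t, expected):
        p = GrowthParams(a=10.0, b=9.0, r=0.5)
        assert logistic_mean(t, p) == pytest.approx(expected, abs=1e-9)

    def test_monotone_and_bounded(self):
        p = GrowthParams(a=7.3, b=4.1, r=0.8)
        t = np.linspace(-5, 30, 400)
        y = logistic_mean(t, p)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < p.a)

    def test_nonfinite_age_rejected(self):
        p = GrowthParams(a=1, b=1, r=1)
        with pytest.raises(ValueError):
            logistic_mean(np.inf, p)

    def test_invalid_params_rejected(self):
        for bad in [dict(a=-1, b=1, r=1), dict(a=1, b=0, r=1), dict(a=1, b=1, r=-2)]:
            with pytest.raises(ValueError):
                GrowthParams(**bad)


class TestTimeGrid:
    def test_requires_increasing(self):
        with pytest.raises(ValueError):
            TimeGrid([1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            TimeGrid([])

    def test_span(self):
        assert TimeGrid([1.0, 3.0, 7.0]).span == 6.0


class TestSAD1Covariance:
    def test_phi_zero_is_diagonal(self):
        S = sad1_covariance(3, SADParams(phi=0.0, nu2=2.0))
        assert np.allclose(S, 2.0 * np.eye(3))

    def test_closed_form_example(self):
        S = sad1_covariance(3, SADParams(phi=0.5, nu2=1.0))
        expected = np.array([[1.0, 0.5, 0.25],
                             [0.5, 1.25, 0.625],
                             [0.25, 0.625, 1.3125]])
        assert np.allclose(S, expected)
        assert np.linalg.det(S) == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_recursion(self):
        # accumulate Cov(e_t, e_s) exactly from e_t = phi*e_{t-1} + eps_t
        for phi, nu2, T in [(0.5, 1.0, 3), (0.8, 2.0, 5), (-0.7, 0.3, 6),
                            (1.2, 0.5, 4), (1.0, 1.0, 4)]:
            exact = np.zeros((T, T))
            var = 0.0
            variances = []
            for t in range(T):
                var = phi**2 * var + nu2
                variances.append(var)
            for i in range(T):
                for j in range(T):
                    exact[i, j] = phi ** abs(i - j) * variances[min(i, j)]
            assert np.allclose(sad1_covariance(T, SADParams(phi, nu2)), exact)

    def test_positive_definite_over_parameter_box(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            phi = rng.uniform(-0.99, 0.99)
            nu2 = rng.uniform(1e-3, 10.0)
            T = int(rng.integers(1, 51))
            S = sad1_covariance(T, SADParams(phi, nu2))
            np.linalg.cholesky(S)  # raises if not PD

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sad1_covariance(0, SADParams(0.5, 1.0))


class TestSAD1ClosedForms:
    def test_logdet_example(self):
        ld, _ = sad1_logdet_and_inverse(3, SADParams(0.5, 1.0))
        assert ld == pytest.approx(0.0, abs=1e-12)

    def test_phi_zero_inverse(self):
        _, inv = sad1_logdet_and_inverse(4, SADParams(0.0, 2.5))
        assert np.allclose(inv, np.eye(4) / 2.5)

    def test_against_dense_linear_algebra(self):
        # |phi| < 1 keeps the matrix well conditioned, so the dense inverse
        # itself is trustworthy at the 1e-8 comparison level
        rng = np.random.default_rng(1)
        for _ in range(100):
            phi = rng.uniform(-0.99, 0.99)
            nu2 = rng.uniform(0.05, 5.0)
            T = int(rng.integers(2, 51))
            p = SADParams(phi, nu2)
            S = sad1_covariance(T, p)
            ld, inv = sad1_logdet_and_inverse(T, p)
            sign, ld_dense = np.linalg.slogdet(S)
            assert sign == 1.0
            assert ld == pytest.approx(ld_dense, rel=1e-8, abs=1e-8)
            inv_dense = np.linalg.inv(S)
            denom = max(np.max(np.abs(inv_dense)), 1.0)
            assert np.max(np.abs(inv - inv_dense)) / denom < 1e-8

    def test_nonstationary_phi_residual_identity(self):
        # for |phi| >= 1 the matrix is too ill-conditioned to invert densely,
        # but the closed form still satisfies S @ inv = I exactly
        for phi, T in [(1.2, 20), (-1.4, 30), (1.0, 40)]:
            p = SADParams(phi, 0.7)
            S = sad1_covariance(T, p)
            _, inv = sad1_logdet_and_inverse(T, p)
            assert np.max(np.abs(S @ inv - np.eye(T))) < 1e-6

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            SADParams(phi=0.5, nu2=0.0)


class TestInnovationLoglik:
    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            T = int(rng.integers(2, 9))
            p = SADParams(phi=rng.uniform(-1.2, 1.2), nu2=rng.uniform(0.1, 3.0))
            e = rng.normal(size=(5, T))
            S = sad1_covariance(T, p)
            ref = stats.multivariate_normal(mean=np.zeros(T), cov=S).logpdf(e).sum()
            assert sad1_mvn_loglik(e, p) == pytest.approx(ref, rel=1e-10, abs=1e-8)
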