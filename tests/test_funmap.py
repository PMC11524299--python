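"""Functional mapping: likelihood, marker fits, effect curves, plasticity."""

import numpy as np
import pytest
from scipy import stats

from fungraph.funmap import (GenotypeVector, LongitudinalTrait, effect_curve,
                             fit_marker, group_loglik, lr_test,
                             permutation_threshold, plasticity_trait)
from fungraph.growth import GrowthParams, TimeGrid, logistic_mean_arr
from fungraph.sad import SADParams, sad1_covariance


def _trait_from_matrix(times, Y):
    grid = TimeGrid(times)
    return LongitudinalTrait(
        ids=[f"i{k}" for k in range(Y.shape[0])],
        grids=[grid] * Y.shape[0],
        values=[Y[k] for k in range(Y.shape[0])],
    )


class TestGroupLoglik:
    def test_single_point_density(self):
        trait = _trait_from_matrix(np.array([1.0]), np.array([[3.0]]))
        geno = GenotypeVector("s", np.array([0]))
        p = GrowthParams(a=3.0001, b=1e-6, r=1.0)  # mean ~ y
        mu = logistic_mean_arr(np.array([1.0]), p.a, p.b, p.r)[0]
        ll = group_loglik(trait, geno, {0: p}, SADParams(0.0, 1.0))
        expected = -0.5 * np.log(2 * np.pi) - 0.5 * (3.0 - mu) ** 2
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            T = int(rng.integers(3, 8))
            n = 50
            times = np.sort(rng.uniform(0, 10, T) + np.arange(T))
            codes = rng.integers(0, 2, n)
            params = {0: GrowthParams(11.0, 8.0, 0.6),
                      1: GrowthParams(9.0, 10.0, 0.45)}
            sad = SADParams(phi=rng.uniform(-0.8, 0.8), nu2=rng.uniform(0.2, 2.0))
            Y = rng.normal(5.0, 2.0, size=(n, T))
            trait = _trait_from_matrix(times, Y)
            geno = GenotypeVector("s", codes)
            S = sad1_covariance(T, sad)
            ref = 0.0
            for i in range(n):
                p = params[int(codes[i])]
                mu = logistic_mean_arr(times, p.a, p.b, p.r)
                ref += stats.multivariate_normal(mean=mu, cov=S).logpdf(Y[i])
            assert group_loglik(trait, geno, params, sad) == pytest.approx(
                ref, rel=1e-10, abs=1e-8)

    def test_missing_param_is_error(self):
        trait = _trait_from_matrix(np.array([1.0, 2.0, 3.0]), np.zeros((2, 3)))
        geno = GenotypeVector("s", np.array([0, 2]))
        with pytest.raises(KeyError):
            group_loglik(trait, geno, {0: GrowthParams(1, 1, 1)},
                         SADParams(0.0, 1.0))


class TestFitMarker:
    def test_recovers_planted_parameters(self, small_population):
        spec, geno, trait = small_population
        res = fit_marker(trait, geno.vector(0), seed=0)
        by_code = dict(zip(res.class_codes.tolist(), res.genotype_params))
        assert by_code[0].a == pytest.approx(12.0, rel=0.10)
        assert by_code[1].a == pytest.approx(10.0, rel=0.10)
        assert by_code[0].r == pytest.approx(0.6, rel=0.15)
        assert by_code[1].r == pytest.approx(0.5, rel=0.15)
        assert res.lr > 30  # planted QTL is unmissable at this effect size
        assert res.lr_deficit < 1e-4

    def test_null_marker_small_lr(self, small_population):
        spec, geno, trait = small_population
        res = fit_marker(trait, geno.vector(3), seed=0, n_restarts=2)
        assert res.lr < 25.0

    def test_single_class_is_error(self):
        times = np.linspace(1, 8, 5)
        Y = np.random.default_rng(0).normal(5, 1, (20, 5))
        trait = _trait_from_matrix(times, Y)
        geno = GenotypeVector("s", np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="insufficient genotype classes"):
            fit_marker(trait, geno)

    def test_small_class_dropped_and_flagged(self, small_population):
        spec, geno, trait = small_population
        codes = geno.codes[1].copy()
        codes[:2] = 2  # a 2-member class, below the floor of 3
        res = fit_marker(trait, GenotypeVector("s", codes), seed=0, n_restarts=1)
        assert 2 not in res.class_codes
        assert any(f.startswith("dropped_small_classes") for f in res.flags)


class TestLRTest:
    def test_equal_likelihoods(self):
        r = _dummy_result(0.0, 0.0)
        lr, p = lr_test(r)
        assert lr == 0.0 and p == 1.0

    def test_chi_square_reference(self):
        r = _dummy_result(logl1=5.0, logl0=0.0)
        lr, p = lr_test(r)
        assert lr == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10.0, 3), rel=1e-12)
        assert p == pytest.approx(0.0186, abs=2e-4)

    def test_negative_noise_clipped(self):
        r = _dummy_result(logl1=-1e-6, logl0=0.0)
        lr, p = lr_test(r)
        assert lr == 0.0 and p == 1.0


def _dummy_result(logl1, logl0):
    from fungraph.funmap import FunMapResult
    return FunMapResult(
        marker_id="s", class_codes=np.array([0, 1]),
        class_sizes=np.array([10, 10]),
        genotype_params=[GrowthParams(1, 1, 1)] * 2,
        null_params=GrowthParams(1, 1, 1),
        sad=SADParams(0.0, 1.0), sad_null=SADParams(0.0, 1.0),
        loglik_h1=logl1, loglik_h0=logl0)


class TestEffectCurve:
    def test_symmetric_two_class_gap(self):
        # mu1 = 6, mu2 = 4 constant: z = 1 at every age
        res = _dummy_result(0, 0)
        res.class_sizes = np.array([50, 50])
        res.genotype_params = [GrowthParams(6.0, 1e-9, 1.0),
                               GrowthParams(4.0, 1e-9, 1.0)]
        grid = TimeGrid(np.linspace(1, 5, 9))
        z = effect_curve(res, grid)
        assert np.allclose(z.values, 1.0, atol=1e-6)

    def test_identical_curves_zero(self):
        res = _dummy_result(0, 0)
        res.class_sizes = np.array([30, 70])
        res.genotype_params = [GrowthParams(5.0, 2.0, 0.5)] * 2
        z = effect_curve(res, TimeGrid(np.linspace(0, 5, 6)))
        assert np.allclose(z.values, 0.0)

    def test_three_class_arithmetic(self):
        # constants 2, 5, 8 with n = (25, 50, 25): z = sqrt(4.5)
        res = _dummy_result(0, 0)
        res.class_codes = np.array([0, 1, 2])
        res.class_sizes = np.array([25, 50, 25])
        res.genotype_params = [GrowthParams(2.0, 1e-9, 1.0),
                               GrowthParams(5.0, 1e-9, 1.0),
                               GrowthParams(8.0, 1e-9, 1.0)]
        z = effect_curve(res, TimeGrid(np.array([1.0, 2.0])))
        assert np.allclose(z.values, np.sqrt(4.5), atol=1e-6)

    def test_invariant_under_class_relabeling(self):
        res = _dummy_result(0, 0)
        res.class_sizes = np.array([40, 60])
        res.genotype_params = [GrowthParams(6.0, 3.0, 0.4),
                               GrowthParams(5.0, 2.0, 0.6)]
        grid = TimeGrid(np.linspace(0, 10, 12))
        z1 = effect_curve(res, grid).values
        res.class_sizes = res.class_sizes[::-1].copy()
        res.genotype_params = res.genotype_params[::-1]
        z2 = effect_curve(res, grid).values
        assert np.allclose(z1, z2)


class TestPlasticity:
    def _trait(self, ids, times, offset=0.0):
        grid = TimeGrid(times)
        rng = np.random.default_rng(0)
        return LongitudinalTrait(
            ids=list(ids), grids=[grid] * len(ids),
            values=[np.linspace(1, 5, len(times)) + offset for _ in ids])

    def test_identical_conditions_zero(self):
        t = np.linspace(1, 6, 6)
        a = self._trait(["x", "y"], t)
        b = self._trait(["x", "y"], t)
        d = plasticity_trait(a, b)
        assert all(np.allclose(v, 0.0) for v in d.values)

    def test_constant_offset(self):
        t = np.linspace(1, 6, 6)
        stress = self._trait(["x"], t)
        control = self._trait(["x"], t, offset=2.0)
        d = plasticity_trait(stress, control)
        assert np.allclose(d.values[0], 2.0)

    def test_unpaired_individual_excluded(self):
        t = np.linspace(1, 6, 6)
        stress = self._trait(["x", "y"], t)
        control = self._trait(["x"], t)
        d = plasticity_trait(stress, control)
        assert d.ids == ["x"]

    def test_interpolation_matches_hand_oracle(self):
        grid_s = TimeGrid(np.array([0.0, 2.0, 4.0, 6.0]))
        grid_c = TimeGrid(np.array([1.0, 3.0, 5.0, 7.0]))
        ys = np.array([0.0, 4.0, 8.0, 12.0])    # 2t
        yc = np.array([3.0, 9.0, 15.0, 21.0])   # 3t
        stress = LongitudinalTrait(ids=["x"], grids=[grid_s], values=[ys])
        control = LongitudinalTrait(ids=["x"], grids=[grid_c], values=[yc])
        d = plasticity_trait(stress, control)
        # shared grid = union within [1, 6]; both linear, so diff = t exactly
        expect_t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert np.allclose(d.grids[0].times, expect_t)
        assert np.allclose(d.values[0], expect_t, atol=1e-10)


class TestPermutationPreconditions:
    def test_too_few_permutations_rejected(self, small_population):
        spec, geno, trait = small_population
        with pytest.raises(ValueError):
            permutation_threshold(trait, geno, B=5)
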