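"""Functional clustering: EM mixture, BIC selection, module tree."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from fungraph.funclust import build_module_tree, fit_mixture, select_K
from fungraph.funmap import EffectCurve
from fungraph.growth import TimeGrid
from fungraph.legendre import lop_design
from fungraph.sad import sad1_covariance
from fungraph.simulate import simulate_curve_families


def test_single_component_is_gls_fit():
    curves, _ = simulate_curve_families(1, 30, seed=0)
    model = fit_mixture(curves, K=1, Q=4, seed=1)
    assert np.all(model.assignments == 0)
    # GLS with the fitted SAD covariance on the pooled mean curve
    grid = curves[0].grid
    Z = np.vstack([c.values for c in curves])
    B = lop_design(grid.times, 4, model.domain)
    S = sad1_covariance(len(grid), model.sad)
    Si = np.linalg.inv(S)
    coef = np.linalg.solve(B.T @ Si @ B, B.T @ Si @ Z.mean(axis=0))
    assert np.allclose(model.coef[0], coef, atol=1e-6)


def test_two_separated_families_recovered():
    curves, labels = simulate_curve_families(2, 50, seed=2)
    model = fit_mixture(curves, K=2, Q=4, seed=3)
    assert adjusted_rand_score(labels, model.assignments) >= 0.95


def test_duplication_leaves_means_unchanged():
    curves, _ = simulate_curve_families(2, 25, seed=4)
    m1 = fit_mixture(curves, K=2, Q=4, seed=5)
    doubled = curves + [
        EffectCurve(curve_id=f"{c.curve_id}_dup", grid=c.grid, values=c.values)
        for c in curves
    ]
    m2 = fit_mixture(doubled, K=2, Q=4, seed=5)
    # match components by nearest mean
    grid = curves[0].grid
    mu1 = m1.mean_curves(grid)
    mu2 = m2.mean_curves(grid)
    for k in range(2):
        j = np.argmin(np.linalg.norm(mu2 - mu1[k], axis=1))
        assert np.allclose(mu1[k], mu2[j], atol=1e-5)


def test_mixing_weights_normalized():
    curves, _ = simulate_curve_families(3, 20, seed=6)
    model = fit_mixture(curves, K=3, Q=4, seed=7)
    assert model.weights.sum() == pytest.approx(1.0)
    assert np.all(model.weights > 0)


def test_bic_definition_and_selection():
    curves, _ = simulate_curve_families(3, 40, seed=8)
    best_K, model, report = select_K(curves, range(1, 6), Q=4, seed=9)
    assert best_K == 3
    N = len(curves)
    for row in report:
        K = row["K"]
        p = K * 5 + (K - 1) + 2
        assert row["bic"] == pytest.approx(-2 * row["loglik"] + p * np.log(N))


def test_homogeneous_family_selects_one():
    curves, _ = simulate_curve_families(1, 40, seed=10)
    best_K, _, _ = select_K(curves, range(1, 5), Q=4, seed=11)
    assert best_K == 1


def test_label_permutation_equivalence():
    """Different initialization seeds give the same partition on separated data."""
    curves, _ = simulate_curve_families(2, 40, seed=12)
    m1 = fit_mixture(curves, K=2, Q=4, seed=100)
    m2 = fit_mixture(curves, K=2, Q=4, seed=200)
    sets1 = {frozenset(np.nonzero(m1.assignments == k)[0]) for k in range(2)}
    sets2 = {frozenset(np.nonzero(m2.assignments == k)[0]) for k in range(2)}
    assert sets1 == sets2


class TestModuleTree:
    def test_small_input_single_root(self):
        curves, _ = simulate_curve_families(2, 20, seed=13)  # 40 curves
        tree = build_module_tree(curves, max_leaf_size=50, seed=14)
        assert tree.root.is_leaf()
        assert tree.root.size == 40

    def test_planted_families_split(self):
        curves, labels = simulate_curve_families(4, 50, seed=15)
        tree = build_module_tree(curves, max_leaf_size=60,
                                 K_range=range(1, 7), seed=16)
        children = tree.root.children
        assert len(children) >= 3  # four planted families, allow one merge
        # leaves partition the input exactly
        leaves = tree.leaves()
        members = [m for leaf in leaves for m in leaf.members]
        assert sorted(members) == sorted(c.curve_id for c in curves)
        # each first-level module is dominated by one planted family
        by_id = {c.curve_id: lab for c, lab in zip(curves, labels)}
        for ch in children:
            fams = [by_id[m] for m in ch.members]
            top = max(np.bincount(fams)) / len(fams)
            assert top >= 0.9

    def test_leaf_size_floor(self):
        curves, _ = simulate_curve_families(1, 20, seed=17)
        with pytest.raises(ValueError):
            build_module_tree(curves, max_leaf_size=3)

    def test_assignments_are_leaf_paths(self):
        curves, _ = simulate_curve_families(3, 30, seed=18)
        tree = build_module_tree(curves, max_leaf_size=40, seed=19)
        assign = tree.assignments()
        assert set(assign) == {c.curve_id for c in curves}
        for node_id in assign.values():
            assert node_id.startswith("M")

    def test_roundtrip_dict(self):
        curves, _ = simulate_curve_families(2, 20, seed=20)
        tree = build_module_tree(curves, max_leaf_size=25, seed=21)
        from fungraph.funclust import ModuleTree
        clone = ModuleTree.from_dict(tree.to_dict())
        assert clone.root.node_id == tree.root.node_id
        assert [l.members for l in clone.leaves()] == [l.members for l in tree.leaves()]
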