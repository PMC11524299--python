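"""Functional clustering of genetic effect curves into network communities.

Effect curves on a shared grid are modelled by a K-component multivariate
normal mixture: component k has mean B c_k (a Legendre-series curve of
order Q over the pooled time range) and all components share one
SAD(1)-structured covariance.  Fitting is by EM with k-means starts; the
number of components is chosen by BIC; modules larger than a leaf-size cap
are recursively re-clustered into submodules, sub-submodules and so on,
producing the multilayer community tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import optimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .funmap import EffectCurve
from .growth import TimeGrid
from .legendre import lop_design
from .sad import SADParams, sad1_innovations

__all__ = ["CurveMixtureModel", "ModuleNode", "ModuleTree",
           "fit_mixture", "select_K", "build_module_tree"]

logger = logging.getLogger(__name__)


@dataclass
class CurveMixtureModel:
    """Fitted K-component curve mixture."""

    K: int
    Q: int
    coef: NDArray[np.float64]          # (K, Q+1) Legendre coefficients
    weights: NDArray[np.float64]       # (K,) mixing proportions
    sad: SADParams
    domain: tuple[float, float]
    loglik: float
    responsibilities: NDArray[np.float64]  # (N, K)
    assignments: NDArray[np.int64]         # (N,)

    def mean_curves(self, grid: TimeGrid) -> NDArray[np.float64]:
        B = lop_design(grid.times, self.Q, self.domain)
        return self.coef @ B.T

    @property
    def n_params(self) -> int:
        # K mean-coefficient vectors + (K-1) free weights + (phi, nu2)
        return self.K * (self.Q + 1) + (self.K - 1) + 2


def _curves_to_matrix(curves: list[EffectCurve]) -> tuple[NDArray, TimeGrid]:
    grid = curves[0].grid
    for c in curves[1:]:
        if len(c.grid) != len(grid) or not np.allclose(c.grid.times, grid.times):
            raise ValueError("all effect curves must share one time grid")
    return np.vstack([c.values for c in curves]), grid


def _component_loglik(Z: NDArray, means: NDArray, sad: SADParams) -> NDArray:
    """(N, K) matrix of per-curve per-component Gaussian log-densities."""
    N, T = Z.shape
    out = np.empty((N, means.shape[0]))
    const = -0.5 * T * np.log(2.0 * np.pi * sad.nu2)
    for k in range(means.shape[0]):
        W = sad1_innovations(Z - means[k], sad.phi)
        out[:, k] = const - 0.5 * np.sum(W * W, axis=1) / sad.nu2
    return out


def _update_sad(R: NDArray, Z: NDArray, means: NDArray) -> SADParams:
    """Maximize the expected complete-data likelihood over (phi, nu2).

    nu2 is profiled analytically for each phi; phi by bounded 1-D search.
    """
    N, T = Z.shape
    tot = float(R.sum()) * T

    def neg(phi: float) -> float:
        ss = 0.0
        for k in range(means.shape[0]):
            W = sad1_innovations(Z - means[k], phi)
            ss += float(np.sum(R[:, k] * np.sum(W * W, axis=1)))
        return 0.5 * tot * np.log(max(ss / tot, 1e-300))

    res = optimize.minimize_scalar(neg, bounds=(-2.0, 2.0), method="bounded",
                                   options={"xatol": 1e-4})
    phi = float(res.x)
    ss = 0.0
    for k in range(means.shape[0]):
        W = sad1_innovations(Z - means[k], phi)
        ss += float(np.sum(R[:, k] * np.sum(W * W, axis=1)))
    return SADParams(phi=phi, nu2=max(ss / tot, 1e-12))


def fit_mixture(
    curves: list[EffectCurve],
    K: int,
    Q: int = 4,
    *,
    max_iter: int = 200,
    tol: float = 1e-7,
    n_init: int = 5,
    seed: int | None = None,
    domain: tuple[float, float] | None = None,
) -> CurveMixtureModel:
    """EM fit of the K-component Legendre-mean / SAD(1)-covariance mixture.

    Initialized from k-means on the raw curve vectors (``n_init`` restarts,
    best final likelihood kept).  Hard assignments are by maximum posterior
    responsibility, ties broken toward the lowest cluster index.  The EM
    log-likelihood is asserted non-decreasing at every step.
    """
    Z, grid = _curves_to_matrix(curves)
    N, T = Z.shape
    if N < 2 * K:
        raise ValueError(f"need at least {2 * K} curves for K={K}, got {N}")
    if Q + 1 > T:
        raise ValueError(f"Legendre order {Q} needs a grid of length > {Q}")
    if domain is None:
        domain = (float(grid.times[0]), float(grid.times[-1]))
    B = lop_design(grid.times, Q, domain)  # (T, Q+1)
    rng = np.random.default_rng(seed)

    best: CurveMixtureModel | None = None
    for init in range(max(1, n_init)):
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1))).fit(Z)
        R = np.zeros((N, K))
        R[np.arange(N), km.labels_] = 1.0
        weights = R.mean(axis=0)
        coef = _wgls_means(R, Z, B, None)
        means = coef @ B.T
        sad = _update_sad(R, Z, means)

        ll_prev = -np.inf
        reseeded = False
        for it in range(max_iter):
            logp = _component_loglik(Z, means, sad) + np.log(weights)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            # EM monotonicity is a structural guarantee of the update
            # (void after a forced re-seed of an emptied component)
            assert reseeded or ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), (
                f"EM log-likelihood decreased: {ll_prev} -> {ll}")
            R = np.exp(logp - norm[:, None])
            # re-seed components that lost all mass
            reseeded = False
            for attempt in range(3):
                empty = np.nonzero(R.sum(axis=0) < 1e-8)[0]
                if empty.size == 0:
                    break
                reseeded = True
                for k in empty:
                    j = int(rng.integers(0, N))
                    R[j] = 0.0
                    R[j, k] = 1.0
            else:
                raise RuntimeError("EM component emptied repeatedly")
            weights = np.maximum(R.mean(axis=0), 1e-12)
            weights /= weights.sum()
            coef = _wgls_means(R, Z, B, sad)
            means = coef @ B.T
            sad = _update_sad(R, Z, means)
            if abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
                ll_prev = ll
                break
            ll_prev = ll

        logp = _component_loglik(Z, means, sad) + np.log(weights)
        norm = logsumexp(logp, axis=1)
        R = np.exp(logp - norm[:, None])
        model = CurveMixtureModel(
            K=K, Q=Q, coef=coef, weights=weights, sad=sad, domain=domain,
            loglik=float(norm.sum()), responsibilities=R,
            assignments=np.argmax(R, axis=1).astype(np.int64),
        )
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    return best


def _wgls_means(R: NDArray, Z: NDArray, B: NDArray,
                sad: SADParams | None) -> NDArray:
    """Responsibility-weighted GLS Legendre coefficients per component.

    With a common covariance across curves the GLS solution is
    (B' S^-1 B)^-1 B' S^-1 zbar_k where zbar_k is the responsibility-weighted
    mean curve; S^-1 enters through its bidiagonal innovation factor.
    """
    if sad is None:
        Bw, Zw = B, Z
    else:
        # innovation transform: rows of L^{-1} Z are uncorrelated
        Bw = sad1_innovations(B.T, sad.phi).T
        Zw = sad1_innovations(Z, sad.phi)
    G = Bw.T @ Bw
    K = R.shape[1]
    coef = np.empty((K, B.shape[1]))
    for k in range(K):
        w = R[:, k]
        zbar = (w @ Zw) / max(w.sum(), 1e-12)
        coef[k] = np.linalg.solve(G, Bw.T @ zbar)
    return coef


def select_K(
    curves: list[EffectCurve],
    K_range: range | list[int],
    Q: int = 4,
    *,
    seed: int | None = None,
    n_init: int = 5,
    **kwargs,
) -> tuple[int, CurveMixtureModel, list[dict]]:
    """Choose the component count minimizing BIC = -2 logL + p log N.

    N counts curves (the exchangeable units), p = K(Q+1) + (K-1) + 2.
    Returns (best K, best model, per-K report).
    """
    Ks = [k for k in K_range if 2 * k <= len(curves)]
    if not Ks:
        raise ValueError("K range empty (or all K too large for the data)")
    N = len(curves)
    rng = np.random.default_rng(seed)
    report, best = [], None
    for K in Ks:
        model = fit_mixture(curves, K, Q, seed=int(rng.integers(0, 2**31 - 1)),
                            n_init=n_init, **kwargs)
        bic = -2.0 * model.loglik + model.n_params * np.log(N)
        report.append({"K": K, "loglik": model.loglik, "bic": bic})
        if best is None or bic < best[1]:
            best = (K, bic, model)
    return best[0], best[2], report


@dataclass
class ModuleNode:
    """One node of the module hierarchy."""

    node_id: str
    members: list[str]                  # curve ids under this node
    mean_curve: NDArray[np.float64]
    children: list["ModuleNode"] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "members": self.members,
            "mean_curve": self.mean_curve.tolist(),
            "flags": self.flags,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleNode":
        return cls(
            node_id=d["node_id"], members=list(d["members"]),
            mean_curve=np.asarray(d["mean_curve"], dtype=float),
            flags=list(d.get("flags", [])),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )


@dataclass
class ModuleTree:
    """Hierarchical module / submodule / sub-submodule assignment of markers."""

    root: ModuleNode
    grid: TimeGrid

    def leaves(self) -> list[ModuleNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf():
                out.append(node)
            else:
                stack.extend(node.children)
        return out

    def assignments(self) -> dict[str, str]:
        """Map each marker id to its leaf node id (the full path)."""
        return {m: leaf.node_id for leaf in self.leaves() for m in leaf.members}

    def to_dict(self) -> dict:
        return {"grid": self.grid.times.tolist(), "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleTree":
        return cls(root=ModuleNode.from_dict(d["root"]), grid=TimeGrid(d["grid"]))


def build_module_tree(
    curves: list[EffectCurve],
    *,
    max_leaf_size: int = 30,
    K_range: range | list[int] | None = None,
    Q: int = 4,
    seed: int | None = None,
    n_init: int = 5,
    max_depth: int = 6,
) -> ModuleTree:
    """Recursive BIC-guided decomposition into modules/submodules/....

    Any node with more than ``max_leaf_size`` members is re-clustered; a node
    for which BIC selects K = 1 stays a leaf (flagged if oversized), as does
    any node at the depth cap.
    """
    if max_leaf_size < 5:
        raise ValueError("max_leaf_size must be >= 5")
    Z, grid = _curves_to_matrix(curves)
    rng = np.random.default_rng(seed)
    by_id = {c.curve_id: c for c in curves}

    def make_node(node_id: str, members: list[str], depth: int) -> ModuleNode:
        sub = [by_id[m] for m in members]
        mean = np.mean([c.values for c in sub], axis=0)
        node = ModuleNode(node_id=node_id, members=list(members), mean_curve=mean)
        if len(members) <= max_leaf_size:
            return node
        if depth >= max_depth:
            node.flags.append("depth_limit")
            logger.warning("module %s: depth limit reached with %d members",
                           node_id, len(members))
            return node
        kr = K_range if K_range is not None else range(1, 7)
        K, model, _ = select_K(sub, kr, Q, seed=int(rng.integers(0, 2**31 - 1)),
                               n_init=n_init)
        if K == 1:
            node.flags.append("oversized_leaf")
            logger.warning("module %s: BIC selected K=1 for %d members (> cap %d)",
                           node_id, len(members), max_leaf_size)
            return node
        for k in range(K):
            mem_k = [m for m, a in zip(members, model.assignments) if a == k]
            if not mem_k:
                continue
            node.children.append(make_node(f"{node_id}.{k + 1}", mem_k, depth + 1))
        return node

    root = make_node("M", [c.curve_id for c in curves], 0)
    return ModuleTree(root=root, grid=grid)
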