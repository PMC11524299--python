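"""Assembly of the multilayer, signed, weighted epistasis network.

Nodes carry time-averaged independent effects; a directed edge s' -> s
carries the time-averaged dependent effect of regulator s' on node s.  Each
reciprocal pair of weights is classified into one of seven epistasis types
(symmetric / asymmetric / directional, positive / negative, plus the
altruistic/repressive mixed-sign class), or "none" when both weights are
below the zero threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numpy.typing import NDArray

from .funclust import ModuleNode, ModuleTree
from .funmap import EffectCurve
from .growth import TimeGrid
from .ode import CurveSystem, EffectDecomposition, decompose, fit_node_ode, select_regulators

__all__ = [
    "EpistasisEdge",
    "MultilayerNetwork",
    "edge_weight",
    "classify_pair",
    "assemble_network",
    "EPISTASIS_TYPES",
]

logger = logging.getLogger(__name__)

EPISTASIS_TYPES = (
    "symmetric_positive",
    "asymmetric_positive",
    "directional_positive",
    "symmetric_negative",
    "asymmetric_negative",
    "directional_negative",
    "altruistic_repressive",
    "none",
)


@dataclass(frozen=True)
class EpistasisEdge:
    """Directed regulatory edge: ``source`` regulates ``target``."""

    source: str
    target: str
    weight: float
    sign: int  # -1, 0, +1

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError("edge weight must be finite")


def edge_weight(dependent_curve: NDArray[np.float64], grid: TimeGrid) -> float:
    """Time-averaged dependent effect: D(tau_T) / (tau_T - tau_1).

    The dependent curve is a running integral starting at zero, so its final
    value divided by the time span is the mean regulatory contribution per
    unit time, sign preserved.
    """
    span = grid.span
    if span <= 0:
        raise ValueError("grid span must be positive")
    return float(dependent_curve[-1] / span)


def classify_pair(W_ab: float, W_ba: float, epsilon: float, delta: float = 0.2) -> str:
    """Epistasis type of a reciprocal weight pair.

    ``W_ab`` is the weight of edge a <- b (b's effect on a) and ``W_ba`` of
    b <- a.  With u = W_ba and v = W_ab: both above +epsilon and within a
    relative gap delta is symmetric positive, otherwise asymmetric positive;
    one positive with the other inside [-epsilon, epsilon] is directional
    positive; mirror rules give the negative classes; opposite signs give
    altruistic/repressive; both inside the threshold give "none".
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    u, v = W_ba, W_ab
    u_pos, u_neg = u > epsilon, u < -epsilon
    v_pos, v_neg = v > epsilon, v < -epsilon
    if not (u_pos or u_neg) and not (v_pos or v_neg):
        return "none"
    if (u_pos and v_neg) or (u_neg and v_pos):
        return "altruistic_repressive"
    if u_pos and v_pos:
        sym = abs(u - v) <= delta * max(abs(u), abs(v))
        return "symmetric_positive" if sym else "asymmetric_positive"
    if u_neg and v_neg:
        sym = abs(u - v) <= delta * max(abs(u), abs(v))
        return "symmetric_negative" if sym else "asymmetric_negative"
    if u_pos or v_pos:
        return "directional_positive"
    return "directional_negative"


@dataclass
class MultilayerNetwork:
    """One directed graph per module-tree node, mirroring the hierarchy."""

    layers: dict[str, nx.DiGraph] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_edge_table(self):
        import pandas as pd

        rows = []
        for layer_id, g in self.layers.items():
            for u, v, d in g.edges(data=True):
                rows.append((layer_id, u, v, d["weight"], d["sign"],
                             d["epistasis_type"]))
        return pd.DataFrame(
            rows, columns=["layer", "source", "target", "weight", "sign",
                           "epistasis_type"])

    def to_node_table(self):
        import pandas as pd

        rows = []
        for layer_id, g in self.layers.items():
            for n, d in g.nodes(data=True):
                rows.append((layer_id, n, d.get("independent_effect", np.nan),
                             d.get("fit_rmse", np.nan)))
        return pd.DataFrame(rows, columns=["layer", "node",
                                           "independent_effect", "fit_rmse"])

    def write_graphml(self, path) -> None:
        """Union graph with a ``layer`` attribute on every node and edge."""
        g = nx.DiGraph()
        for layer_id, sub in self.layers.items():
            for n, d in sub.nodes(data=True):
                g.add_node(f"{layer_id}:{n}", layer=layer_id, **{
                    k: float(v) for k, v in d.items() if np.isscalar(v)})
            for u, v, d in sub.edges(data=True):
                g.add_edge(f"{layer_id}:{u}", f"{layer_id}:{v}", layer=layer_id,
                           weight=float(d["weight"]), sign=int(d["sign"]),
                           epistasis_type=str(d["epistasis_type"]))
        nx.write_graphml(g, path)


def _layer_network(
    curves: list[EffectCurve],
    *,
    d_max: int,
    K_ind: int,
    K_dep: int,
    epsilon_frac: float,
    delta: float,
) -> tuple[nx.DiGraph, dict[str, EffectDecomposition]]:
    system = CurveSystem(curves)
    span = system.grid.span
    g = nx.DiGraph()
    decomps: dict[str, EffectDecomposition] = {}
    weights: dict[tuple[str, str], float] = {}
    for cid in system.ids:
        regs = select_regulators(system, cid, K_ind=K_ind, K_dep=K_dep, d_max=d_max)
        node = fit_node_ode(system, cid, regs, K_ind=K_ind, K_dep=K_dep)
        dec = decompose(node)
        decomps[cid] = dec
        g.add_node(cid,
                   independent_effect=float(
                       np.trapezoid(dec.independent, system.grid.times) / span),
                   fit_rmse=node.rmse)
        for r in regs:
            weights[(r, cid)] = edge_weight(dec.dependent[r], system.grid)
    wmax = max((abs(w) for w in weights.values()), default=0.0)
    epsilon = max(epsilon_frac * wmax, 1e-12)
    for (src, tgt), w in weights.items():
        w_rev = weights.get((tgt, src), 0.0)
        etype = classify_pair(W_ab=w, W_ba=w_rev, epsilon=epsilon, delta=delta)
        sign = 0 if abs(w) <= epsilon else (1 if w > 0 else -1)
        if sign != 0:
            g.add_edge(src, tgt, weight=w, sign=sign, epistasis_type=etype)
    return g, decomps


def assemble_network(
    tree: ModuleTree,
    curves: list[EffectCurve],
    *,
    d_max: int = 5,
    K_ind: int = 3,
    K_dep: int = 3,
    epsilon_frac: float = 0.05,
    delta: float = 0.2,
) -> tuple[MultilayerNetwork, dict[str, dict[str, EffectDecomposition]]]:
    """Build one interaction network per module-tree node over its children.

    Internal nodes use their children's mean effect curves as network nodes
    (coarse-grained layers); leaves use the member markers' own curves
    (fine-grained layers).  Single-child nodes yield empty layers.

    Returns the network plus per-layer effect decompositions.
    """
    by_id = {c.curve_id: c for c in curves}
    net = MultilayerNetwork(metadata={
        "d_max": d_max, "K_ind": K_ind, "K_dep": K_dep,
        "epsilon_frac": epsilon_frac, "delta": delta,
    })
    all_decomps: dict[str, dict[str, EffectDecomposition]] = {}

    def visit(node: ModuleNode) -> None:
        if node.is_leaf():
            children = [by_id[m] for m in node.members]
        else:
            children = [
                EffectCurve(curve_id=ch.node_id, grid=tree.grid,
                            values=np.maximum(ch.mean_curve, 0.0))
                for ch in node.children
            ]
        if len(children) >= 2:
            try:
                g, decomps = _layer_network(
                    children, d_max=d_max, K_ind=K_ind, K_dep=K_dep,
                    epsilon_frac=epsilon_frac, delta=delta)
            except ValueError as exc:
                logger.warning("layer %s skipped: %s", node.node_id, exc)
                g, decomps = nx.DiGraph(), {}
            net.layers[node.node_id] = g
            all_decomps[node.node_id] = decomps
        else:
            net.layers[node.node_id] = nx.DiGraph()
            all_decomps[node.node_id] = {}
            if len(children) == 1:
                net.layers[node.node_id].add_node(children[0].curve_id)
        for ch in node.children:
            visit(ch)

    visit(tree.root)
    return net, all_decomps
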