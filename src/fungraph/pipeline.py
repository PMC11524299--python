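"""End-to-end orchestration: scan -> effect curves -> clustering -> network.

``run_pipeline`` executes the stages in order against one results directory,
writing a manifest that echoes every materialized default (seed, thresholds,
basis orders) and the completion state of each stage.  Stages whose outputs
already exist under an unchanged configuration are skipped, so a partial run
resumes from its intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .funclust import build_module_tree
from .funmap import (EffectCurve, effect_curve, max_lr, permutation_threshold,
                     plasticity_trait, scan)
from .growth import TimeGrid
from .io import (align_trait, read_curves, read_genotypes, read_phenotypes,
                 read_scan_results, read_tree, scan_table,
                 write_curves, write_scan_results, write_tree)
from .network import assemble_network

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of the pipeline, with its materialized default."""

    genotypes: str = ""
    phenotypes: str = ""
    out_dir: str = "fungraph_out"
    trait_mode: str = "single"      # "single", "plasticity", or a condition name
    grid_points: int = 30           # evaluation grid for effect curves
    permutations: int = 200
    alpha: float = 0.05
    min_class_size: int = 3
    n_restarts: int = 5
    perm_restarts: int = 2
    lop_order: int = 4              # clustering mean-curve order Q
    k_max: int = 6
    leaf_size: int = 30
    d_max: int = 5
    lop_ind: int = 3
    lop_dep: int = 3
    epsilon_frac: float = 0.05
    delta: float = 0.2
    seed: int = 0
    threads: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _select_trait(config: RunConfig):
    pheno = read_phenotypes(config.phenotypes)
    if isinstance(pheno, dict):
        if config.trait_mode == "plasticity":
            conds = sorted(pheno)
            if len(conds) != 2:
                raise ValueError(f"plasticity mode needs 2 conditions, got {conds}")
            # convention: later-sorted condition is treated as stress
            control, stress = pheno[conds[0]], pheno[conds[1]]
            return plasticity_trait(stress, control)
        if config.trait_mode in pheno:
            return pheno[config.trait_mode]
        raise ValueError(
            f"trait_mode {config.trait_mode!r} not among conditions {sorted(pheno)}")
    if config.trait_mode not in ("single", "plasticity"):
        raise ValueError("trait_mode names a condition but file has none")
    return pheno


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "package": "fungraph",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "stages": {},
    }
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") == manifest["config_digest"]:
            manifest["stages"] = old.get("stages", {})
        else:
            logger.info("configuration changed; all stages recomputed")

    def done(stage: str, *files: Path) -> bool:
        return (manifest["stages"].get(stage, {}).get("status") == "complete"
                and all(f.exists() for f in files))

    def record(stage: str, status: str, **extra) -> None:
        manifest["stages"][stage] = {"status": status, **extra}
        manifest_path.write_text(json.dumps(manifest, indent=1))

    rng = np.random.default_rng(config.seed)
    geno = read_genotypes(config.genotypes)
    trait = align_trait(geno, _select_trait(config))

    try:
        # ---- stage: scan -------------------------------------------------
        scan_json = out / "scan_results.json"
        scan_tsv = out / "scan.tsv"
        thr_json = out / "threshold.json"
        if done("scan", scan_json, thr_json):
            results = read_scan_results(scan_json)
            threshold = json.loads(thr_json.read_text())["threshold"]
            logger.info("scan stage reused from %s", scan_json)
        else:
            results = scan(trait, geno, min_class_size=config.min_class_size,
                           n_restarts=config.n_restarts,
                           seed=int(rng.integers(2**31 - 1)),
                           n_jobs=config.threads)
            threshold, maxima = permutation_threshold(
                trait, geno, config.permutations, config.alpha,
                min_class_size=config.min_class_size,
                n_restarts=config.perm_restarts,
                seed=int(rng.integers(2**31 - 1)), n_jobs=config.threads)
            write_scan_results(results, scan_json)
            thr_json.write_text(json.dumps({
                "threshold": threshold, "alpha": config.alpha,
                "B": config.permutations, "maxima": list(maxima)}))
            table = scan_table(results, geno, threshold)
            table.to_csv(scan_tsv, sep="\t", index=False)
            record("scan", "complete", markers=len(results),
                   fitted=sum(r is not None for r in results),
                   max_lr=max_lr(results), threshold=threshold)

        # ---- stage: effect curves ---------------------------------------
        curves_csv = out / "curves.csv"
        if done("curves", curves_csv):
            curves = read_curves(curves_csv)
        else:
            lo, hi = trait.pooled_time_range
            grid = TimeGrid(np.linspace(lo, hi, config.grid_points))
            curves = [effect_curve(r, grid) for r in results if r is not None]
            write_curves(curves, curves_csv)
            record("curves", "complete", curves=len(curves))

        # ---- stage: clustering ------------------------------------------
        tree_json = out / "tree.json"
        if done("cluster", tree_json):
            tree = read_tree(tree_json)
        else:
            tree = build_module_tree(
                curves, max_leaf_size=config.leaf_size,
                K_range=range(1, config.k_max + 1), Q=config.lop_order,
                seed=int(rng.integers(2**31 - 1)))
            write_tree(tree, tree_json)
            record("cluster", "complete", leaves=len(tree.leaves()))

        # ---- stage: network ---------------------------------------------
        edges_tsv = out / "edges.tsv"
        nodes_tsv = out / "nodes.tsv"
        graphml = out / "network.graphml"
        if not done("network", edges_tsv, graphml):
            net, decomps = assemble_network(
                tree, curves, d_max=config.d_max, K_ind=config.lop_ind,
                K_dep=config.lop_dep, epsilon_frac=config.epsilon_frac,
                delta=config.delta)
            net.to_edge_table().to_csv(edges_tsv, sep="\t", index=False)
            net.to_node_table().to_csv(nodes_tsv, sep="\t", index=False)
            net.write_graphml(graphml)
            _write_decompositions(decomps, out / "decompositions.csv")
            record("network", "complete",
                   layers=len(net.layers),
                   edges=int(sum(g.number_of_edges() for g in net.layers.values())))
    except Exception as exc:  # manifest records partial completion
        record("error", "failed", message=str(exc))
        raise

    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_decompositions(decomps, path: Path) -> None:
    import pandas as pd

    rows = []
    for layer, per_node in decomps.items():
        for node_id, dec in per_node.items():
            for comp, vals in (("net_fitted", dec.net_fitted),
                               ("independent", dec.independent),
                               *((f"dependent:{r}", v)
                                 for r, v in dec.dependent.items())):
                for t, v in zip(dec.grid.times, vals):
                    rows.append((layer, node_id, comp, t, v))
    pd.DataFrame(rows, columns=["layer", "node", "component", "time", "value"]
                 ).to_csv(path, index=False)
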