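"""Readers and writers for the pipeline's file formats.

Genotypes come in as VCF (biallelic sites, alt-allele dosage coding) or as
a CSV matrix with markers in rows and individuals in columns; phenotypes as
long-format CSV (id, time, value[, condition]); effect curves as a
markers-by-ages CSV; module trees and node fits as JSON; networks as
GraphML / TSV via the network module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .funclust import ModuleTree
from .funmap import (MISSING, EffectCurve, FunMapResult, GenotypeMatrix,
                     LongitudinalTrait, lr_test)
from .growth import GrowthParams, TimeGrid
from .sad import SADParams

__all__ = [
    "read_genotypes",
    "write_genotypes_csv",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_curves",
    "write_curves",
    "read_tree",
    "write_tree",
    "scan_table",
    "write_scan_results",
    "read_scan_results",
    "validate_ids",
    "align_trait",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, fmt: str | None = None,
                   *, multiallelic: str = "skip") -> GenotypeMatrix:
    """Load a genotype matrix from VCF or CSV (inferred from the suffix).

    ``multiallelic`` is "skip" (drop such VCF sites, logged) or "error".
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "csv"
    if fmt == "vcf":
        return _read_vcf(path, multiallelic=multiallelic)
    return _read_csv_matrix(path)


def _read_csv_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    meta_cols = [c for c in ("chrom", "pos") if c in df.columns]
    chrom = df["chrom"].astype(str).tolist() if "chrom" in df.columns else []
    pos = df["pos"].astype(int).tolist() if "pos" in df.columns else []
    data = df.drop(columns=meta_cols)
    codes = data.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int64)
    return GenotypeMatrix(
        marker_ids=[str(i) for i in df.index],
        individual_ids=[str(c) for c in data.columns],
        codes=codes, chrom=chrom, pos=pos,
    )


def _read_vcf(path: Path, multiallelic: str = "skip") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(f"multi-allelic site at {v.CHROM}:{v.POS}")
            logger.info("skipping multi-allelic site %s:%d", v.CHROM, v.POS)
            continue
        dos = np.empty(len(individual_ids), dtype=np.int64)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = int(sum(alleles))
        marker_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(str(v.CHROM))
        pos.append(int(v.POS))
        rows.append(dos)
    if not rows:
        raise ValueError(f"no usable biallelic sites in {path}")
    return GenotypeMatrix(marker_ids=marker_ids, individual_ids=individual_ids,
                          codes=np.vstack(rows), chrom=chrom, pos=pos)


def write_genotypes_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.codes, index=geno.marker_ids,
                      columns=geno.individual_ids).astype(float)
    df[df == MISSING] = np.nan
    df.insert(0, "pos", geno.pos)
    df.insert(0, "chrom", geno.chrom)
    df.to_csv(path, index_label="marker")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal uncompressed VCF 4.2 with dosage-coded genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individual_ids) + "\n")
        for j in range(geno.m):
            gts = "\t".join(_GT[int(c)] for c in geno.codes[j])
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.marker_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def validate_ids(geno: GenotypeMatrix, trait: LongitudinalTrait) -> None:
    """Require identical individual sets in genotypes and phenotypes."""
    gset, tset = set(geno.individual_ids), set(trait.ids)
    if gset != tset:
        offenders = sorted(gset.symmetric_difference(tset))
        raise ValueError(
            f"genotype/phenotype individual mismatch: {offenders[:20]}"
            + ("..." if len(offenders) > 20 else ""))


def align_trait(geno: GenotypeMatrix, trait: LongitudinalTrait) -> LongitudinalTrait:
    """Validate and reorder the phenotypes to the genotype column order.

    Marker scans pair trait row i with genotype column i, so the two must
    agree positionally, not just as sets.
    """
    validate_ids(geno, trait)
    if trait.ids == geno.individual_ids:
        return trait
    pos = {iid: k for k, iid in enumerate(trait.ids)}
    return trait.subset([pos[iid] for iid in geno.individual_ids])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> LongitudinalTrait | dict[str, LongitudinalTrait]:
    """Long-format CSV; with a ``condition`` column, one trait per condition."""
    df = pd.read_csv(path)
    required = {"id", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file needs columns {sorted(required)}")
    if "condition" in df.columns:
        return {str(cond): LongitudinalTrait.from_dataframe(sub)
                for cond, sub in df.groupby("condition")}
    return LongitudinalTrait.from_dataframe(df)


def write_phenotypes(traits: LongitudinalTrait | dict[str, LongitudinalTrait],
                     path: str | Path) -> None:
    if isinstance(traits, LongitudinalTrait):
        traits.to_dataframe().to_csv(path, index=False)
        return
    frames = []
    for cond, tr in traits.items():
        df = tr.to_dataframe()
        df["condition"] = cond
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# effect curves
# ---------------------------------------------------------------------------

def write_curves(curves: list[EffectCurve], path: str | Path) -> None:
    grid = curves[0].grid
    df = pd.DataFrame([c.values for c in curves],
                      index=[c.curve_id for c in curves],
                      columns=[f"{t:g}" for t in grid.times])
    df.to_csv(path, index_label="marker")


def read_curves(path: str | Path) -> list[EffectCurve]:
    df = pd.read_csv(path, index_col=0)
    grid = TimeGrid(np.array([float(c) for c in df.columns]))
    return [EffectCurve(curve_id=str(i), grid=grid,
                        values=row.to_numpy(dtype=float))
            for i, row in df.iterrows()]


# ---------------------------------------------------------------------------
# module tree
# ---------------------------------------------------------------------------

def write_tree(tree: ModuleTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1)


def read_tree(path: str | Path) -> ModuleTree:
    with open(path) as fh:
        return ModuleTree.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# scan results
# ---------------------------------------------------------------------------

def scan_table(results: list[FunMapResult | None], geno: GenotypeMatrix,
               threshold: float | None = None) -> pd.DataFrame:
    """Per-marker summary table of the LR scan."""
    rows = []
    for idx, res in enumerate(results):
        base = {"marker": geno.marker_ids[idx], "chrom": geno.chrom[idx],
                "pos": geno.pos[idx]}
        if res is None:
            rows.append({**base, "J": 0, "LR": np.nan, "p": np.nan,
                         "significant": False})
            continue
        lr, p = lr_test(res)
        row = {**base, "J": res.J, "LR": lr, "p": p,
               "significant": bool(threshold is not None and lr >= threshold),
               "phi": res.sad.phi, "nu2": res.sad.nu2}
        for code, gp in zip(res.class_codes, res.genotype_params):
            row[f"a_{code}"] = gp.a
            row[f"b_{code}"] = gp.b
            row[f"r_{code}"] = gp.r
        rows.append(row)
    return pd.DataFrame(rows)


def write_scan_results(results: list[FunMapResult | None], path: str | Path) -> None:
    """JSON round-trip of fitted marker models (for pipeline resume)."""
    payload = []
    for res in results:
        if res is None:
            payload.append(None)
            continue
        payload.append({
            "marker_id": res.marker_id,
            "class_codes": res.class_codes.tolist(),
            "class_sizes": res.class_sizes.tolist(),
            "genotype_params": [[p.a, p.b, p.r] for p in res.genotype_params],
            "null_params": [res.null_params.a, res.null_params.b, res.null_params.r],
            "sad": [res.sad.phi, res.sad.nu2],
            "sad_null": [res.sad_null.phi, res.sad_null.nu2],
            "loglik_h1": res.loglik_h1,
            "loglik_h0": res.loglik_h0,
            "converged": res.converged,
            "flags": res.flags,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_scan_results(path: str | Path) -> list[FunMapResult | None]:
    with open(path) as fh:
        payload = json.load(fh)
    out: list[FunMapResult | None] = []
    for d in payload:
        if d is None:
            out.append(None)
            continue
        out.append(FunMapResult(
            marker_id=d["marker_id"],
            class_codes=np.asarray(d["class_codes"], dtype=np.int64),
            class_sizes=np.asarray(d["class_sizes"], dtype=np.int64),
            genotype_params=[GrowthParams(*p) for p in d["genotype_params"]],
            null_params=GrowthParams(*d["null_params"]),
            sad=SADParams(*d["sad"]),
            sad_null=SADParams(*d["sad_null"]),
            loglik_h1=d["loglik_h1"],
            loglik_h0=d["loglik_h0"],
            converged=d["converged"],
            flags=list(d["flags"]),
        ))
    return out
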