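"""End-to-end pipeline: simulate/load -> preprocess -> train E- and M-maps
-> spots -> gene sets -> phenotype maps -> E-M integration, with a run
manifest and reproducible outputs.

All numeric outputs use a fixed float format and stable row/column
ordering, so rerunning with the same config and seed reproduces
byte-identical files.  Per-stage seeds are derived from the master seed
via a counter, so individual stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .matrix import OmicsMatrix, ConfigurationError, SurvivalTable
from .preprocess import (center_genes, drop_sex_chromosomes, promoter_beta,
                         quantile_normalize)
from .synthetic import CohortConfig, SyntheticTruth, generate_cohort
from .som import SomModel, SomParams, train_som
from .spots import (call_spots, detect_group_spots, module_recovery,
                    spot_implication, spot_number_distribution,
                    spots_to_frame)
from .genesets import GeneSet, gsz_profiles
from .phenotype import (covariate_map, female_difference_map, prognostic_map)
from .integration import build_em_network, covariance_map, sample_similarity

log = logging.getLogger("cartograph")

_FF = "%.10g"


@dataclass
class RunConfig:
    """One pipeline run: either a simulate block or paths to input files."""

    out_dir: str
    seed: int = 0
    simulate: Optional[CohortConfig] = None
    expr_path: Optional[str] = None
    cpg_path: Optional[str] = None
    genes_path: Optional[str] = None
    pheno_path: Optional[str] = None
    gmt_path: Optional[str] = None
    expr_grid: int = 50
    meth_grid: int = 30
    epochs: int = 40
    spot_quantile: float = 0.98
    spot_min_size: int = 3
    connectivity: int = 8
    call_quantile: float = 0.90
    implication_conf_min: float = 0.5
    em_p_max: float = 1e-3
    em_r_max: float = 0.0
    plots: bool = False

    def __post_init__(self) -> None:
        if self.simulate is None:
            needed = [self.expr_path, self.cpg_path, self.genes_path,
                      self.pheno_path]
            if any(p is None for p in needed):
                raise ConfigurationError(
                    "need either a simulate block or expr/cpg/genes/pheno paths")
            for p in needed:
                if not os.path.exists(p):
                    raise ConfigurationError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = CohortConfig(**sim)
        return cls(simulate=sim, **raw)

    def stage_seed(self, counter: int) -> int:
        return (self.seed * 1009 + counter) % (2 ** 31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_map_frame(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FF)


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute all stages; return the manifest (also written as JSON)."""
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    outputs: List[str] = []
    manifest: Dict = {"seed": cfg.seed, "parameters": {}, "inputs": {},
                      "outputs": outputs}

    def emit(name: str) -> str:
        path = os.path.join(out, name)
        outputs.append(name)
        return path

    def stage(name):
        log.info("stage %s", name)

    # ---- inputs -------------------------------------------------------
    truth: Optional[SyntheticTruth] = None
    if cfg.simulate is not None:
        stage("simulate")
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.stage_seed(0))
        expr, cpgs, ann, pheno, truth = generate_cohort(sim_cfg)
        cio.write_matrix_tsv(expr, emit("expr.tsv"))
        cio.write_cpg_table(cpgs, emit("cpg.tsv"))
        cio.write_gene_annotation(ann, emit("genes.tsv"))
        cio.write_phenotype_csv(pheno, emit("pheno.csv"))
        truth.to_json(emit("truth.json"))
    else:
        stage("load")
        expr = cio.read_matrix_tsv(cfg.expr_path)
        cpgs = cio.read_cpg_table(cfg.cpg_path)
        ann = cio.read_gene_annotation(cfg.genes_path)
        pheno = cio.read_phenotype_csv(cfg.pheno_path)
        for key, p in [("expr", cfg.expr_path), ("cpg", cfg.cpg_path),
                       ("genes", cfg.genes_path), ("pheno", cfg.pheno_path)]:
            manifest["inputs"][key] = {"path": p, "sha256": _sha256(p)}

    # ---- preprocess ---------------------------------------------------
    stage("preprocess")
    expr = quantile_normalize(expr)
    agg = promoter_beta(cpgs, ann)
    meth = agg.matrix
    if agg.dropped_genes:
        log.info("promoter aggregation dropped %d genes with no CpG in window",
                 len(agg.dropped_genes))
    expr = drop_sex_chromosomes(expr, ann)
    meth = drop_sex_chromosomes(meth, ann)
    cio.write_matrix_tsv(meth, emit("meth_gene.tsv"))
    expr_c = center_genes(expr)
    meth_c = center_genes(meth)

    groups = dict(zip(pheno["sample_id"], pheno["subtype"]))
    surv = SurvivalTable.from_phenotype(pheno)

    # ---- train --------------------------------------------------------
    stage("train")
    som_e = train_som(expr_c, SomParams(grid_k=cfg.expr_grid,
                                        epochs=cfg.epochs,
                                        seed=cfg.stage_seed(1)))
    som_m = train_som(meth_c, SomParams(grid_k=cfg.meth_grid,
                                        epochs=cfg.epochs,
                                        seed=cfg.stage_seed(2)))
    som_e.save(os.path.join(out, "som_expr"))
    som_m.save(os.path.join(out, "som_meth"))
    outputs.extend(["som_expr/codebook.tsv", "som_expr/bmu.tsv",
                    "som_expr/params.yaml", "som_meth/codebook.tsv",
                    "som_meth/bmu.tsv", "som_meth/params.yaml"])

    # ---- spots --------------------------------------------------------
    stage("spots")
    spot_sets = {}
    calls_by_layer = {}
    for tag, model in [("expr", som_e), ("meth", som_m)]:
        spots = detect_group_spots(model, groups, q=cfg.spot_quantile,
                                   min_size=cfg.spot_min_size,
                                   connectivity=cfg.connectivity)
        spot_sets[tag] = spots
        frame = spots_to_frame(spots)
        _write_map_frame(frame, emit(f"spots_{tag}.tsv"))
        calls = call_spots(spots, model, q=cfg.call_quantile)
        calls_by_layer[tag] = calls
        calls.astype(int).to_csv(emit(f"calls_{tag}.tsv"), sep="\t")
        dist = spot_number_distribution(calls, groups)
        dist.to_csv(emit(f"spot_numbers_{tag}.tsv"), sep="\t")
        edge_rows = []
        for g in sorted(set(groups.values())):
            members = [s for s in calls.columns if groups.get(s) == g]
            if not members:
                continue
            edges, _ = spot_implication(calls, members,
                                        conf_min=cfg.implication_conf_min)
            for e in edges:
                edge_rows.append({"group": g, "spot_a": e.spot_a,
                                  "spot_b": e.spot_b, "conf_ab": e.conf_ab,
                                  "conf_ba": e.conf_ba})
        _write_map_frame(pd.DataFrame(edge_rows,
                                      columns=["group", "spot_a", "spot_b",
                                               "conf_ab", "conf_ba"]),
                         emit(f"implication_edges_{tag}.tsv"))

    # ---- gene sets ----------------------------------------------------
    stage("genesets")
    if cfg.gmt_path is not None:
        sets = cio.read_gmt(cfg.gmt_path)
        manifest["inputs"]["gmt"] = {"path": cfg.gmt_path,
                                     "sha256": _sha256(cfg.gmt_path)}
    else:
        # spot modules double as gene sets when no GMT is supplied
        sets = {f"E_{sp.spot_id}": list(sp.genes)
                for sp in spot_sets["expr"] if sp.genes}
    if sets:
        gsz = gsz_profiles(sets, expr_c)
        gsz.index.name = "set"
        gsz.to_csv(emit("gsz.tsv"), sep="\t", float_format=_FF)

    # ---- phenotype maps -----------------------------------------------
    stage("phenomaps")
    pheno_idx = pheno.set_index("sample_id")
    for tag, model in [("expr", som_e), ("meth", som_m)]:
        pm = prognostic_map(model, surv)
        _write_map_frame(pm.to_frame(), emit(f"phenomap_hr_{tag}.tsv"))
        for stat in ("age", "tlr"):
            cm = covariate_map(model, pheno_idx[stat])
            _write_map_frame(cm.to_frame(), emit(f"phenomap_{stat}_{tag}.tsv"))
        fm = female_difference_map(model, pheno_idx["sex"])
        _write_map_frame(fm.to_frame(), emit(f"phenomap_sex_{tag}.tsv"))

    # ---- integration --------------------------------------------------
    stage("integrate")
    for tag, model in [("expr", som_e), ("meth", som_m)]:
        cov = covariance_map(model, expr, meth)
        _write_map_frame(cov.to_frame(), emit(f"covmap_{tag}.tsv"))
    universe = len(som_e.gene_ids.intersection(som_m.gene_ids))
    net = build_em_network(spot_sets["expr"], spot_sets["meth"], universe,
                           p_max=cfg.em_p_max, r_max=cfg.em_r_max)
    _write_map_frame(net.to_frame() if net.edges else
                     pd.DataFrame(columns=["e_spot", "m_spot", "overlap",
                                           "p", "r"]),
                     emit("em_edges.tsv"))
    net.write_graphml(emit("em_network.graphml"))
    sim = sample_similarity(som_e)
    sim.correlation.loc[sim.order, sim.order].to_csv(
        emit("similarity_expr.tsv"), sep="\t", float_format=_FF)

    # ---- recovery (synthetic runs only) -------------------------------
    if truth is not None:
        rec = module_recovery(truth.module_members, spot_sets["expr"])
        _write_map_frame(rec, emit("recovery.tsv"))
        manifest["module_recovery"] = {
            str(r.module): {"best_spot": r.best_spot,
                            "jaccard": round(float(r.jaccard), 6)}
            for r in rec.itertuples(index=False)}

    manifest["parameters"] = {
        k: v for k, v in dataclasses.asdict(cfg).items()
        if k not in ("simulate",)}
    if cfg.simulate is not None:
        manifest["parameters"]["simulate"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(cfg.simulate).items()}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
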