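"""End-to-end pipeline: lineage prep -> attention encoder (x repeats) ->
GRN selection -> network control -> driver ranking -> gene modules."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .control import candidate_union, solve_mds, solve_mfvs
from .data_io import (GeneGraph, LineageExpression, attach_pseudotime,
                      augment_with_coexpression, read_expression,
                      read_prior_edgelist, read_pseudotime,
                      restrict_to_expressed, write_grn, write_report)
from .drivers import DriverReport, build_report, influence_scores
from .encoder import EncoderConfig, train_encoder
from .grn import EdgeWeightTable, combine_layers, scale_attention, select_edges
from .lineage import bin_pseudotime, compute_logfc
from .rgm import aucell_activity, extract_rgms, write_activity, write_modules_gmt

logger = logging.getLogger("celldriver")


@dataclass
class RunConfig:
    seed: int = 0
    repeats: int = 20              # encoder restarts averaged into the GRN
    aggregate: str = "weights"     # "weights" | "none"
    # lineage prep
    k_states: int = 4
    fdr_cutoff: float = 0.01
    # prior augmentation
    use_coexpression: bool = True
    coexpression_top_frac: float = 0.01
    coexpression_rho_min: float = 0.6
    # encoder
    hidden_dim: int = 128
    out_dim: int = 64
    heads: int = 4
    tau: float = 0.25
    epochs: int = 350
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    use_de_encoding: bool = True
    resample_corruption: bool = True
    # GRN selection
    mu: float = 0.5
    k_d: int = 8
    # driver ranking
    lam: float = 0.8
    top_n: int = 100
    # control
    time_limit: float = 600.0
    # modules
    aucell_top_frac: float = 0.05
    min_module_size: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def encoder_config(self, seed: int) -> EncoderConfig:
        return EncoderConfig(hidden_dim=self.hidden_dim, out_dim=self.out_dim,
                             heads=self.heads, tau=self.tau, epochs=self.epochs,
                             learning_rate=self.learning_rate,
                             weight_decay=self.weight_decay, seed=seed,
                             use_de_encoding=self.use_de_encoding,
                             resample_corruption=self.resample_corruption)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    graph: GeneGraph
    diffexp: object
    weights: EdgeWeightTable
    grn: object
    report: DriverReport
    modules: list
    activity: object
    manifest: dict = field(default_factory=dict)


def run_analysis(prior: GeneGraph, expr: LineageExpression,
                 cfg: RunConfig) -> PipelineResult:
    """Run the full method on in-memory inputs."""
    graph = restrict_to_expressed(prior, expr)
    if cfg.use_coexpression:
        graph = augment_with_coexpression(graph, expr,
                                          top_frac=cfg.coexpression_top_frac,
                                          rho_min=cfg.coexpression_rho_min)
    expr = bin_pseudotime(expr, cfg.k_states)
    de = compute_logfc(expr, fdr_cutoff=cfg.fdr_cutoff)

    n_runs = cfg.repeats if cfg.aggregate == "weights" else 1
    if cfg.aggregate not in ("weights", "none"):
        raise ValueError("aggregate must be 'weights' or 'none'")
    if cfg.aggregate == "none" and cfg.repeats > 1:
        logger.warning("aggregate='none': only the first repeat builds the GRN")
    tables = []
    for r in range(n_runs):
        enc_cfg = cfg.encoder_config(seed=cfg.seed + r)
        _emb, att, _enc = train_encoder(graph, expr, de, enc_cfg)
        tables.append(combine_layers(scale_attention(att, graph), mu=cfg.mu))
    weights = _average_tables(tables)

    grn = select_edges(weights, graph, k_d=cfg.k_d)
    mfvs_sol = solve_mfvs(grn, time_limit=cfg.time_limit)
    mds_sol = solve_mds(grn, time_limit=cfg.time_limit)
    scores = influence_scores(weights, grn, lam=cfg.lam)
    report = build_report(mfvs_sol, mds_sol, scores, grn, top_n=cfg.top_n)
    report.extras["solver"] = {
        "mfvs": {"objective": mfvs_sol.objective, "optimal": mfvs_sol.optimal},
        "mds": {"objective": mds_sol.objective, "optimal": mds_sol.optimal},
    }
    modules = extract_rgms(grn, report.drivers, de, expr,
                           min_size=cfg.min_module_size)
    activity = aucell_activity(expr, modules, top_frac=cfg.aucell_top_frac,
                               seed=cfg.seed)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "repeats": n_runs,
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "n_genes": graph.n_nodes,
        "n_prior_edges": graph.n_edges,
        "n_grn_edges": grn.n_edges,
    }
    return PipelineResult(graph=graph, diffexp=de, weights=weights, grn=grn,
                          report=report, modules=modules, activity=activity,
                          manifest=manifest)


def _average_tables(tables: list[EdgeWeightTable]) -> EdgeWeightTable:
    if len(tables) == 1:
        return tables[0]
    out = tables[0]
    for attr in ("beta_in", "beta_out", "beta_combined"):
        setattr(out, attr,
                np.mean([getattr(t, attr) for t in tables], axis=0))
    for li in out.layers:
        for key in out.layers[li]:
            out.layers[li][key] = np.mean(
                [t.layers[li][key] for t in tables], axis=0)
    return out


def run_pipeline(prior_path, expression_path, pseudotime_path, cfg: RunConfig,
                 out_dir) -> PipelineResult:
    """File-based front end: read inputs, run, write all artifacts."""
    for p in (prior_path, expression_path, pseudotime_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    prior = read_prior_edgelist(prior_path)
    expr = read_expression(expression_path)
    expr = attach_pseudotime(expr, read_pseudotime(pseudotime_path))
    result = run_analysis(prior, expr, cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grn(result.grn, out / "grn.tsv")
    report = result.report.to_dict()
    report["influence_scores"] = result.report.influence.as_frame().to_dict("records")
    write_report(report, out / "driver_report.json")
    result.report.influence.as_frame().assign(
        is_candidate=lambda df: df.gene.isin(
            result.report.candidates_mfvs | result.report.candidates_mds),
        is_driver=lambda df: df.gene.isin(set(result.report.drivers)),
    ).to_csv(out / "influence.tsv", sep="\t", index=False)
    write_modules_gmt(result.modules, out / "modules.gmt")
    write_activity(result.activity, out / "activity.tsv")
    write_report(result.manifest, out / "manifest.json")
    return result
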