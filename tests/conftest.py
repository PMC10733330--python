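"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import celldriver as cd
from celldriver.drivers import build_report
from celldriver.grn import combine_layers, scale_attention, select_edges


@pytest.fixture(scope="session")
def tiny():
    return cd.tiny_worked_example()


@pytest.fixture(scope="session")
def tiny_trained(tiny):
    """Short training run on the 12-gene worked example."""
    graph = cd.restrict_to_expressed(tiny.prior, tiny.expression)
    expr = cd.bin_pseudotime(tiny.expression, 4)
    de = cd.compute_logfc(expr)
    emb, att, enc = cd.train_encoder(
        graph, expr, de, cd.EncoderConfig(epochs=30, seed=3))
    return {"graph": graph, "expr": expr, "de": de,
            "embeddings": emb, "attention": att, "encoding": enc}


@pytest.fixture(scope="session")
def default_run():
    """One scaled-down end-to-end run on the default planted scenario,
    shared by the GRN, driver, and module tests."""
    sc = cd.default_scenario(seed=11)
    graph = cd.restrict_to_expressed(sc.prior, sc.expression)
    graph = cd.augment_with_coexpression(graph, sc.expression)
    expr = cd.bin_pseudotime(sc.expression, 4)
    de = cd.compute_logfc(expr)
    emb, att, enc = cd.train_encoder(
        graph, expr, de, cd.EncoderConfig(epochs=50, seed=11))
    table = combine_layers(scale_attention(att, graph), mu=0.5)
    grn = select_edges(table, graph, k_d=8)
    mfvs_sol = cd.solve_mfvs(grn, time_limit=10)
    mds_sol = cd.solve_mds(grn, time_limit=10)
    scores = cd.influence_scores(table, grn, lam=0.8)
    report = build_report(mfvs_sol, mds_sol, scores, grn)
    modules = cd.extract_rgms(grn, report.drivers, de, expr)
    activity = cd.aucell_activity(expr, modules, seed=11)
    return {"scenario": sc, "graph": graph, "expr": expr, "de": de,
            "attention": att, "encoding": enc, "table": table, "grn": grn,
            "mfvs": mfvs_sol, "mds": mds_sol, "scores": scores,
            "report": report, "modules": modules, "activity": activity}


def quick_pipeline(scenario, seed, epochs=50, time_limit=10.0):
    """Scaled-down pipeline used by the multi-seed tests."""
    cfg = cd.RunConfig(seed=seed, repeats=1, epochs=epochs,
                       time_limit=time_limit)
    return cd.run_analysis(scenario.prior, scenario.expression, cfg)
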