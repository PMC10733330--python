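"""Influence-score ranking of driver-gene candidates and network
controllability reporting.

A gene's influence is the log-transformed sum of the degree-scaled
attention its GRN neighbors pay to it: S_in collects the out-channel
weights of incoming edges (how strongly its regulators' messages select
it as a target), S_out the in-channel weights of outgoing edges (how
strongly its targets select it as a regulator).  The final score
S = lambda * S_out + (1 - lambda) * S_in leans toward S_out because master
regulators typically have large out-degrees.  The driver regulators are the
top-ranked genes intersected with the MFVS/MDS candidate union.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import ControlSolution
from .grn import EdgeWeightTable, LineageGRN

logger = logging.getLogger("celldriver")


@dataclass
class InfluenceScores:
    genes: list[str]
    s_in: np.ndarray
    s_out: np.ndarray
    s: np.ndarray
    lam: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "S_in": self.s_in,
                             "S_out": self.s_out, "S": self.s})

    def rank(self) -> list[str]:
        """Genes by descending S; ties break lexicographically."""
        order = sorted(range(len(self.genes)),
                       key=lambda k: (-self.s[k], self.genes[k]))
        return [self.genes[k] for k in order]


@dataclass
class DriverReport:
    candidates_mfvs: set[str]
    candidates_mds: set[str]
    influence: InfluenceScores
    drivers: list[str]
    controllability_mfvs: float
    controllability_mds: float
    jaccard: float
    coverage: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidates_mfvs": sorted(self.candidates_mfvs),
            "candidates_mds": sorted(self.candidates_mds),
            "drivers": list(self.drivers),
            "metrics": {
                "controllability_score_mfvs": self.controllability_mfvs,
                "controllability_score_mds": self.controllability_mds,
                "jaccard": self.jaccard,
                "coverage": self.coverage,
            },
            **self.extras,
        }


def influence_scores(table: EdgeWeightTable, grn: LineageGRN,
                     lam: float = 0.8) -> InfluenceScores:
    """S_i^in = ln(1 + sum over GRN predecessors j of beta_out(j->i));
    S_i^out = ln(1 + sum over GRN successors j of beta_in(i->j));
    S = lam * S_out + (1 - lam) * S_in.  Sums run over selected GRN edges
    only, using the layer-combined per-channel weights."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if table.beta_in is None or table.beta_out is None:
        raise ValueError("combine_layers must run before influence scoring")
    # map GRN edges back to prior-edge indices of the weight table
    prior_index = {(i, j): k for k, (i, j) in enumerate(map(tuple, table.graph.edges))}
    n = grn.n_nodes
    sum_in = np.zeros(n)    # incoming beta_out, per target
    sum_out = np.zeros(n)   # outgoing beta_in, per source
    for i, j in map(tuple, grn.edges):
        k = prior_index[(i, j)]
        sum_in[j] += table.beta_out[k]
        sum_out[i] += table.beta_in[k]
    s_in = np.log1p(sum_in)
    s_out = np.log1p(sum_out)
    return InfluenceScores(genes=list(grn.nodes), s_in=s_in, s_out=s_out,
                           s=lam * s_out + (1 - lam) * s_in, lam=lam)


def select_drivers(scores: InfluenceScores, candidates: set[str],
                   top_n: int = 100) -> list[str]:
    """Intersect the top_n genes by influence with the control-theoretic
    candidate set; return in descending-score order."""
    top = scores.rank()[:top_n]
    drivers = [g for g in top if g in candidates]
    if not drivers:
        logger.warning("no overlap between top-%d influence genes and candidates", top_n)
    return drivers


def controllability_metrics(mfvs: set[str], mds: set[str], drivers: list[str],
                            all_genes: set[str]) -> tuple[float, float, float, float]:
    """Controllability score 1 - |D_x|/|V| per method, Jaccard index of the
    two driver sets, and coverage |R| / |D_MFVS union D_MDS|."""
    if not (mfvs <= all_genes and mds <= all_genes):
        raise ValueError("driver sets must be subsets of the gene universe")
    nv = len(all_genes)
    score_mfvs = 1.0 - len(mfvs) / nv
    score_mds = 1.0 - len(mds) / nv
    union = mfvs | mds
    if not union:
        logger.warning("empty candidate union; Jaccard and coverage undefined")
        return score_mfvs, score_mds, math.nan, math.nan
    jaccard = len(mfvs & mds) / len(union)
    coverage = len(set(drivers)) / len(union)
    return score_mfvs, score_mds, jaccard, coverage


def build_report(mfvs_sol: ControlSolution, mds_sol: ControlSolution,
                 scores: InfluenceScores, grn: LineageGRN,
                 top_n: int = 100) -> DriverReport:
    candidates = set(mfvs_sol.driver_set) | set(mds_sol.driver_set)
    drivers = select_drivers(scores, candidates, top_n=top_n)
    c_mfvs, c_mds, jac, cov = controllability_metrics(
        set(mfvs_sol.driver_set), set(mds_sol.driver_set), drivers,
        set(grn.nodes))
    return DriverReport(candidates_mfvs=set(mfvs_sol.driver_set),
                        candidates_mds=set(mds_sol.driver_set),
                        influence=scores, drivers=drivers,
                        controllability_mfvs=c_mfvs,
                        controllability_mds=c_mds,
                        jaccard=jac, coverage=cov)
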