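"""Scoring a weighted edge ranking against a ground-truth network.

AUPRC follows the step (precision-recall) integration convention; EPR
(early precision ratio) is the precision among the top-k predicted edges
(k = number of true edges) relative to the truth density, so a random
predictor scores about 1.  The candidate universe is all ordered gene pairs
over the shared gene set, self-pairs excluded; unranked pairs score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score


@dataclass
class GroundTruthNet:
    pairs: set[tuple[str, str]]
    universe: set[str]

    def __post_init__(self):
        for s, t in self.pairs:
            if s not in self.universe or t not in self.universe:
                raise ValueError(f"truth pair ({s}, {t}) outside gene universe")


def _shared_candidates(ranking: dict[tuple[str, str], float],
                       truth: GroundTruthNet):
    pred_genes = {g for pair in ranking for g in pair}
    genes = sorted(pred_genes & truth.universe)
    if not genes:
        raise ValueError("no shared genes between prediction and truth")
    truth_pairs = {(s, t) for s, t in truth.pairs if s in set(genes) and t in set(genes)}
    if not truth_pairs:
        raise ValueError("no ground-truth edges over the shared gene set")
    y_true, y_score = [], []
    for s in genes:
        for t in genes:
            if s == t:
                continue
            y_true.append((s, t) in truth_pairs)
            y_score.append(ranking.get((s, t), 0.0))
    return np.asarray(y_true, dtype=bool), np.asarray(y_score, dtype=float), truth_pairs


def auprc(ranking: dict[tuple[str, str], float], truth: GroundTruthNet) -> float:
    """Area under the precision-recall curve (step integration)."""
    y_true, y_score, _ = _shared_candidates(ranking, truth)
    return float(average_precision_score(y_true, y_score))


def epr(ranking: dict[tuple[str, str], float], truth: GroundTruthNet) -> float:
    """Early precision ratio: precision@k over truth density, k = |truth|."""
    y_true, y_score, truth_pairs = _shared_candidates(ranking, truth)
    k = len(truth_pairs)
    order = np.argsort(-y_score, kind="stable")
    top = order[:k]
    precision = float(y_true[top].mean())
    density = k / len(y_true)
    return precision / density


def grn_ranking(grn) -> dict[tuple[str, str], float]:
    """LineageGRN -> {(source, target): weight} mapping for scoring."""
    return {(grn.nodes[i], grn.nodes[j]): float(w)
            for (i, j), w in zip(grn.edges, grn.weights)}


def topology_report(grn) -> dict:
    """Node/edge counts, log-log degree-distribution slope and R^2, and the
    average clustering coefficient of the undirected projection."""
    g = nx.DiGraph()
    g.add_nodes_from(grn.nodes)
    g.add_edges_from((grn.nodes[i], grn.nodes[j]) for i, j in grn.edges)
    if g.number_of_nodes() < 10:
        raise ValueError("topology report needs >= 10 nodes")
    degrees = np.array([d for _, d in g.degree()])
    slope, r2 = _powerlaw_fit(degrees)
    und = g.to_undirected()
    und.remove_edges_from(nx.selfloop_edges(und))
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "degree_slope": slope,
        "degree_fit_r2": r2,
        "avg_clustering": float(nx.average_clustering(und)),
    }


def _powerlaw_fit(degrees: np.ndarray) -> tuple[float, float]:
    """Least squares on binned log k vs log P(k); NaN when the degree
    support is degenerate (< 3 distinct positive degrees)."""
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        return math.nan, math.nan
    # logarithmic binning of the empirical degree distribution
    edges = np.unique(np.round(np.logspace(0, np.log10(ks.max() + 1), 12)))
    pk, kc = [], []
    p = counts / counts.sum()
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ks >= lo) & (ks < hi)
        if mask.any():
            width = hi - lo
            pk.append(p[mask].sum() / width)
            kc.append(np.sqrt(lo * max(hi - 1, lo)))
    if len(pk) < 3:
        return math.nan, math.nan
    lx, ly = np.log10(np.asarray(kc)), np.log10(np.asarray(pk))
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return float(slope), r2
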