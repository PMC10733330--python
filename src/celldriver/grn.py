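"""From attention coefficients to the cell-lineage-specific GRN.

Softmax-normalized attention is only comparable within a neighborhood; the
coefficients are therefore rescaled by the center node's degree (in-channel:
the target's in-degree; out-channel: the source's out-degree), averaged over
the two channels, combined across the two layers with weight mu, and the
top k_d * N edges by combined weight form the lineage GRN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GeneGraph
from .encoder import AttentionRecord


@dataclass
class EdgeWeightTable:
    """Per prior edge, degree-scaled attention weights.

    Arrays are length E in the graph's edge order.  ``layers`` maps layer
    index -> dict with keys 'in', 'out', 'beta'; ``beta_in`` / ``beta_out``
    / ``beta_combined`` are the mu-combined cross-layer versions.
    """

    graph: GeneGraph
    layers: dict[int, dict[str, np.ndarray]]
    mu: float | None = None
    beta_in: np.ndarray | None = None
    beta_out: np.ndarray | None = None
    beta_combined: np.ndarray | None = None


@dataclass
class LineageGRN:
    """Selected, weighted, directed lineage-specific network."""

    nodes: list[str]
    edges: np.ndarray      # (E_sel, 2) indices into nodes
    weights: np.ndarray    # (E_sel,) combined beta
    origin: list[str]
    k_d: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def iter_edges(self):
        for (i, j), w, o in zip(self.edges, self.weights, self.origin):
            yield self.nodes[i], self.nodes[j], float(w), o

    def edge_set(self) -> set[tuple[str, str]]:
        return {(self.nodes[i], self.nodes[j]) for i, j in self.edges}

    def successors(self, gene: str) -> set[str]:
        g = self.nodes.index(gene)
        return {self.nodes[j] for i, j in self.edges if i == g}

    def predecessors(self, gene: str) -> set[str]:
        g = self.nodes.index(gene)
        return {self.nodes[i] for i, j in self.edges if j == g}


def scale_attention(att: AttentionRecord, graph: GeneGraph) -> EdgeWeightTable:
    """Scale head-averaged attention by the center's degree, per layer.

    For prior edge i -> j: the in-channel coefficient (center j attending to
    its regulator i) is multiplied by indegree(j); the out-channel
    coefficient (center i attending to its target j) by outdegree(i); beta
    is the mean of the two.
    """
    indeg = graph.in_degree().astype(float)
    outdeg = graph.out_degree().astype(float)
    e = graph.edges
    n_e = len(e)
    layers: dict[int, dict[str, np.ndarray]] = {}
    layer_ids = sorted({li for (li, _) in att.alpha})
    for li in layer_ids:
        a_in = att.alpha[li, "in"][:n_e].mean(axis=1)    # heads averaged
        a_out = att.alpha[li, "out"][:n_e].mean(axis=1)
        b_in = a_in * indeg[e[:, 1]]
        b_out = a_out * outdeg[e[:, 0]]
        layers[li] = {"in": b_in, "out": b_out, "beta": 0.5 * (b_in + b_out)}
    return EdgeWeightTable(graph=graph, layers=layers)


def degree_conservation_residual(att: AttentionRecord, graph: GeneGraph) -> float:
    """Max |sum of degree-scaled coefficients over a neighborhood+self -
    center degree| across layers, directions, heads (softmax rows sum to 1,
    so the scaled coefficients must conserve the degree)."""
    indeg = graph.in_degree().astype(float)
    outdeg = graph.out_degree().astype(float)
    worst = 0.0
    for (li, direction), a in att.alpha.items():
        cen = att.center[direction]
        deg = indeg if direction == "in" else outdeg
        for k in range(a.shape[1]):
            scaled = a[:, k] * deg[cen]
            sums = np.zeros(att.n_nodes)
            np.add.at(sums, cen, scaled)
            worst = max(worst, float(np.abs(sums - deg).max()))
    return worst


def combine_layers(table: EdgeWeightTable, mu: float = 0.5) -> EdgeWeightTable:
    """beta_combined = mu * beta(layer 1) + (1 - mu) * beta(layer 2);
    the per-channel betas are combined the same way (used by the influence
    scores)."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    l1, l2 = table.layers[1], table.layers[2]
    table.mu = mu
    table.beta_in = mu * l1["in"] + (1 - mu) * l2["in"]
    table.beta_out = mu * l1["out"] + (1 - mu) * l2["out"]
    table.beta_combined = mu * l1["beta"] + (1 - mu) * l2["beta"]
    return table


def select_edges(table: EdgeWeightTable, graph: GeneGraph, k_d: int = 8) -> LineageGRN:
    """Keep the top min(k_d * N, E) prior edges by combined weight; ties at
    the cutoff break by (source symbol, target symbol) for determinism."""
    if k_d < 1:
        raise ValueError("k_d must be >= 1")
    if table.beta_combined is None:
        raise ValueError("combine_layers must run before edge selection")
    w = table.beta_combined
    e = graph.edges
    keys = [(-w[k], graph.nodes[e[k, 0]], graph.nodes[e[k, 1]]) for k in range(len(e))]
    order = sorted(range(len(e)), key=lambda k: keys[k])
    n_keep = min(k_d * graph.n_nodes, len(e))
    kept = sorted(order[:n_keep])
    return LineageGRN(nodes=list(graph.nodes),
                      edges=e[kept].copy(),
                      weights=w[kept].copy(),
                      origin=[graph.edge_origin[k] for k in kept],
                      k_d=k_d)
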