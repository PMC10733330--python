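"""Driver-gene candidates by network control: minimum feedback vertex set
(MFVS) and minimum dominating set (MDS) on the lineage GRN.

Under mild decay conditions, steering the feedback vertex set plus all
source nodes of a nonlinear regulatory network is sufficient to move the
system between its attractors; the dominating-set view instead requires
every gene to be directly regulated by a controlled gene.  Both are NP-hard
0-1 integer programs, shrunk first by solution-preserving graph
reductions and then solved exactly with a MILP back end (HiGHS via SciPy).
Brute-force oracles for small graphs are included for verification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

logger = logging.getLogger("celldriver")


@dataclass
class ControlSolution:
    method: str                  # "MFVS" | "MDS"
    driver_set: set[str]
    objective: int
    optimal: bool
    solver_status: str
    fvs_part: set[str] = field(default_factory=set)  # MFVS only: cycle-breaking part


def _digraph(grn) -> nx.DiGraph:
    """Unweighted topology of a LineageGRN (or pass a DiGraph through)."""
    if isinstance(grn, nx.DiGraph):
        return grn
    g = nx.DiGraph()
    g.add_nodes_from(grn.nodes)
    g.add_edges_from((grn.nodes[i], grn.nodes[j]) for i, j in grn.edges)
    return g


# ---------------------------------------------------------------------------
# MILP back end (thin solver-agnostic wrapper around scipy/HiGHS)
# ---------------------------------------------------------------------------

def _solve_binary_program(n_binary: int, n_integer: int, cost: np.ndarray,
                          a_rows, a_lb, int_lb, int_ub, time_limit: float,
                          integer_z: bool = True):
    """min cost @ x over x = [y (binary), z (in bounds)] s.t. A x >= lb."""
    n = n_binary + n_integer
    lb = np.concatenate([np.zeros(n_binary), np.full(n_integer, int_lb)])
    ub = np.concatenate([np.ones(n_binary), np.full(n_integer, int_ub)])
    constraints = []
    if a_rows:
        a = csr_matrix(np.asarray(a_rows, dtype=float))
        constraints.append(LinearConstraint(a, lb=np.asarray(a_lb, dtype=float),
                                            ub=np.inf))
    integrality = np.concatenate([np.ones(n_binary),
                                  np.full(n_integer, 1.0 if integer_z else 0.0)])
    res = milp(c=cost, constraints=constraints,
               integrality=integrality,
               bounds=Bounds(lb, ub),
               options={"time_limit": time_limit})
    return res


# ---------------------------------------------------------------------------
# MFVS: contraction + ILP
# ---------------------------------------------------------------------------

def contract_for_mfvs(grn):
    """Iterated solution-preserving reductions for the feedback vertex set.

    Rules, applied to fixpoint: drop nodes with in- or out-degree 0 (they
    lie on no cycle); a self-loop node must be in the FVS (forced-in, then
    removed); a node with a single predecessor (resp. successor) is merged
    into that neighbor, since every cycle through it passes the neighbor.

    Returns (reduced DiGraph, forced_in set, excluded set, mapping) where
    mapping sends each surviving reduced node to its original label (labels
    are preserved by the merges, so this is the identity on survivors).
    """
    g = _digraph(grn).copy()
    forced: set = set()
    excluded: set = set()
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v not in g:
                continue
            if g.has_edge(v, v):
                forced.add(v)
                g.remove_node(v)
                changed = True
                continue
            if g.in_degree(v) == 0 or g.out_degree(v) == 0:
                excluded.add(v)
                g.remove_node(v)
                changed = True
                continue
            if g.in_degree(v) == 1:
                u = next(iter(g.predecessors(v)))
                _merge(g, v, into=u, redirect="out")
                changed = True
                continue
            if g.out_degree(v) == 1:
                w = next(iter(g.successors(v)))
                _merge(g, v, into=w, redirect="in")
                changed = True
    mapping = {v: v for v in g.nodes}
    return g, forced, excluded, mapping


def _merge(g: nx.DiGraph, v, into, redirect: str):
    """Remove v, rerouting its out-edges (redirect='out') or in-edges
    (redirect='in') through `into`; a v<->into 2-cycle becomes a self-loop."""
    if redirect == "out":
        for w in list(g.successors(v)):
            g.add_edge(into, w if w != v else into)
    else:
        for u in list(g.predecessors(v)):
            g.add_edge(u if u != v else into, into)
    g.remove_node(v)


def _mfvs_ilp(g: nx.DiGraph, time_limit: float):
    """Ordering-based 0-1 ILP: min sum y_i subject to
    z_i - z_j + N y_i >= 1 for every edge i->j, z in [1, N].

    The problem decomposes over strongly connected components (edges between
    components lie on no cycle), so each nontrivial component is solved as
    its own program.  The ordering variables z are relaxed to continuous:
    any acyclic graph admits real-valued ordering potentials, so the optimum
    is unchanged while the search tree only branches on y."""
    chosen: set = set()
    optimal = True
    messages = []
    for comp in nx.strongly_connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        nodes = sorted(comp, key=str)
        index = {v: k for k, v in enumerate(nodes)}
        n = len(nodes)
        rows, lbs = [], []
        for u, v in sub.edges:
            if u == v:
                continue
            row = np.zeros(2 * n)
            row[index[u]] = n            # y_u
            row[n + index[u]] = 1.0      # z_u
            row[n + index[v]] = -1.0     # z_v
            rows.append(row)
            lbs.append(1.0)
        if not rows:
            continue
        cost = np.concatenate([np.ones(n), np.zeros(n)])
        res = _solve_binary_program(n, n, cost, rows, lbs, 1, n, time_limit,
                                    integer_z=False)
        if res.x is None:
            raise RuntimeError(f"MILP back end returned no solution: {res.message}")
        y = np.round(res.x[:n]).astype(int)
        chosen |= {nodes[k] for k in range(n) if y[k] == 1}
        optimal &= bool(res.status == 0)
        messages.append(str(res.message))
    return chosen, optimal, "; ".join(dict.fromkeys(messages)) or "no cycles"


def solve_mfvs(grn, time_limit: float = 600.0, use_reductions: bool = True) -> ControlSolution:
    """MFVS-based driver genes: the minimum cycle-breaking set plus every
    source node (in-degree 0) of the GRN."""
    g = _digraph(grn)
    if use_reductions:
        reduced, forced, _excl, mapping = contract_for_mfvs(g)
        chosen, optimal, status = _mfvs_ilp(reduced, time_limit)
        fvs = forced | {mapping[v] for v in chosen}
    else:
        selfloops = {v for v in g.nodes if g.has_edge(v, v)}
        core = g.copy()
        core.remove_nodes_from(selfloops)
        chosen, optimal, status = _mfvs_ilp(core, time_limit)
        fvs = selfloops | chosen
    sources = {v for v in g.nodes if g.in_degree(v) == 0}
    _assert_acyclic_after_removal(g, fvs)
    return ControlSolution(method="MFVS", driver_set=fvs | sources,
                           objective=len(fvs | sources), optimal=optimal,
                           solver_status=str(status), fvs_part=fvs)


def _assert_acyclic_after_removal(g: nx.DiGraph, fvs: set):
    h = g.copy()
    h.remove_nodes_from(fvs)
    if not nx.is_directed_acyclic_graph(h):
        raise AssertionError("FVS removal left a directed cycle")


# ---------------------------------------------------------------------------
# MDS: reduction + ILP
# ---------------------------------------------------------------------------

def reduce_for_mds(grn):
    """Solution-preserving preprocessing for the directed dominating set.

    A node with no predecessors can only be covered by itself, so it is
    forced into the set; nodes it points to are covered; a covered node with
    no uncovered successors is useless and removed.  Returns (reduced
    DiGraph, forced_in set, needs_cover set, mapping)."""
    g = _digraph(grn).copy()
    forced: set = set()
    covered: set = set()
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v not in g:
                continue
            if g.in_degree(v) == 0 and v not in covered and v not in forced:
                forced.add(v)
                covered.add(v)
                covered.update(g.successors(v))
                changed = True
        for v in list(g.nodes):
            if v in covered and all(w in covered for w in g.successors(v)) \
                    and v not in forced:
                g.remove_node(v)
                changed = True
            elif v in forced and all(w in covered for w in g.successors(v)):
                g.remove_node(v)
                changed = True
    needs_cover = {v for v in g.nodes if v not in covered}
    mapping = {v: v for v in g.nodes}
    return g, forced, needs_cover, mapping


def _mds_ilp(g: nx.DiGraph, needs_cover, time_limit: float):
    nodes = sorted(g.nodes, key=str)
    if not nodes or not needs_cover:
        return set(), True, "empty"
    index = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    rows, lbs = [], []
    for v in needs_cover:
        row = np.zeros(n)
        row[index[v]] = 1.0
        for u in g.predecessors(v):
            row[index[u]] = 1.0
        rows.append(row)
        lbs.append(1.0)
    res = _solve_binary_program(n, 0, np.ones(n), rows, lbs, 0, 0, time_limit)
    if res.x is None:
        raise RuntimeError(f"MILP back end returned no solution: {res.message}")
    y = np.round(res.x).astype(int)
    return {nodes[k] for k in range(n) if y[k] == 1}, bool(res.status == 0), res.message


def solve_mds(grn, time_limit: float = 600.0, use_reductions: bool = True) -> ControlSolution:
    """Minimum set of genes such that every gene is selected or has a
    selected regulator (each member controls its successor neighbors)."""
    g = _digraph(grn)
    if use_reductions:
        reduced, forced, needs_cover, mapping = reduce_for_mds(g)
        chosen, optimal, status = _mds_ilp(reduced, needs_cover, time_limit)
        mds = forced | {mapping[v] for v in chosen}
    else:
        mds, optimal, status = _mds_ilp(g, set(g.nodes), time_limit)
    _assert_dominating(g, mds)
    return ControlSolution(method="MDS", driver_set=mds, objective=len(mds),
                           optimal=optimal, solver_status=str(status))


def _assert_dominating(g: nx.DiGraph, mds: set):
    for v in g.nodes:
        if v not in mds and not any(u in mds for u in g.predecessors(v)):
            raise AssertionError(f"node {v!r} is not dominated")


def candidate_union(mfvs: ControlSolution, mds: ControlSolution) -> set:
    """Driver-gene candidate set: union of the two control solutions."""
    return set(mfvs.driver_set) | set(mds.driver_set)


# ---------------------------------------------------------------------------
# Exhaustive oracles (small graphs only)
# ---------------------------------------------------------------------------

def brute_force_mfvs(g: nx.DiGraph, max_nodes: int = 16) -> set:
    """Smallest vertex set whose removal leaves the digraph acyclic."""
    nodes = sorted(g.nodes, key=str)
    if len(nodes) > max_nodes:
        raise ValueError("brute force limited to small graphs")
    for size in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            h = g.copy()
            h.remove_nodes_from(subset)
            if nx.is_directed_acyclic_graph(h):
                return set(subset)
    raise RuntimeError("unreachable")


def brute_force_mds(g: nx.DiGraph, max_nodes: int = 16) -> set:
    """Smallest set dominating every node via out-edges."""
    nodes = sorted(g.nodes, key=str)
    if len(nodes) > max_nodes:
        raise ValueError("brute force limited to small graphs")
    succ_mask = {}
    index = {v: k for k, v in enumerate(nodes)}
    for v in nodes:
        m = 1 << index[v]
        for w in g.successors(v):
            m |= 1 << index[w]
        succ_mask[v] = m
    full = (1 << len(nodes)) - 1
    for size in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            m = 0
            for v in subset:
                m |= succ_mask[v]
            if m == full:
                return set(subset)
    raise RuntimeError("unreachable")
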