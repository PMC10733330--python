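"""Input/output and prior-network assembly.

Reads the prior gene-interaction network from an edge list (undirected rows
expanded to both directions), expression matrices from delimited text, MTX
triplets with sidecar name files, or H5AD, and pseudotime tables; augments
the prior with dataset-specific co-expression edges; writes GRNs and reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("celldriver")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneGraph:
    """Directed gene-interaction graph over gene symbols.

    ``edges`` is an (E, 2) integer array of (source index, target index)
    pairs into ``nodes``; self-loops are excluded (self-attention is handled
    separately by the encoder).  ``edge_origin`` tags each edge as coming
    from the curated prior or from co-expression augmentation.
    """

    nodes: list[str]
    edges: np.ndarray  # (E, 2) int
    edge_origin: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if not self.edge_origin:
            self.edge_origin = ["prior"] * len(self.edges)
        self.validate()

    def validate(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate gene symbols in graph nodes")
        if any((not s) or (s != s.strip()) for s in self.nodes):
            raise ValueError("empty or unstripped gene symbol")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= len(self.nodes):
                raise ValueError("edge endpoint outside node range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop present in edge set")
            keys = self.edges[:, 0] * len(self.nodes) + self.edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate edges")
        if len(self.edge_origin) != len(self.edges):
            raise ValueError("edge_origin length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency, A[i, j] = True iff edge i -> j."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = True
        return a

    def in_degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self.edges):
            np.add.at(d, self.edges[:, 1], 1)
        return d

    def out_degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self.edges):
            np.add.at(d, self.edges[:, 0], 1)
        return d

    def edge_set(self) -> set[tuple[str, str]]:
        return {(self.nodes[i], self.nodes[j]) for i, j in self.edges}


@dataclass
class LineageExpression:
    """Cells x genes log-normalized expression for one lineage, with
    per-cell pseudotime and (after binning) developmental state labels."""

    cell_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray          # (M, N) float, finite, >= 0
    pseudotime: np.ndarray | None = None   # (M,) float
    state_labels: np.ndarray | None = None  # (M,) int in 1..K

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self):
        m, n = self.values.shape
        if m != len(self.cell_ids) or n != len(self.gene_symbols):
            raise ValueError("expression matrix shape does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.values.min() < 0:
            raise ValueError("negative expression values")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=np.float64)
            if self.pseudotime.shape != (m,) or not np.all(np.isfinite(self.pseudotime)):
                raise ValueError("pseudotime must be finite and per-cell")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)


# ---------------------------------------------------------------------------
# Prior network ingestion
# ---------------------------------------------------------------------------

def read_prior_edgelist(path, directedness_column: str | None = "directed") -> GeneGraph:
    """Read a prior interaction edge list (TSV: source, target[, directed]).

    Rows flagged undirected (directed == 0) are expanded to both directions;
    duplicates are collapsed; self-loop rows are dropped with a logged count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty edge-list file: {path}")
    if df.shape[1] < 2:
        raise ValueError(f"edge list needs >= 2 columns, got {df.shape[1]}: {path}")
    if df.empty:
        raise ValueError(f"edge-list file has no rows: {path}")

    src_col, tgt_col = df.columns[0], df.columns[1]
    if directedness_column is not None and directedness_column in df.columns:
        dir_raw = df[directedness_column]
    elif df.shape[1] >= 3:
        dir_raw = df[df.columns[2]]
    else:
        dir_raw = pd.Series(["1"] * len(df))

    pairs: set[tuple[str, str]] = set()
    n_self = 0
    for lineno, (s, t, d) in enumerate(zip(df[src_col], df[tgt_col], dir_raw), start=2):
        if not isinstance(s, str) or not isinstance(t, str) or not s.strip() or not t.strip():
            raise ValueError(f"unparsable edge row at line {lineno} of {path}")
        s, t = s.strip(), t.strip()
        d = "1" if pd.isna(d) else str(d).strip()
        if d not in ("0", "1"):
            raise ValueError(f"bad directedness flag {d!r} at line {lineno} of {path}")
        if s == t:
            n_self += 1
            continue
        pairs.add((s, t))
        if d == "0":
            pairs.add((t, s))
    if n_self:
        logger.warning("dropped %d self-loop rows from %s", n_self, path)
    if not pairs:
        raise ValueError(f"no usable edges in {path}")

    nodes = sorted({g for p in pairs for g in p})
    index = {g: i for i, g in enumerate(nodes)}
    edges = np.array(sorted((index[s], index[t]) for s, t in pairs), dtype=np.int64)
    return GeneGraph(nodes=nodes, edges=edges)


def restrict_to_expressed(graph: GeneGraph, expr: LineageExpression) -> GeneGraph:
    """Induced subgraph on genes present in both the graph and the
    expression matrix; node order follows the expression gene order."""
    graph_set = set(graph.nodes)
    nodes = [g for g in expr.gene_symbols if g in graph_set]
    if not nodes:
        raise ValueError("no overlap between graph genes and expressed genes")
    new_index = {g: i for i, g in enumerate(nodes)}
    edges, origin = [], []
    for (i, j), o in zip(graph.edges, graph.edge_origin):
        s, t = graph.nodes[i], graph.nodes[j]
        if s in new_index and t in new_index:
            edges.append((new_index[s], new_index[t]))
            origin.append(o)
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return GeneGraph(nodes=nodes, edges=edges, edge_origin=origin)


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Spearman correlation between columns; constant columns get rho 0."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    sd = ranks.std(axis=0)
    const = sd == 0
    if const.any():
        logger.warning("treating %d constant-expression genes as rho=0", int(const.sum()))
    centered = ranks - ranks.mean(axis=0)
    denom = np.where(const, 1.0, sd * values.shape[0])
    z = centered / denom
    rho = z.T @ z * values.shape[0]
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def augment_with_coexpression(graph: GeneGraph, expr: LineageExpression,
                              top_frac: float = 0.01,
                              rho_min: float = 0.6) -> GeneGraph:
    """Add the top ``top_frac`` of gene pairs by |Spearman rho| (among pairs
    with rho > rho_min) as bidirectional co-expression edges.

    The denominator for the top fraction is the number of unordered pairs
    over the graph's node set; ties at the cutoff are all included; pairs
    already in the prior keep their prior origin.
    """
    if expr.n_cells < 3:
        raise ValueError("co-expression augmentation needs >= 3 cells")
    expr_index = {g: i for i, g in enumerate(expr.gene_symbols)}
    cols = [expr_index[g] for g in graph.nodes]
    if len(cols) != len(graph.nodes):
        raise ValueError("graph contains genes missing from expression")
    rho = spearman_matrix(expr.values[:, cols])

    n = graph.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = rho[iu, ju]
    eligible = vals > rho_min
    n_top = int(round(top_frac * len(iu)))
    chosen = np.zeros(len(iu), dtype=bool)
    if n_top > 0 and eligible.any():
        mag = np.abs(vals)
        elig_idx = np.flatnonzero(eligible)
        if len(elig_idx) <= n_top:
            chosen[elig_idx] = True
        else:
            order = elig_idx[np.argsort(-mag[elig_idx], kind="stable")]
            cutoff = mag[order[n_top - 1]]
            chosen[elig_idx[mag[elig_idx] >= cutoff]] = True  # keep ties

    existing = graph.edge_set()
    new_edges = list(map(tuple, graph.edges))
    new_origin = list(graph.edge_origin)
    for i, j in zip(iu[chosen], ju[chosen]):
        for s, t in ((int(i), int(j)), (int(j), int(i))):
            if (graph.nodes[s], graph.nodes[t]) not in existing:
                new_edges.append((s, t))
                new_origin.append("coexpression")
                existing.add((graph.nodes[s], graph.nodes[t]))
    return GeneGraph(nodes=list(graph.nodes),
                     edges=np.array(new_edges, dtype=np.int64),
                     edge_origin=new_origin)


# ---------------------------------------------------------------------------
# Expression / pseudotime / GRN / report IO
# ---------------------------------------------------------------------------

def read_expression(path) -> LineageExpression:
    """Read cells x genes expression from CSV/TSV, MTX triplet (with
    ``genes.txt``/``cells.txt`` sidecars), or H5AD."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata
        ad = anndata.read_h5ad(path)
        x = ad.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return LineageExpression(cell_ids=[str(c) for c in ad.obs_names],
                                 gene_symbols=[str(g) for g in ad.var_names],
                                 values=np.asarray(x, dtype=np.float64))
    if suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path), dtype=np.float64)
        genes = (path.parent / "genes.txt").read_text().split()
        cells = (path.parent / "cells.txt").read_text().split()
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match {len(cells)} cells x {len(genes)} genes")
        return LineageExpression(cell_ids=cells, gene_symbols=genes, values=mat)
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LineageExpression(cell_ids=[str(c) for c in df.index],
                             gene_symbols=[str(g) for g in df.columns],
                             values=df.to_numpy(dtype=np.float64))


def read_pseudotime(path) -> pd.Series:
    """TSV cell_id<TAB>pseudotime -> Series indexed by cell id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"pseudotime table needs >= 2 columns: {path}")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=np.float64),
                     index=df.iloc[:, 0].astype(str).tolist())


def attach_pseudotime(expr: LineageExpression, pt: pd.Series) -> LineageExpression:
    missing = [c for c in expr.cell_ids if c not in pt.index]
    if missing:
        raise ValueError(f"pseudotime missing for {len(missing)} cells, e.g. {missing[:3]}")
    expr.pseudotime = pt.loc[expr.cell_ids].to_numpy(dtype=np.float64)
    expr.validate()
    return expr


def write_expression(expr: LineageExpression, path):
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_symbols)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",")


def write_grn(grn, path):
    """Write a lineage GRN as TSV: source, target, weight, origin."""
    rows = [{"source": s, "target": t, "weight": w, "origin": o}
            for s, t, w, o in grn.iter_edges()]
    pd.DataFrame(rows, columns=["source", "target", "weight", "origin"]).to_csv(
        path, sep="\t", index=False)


def read_grn_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    if not {"source", "target"}.issubset(df.columns):
        raise ValueError(f"GRN TSV must have source/target columns: {path}")
    return df


def write_report(report: dict, path):
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default,
                                     allow_nan=True) + "\n")
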