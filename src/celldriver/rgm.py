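"""Regulon-like gene modules (RGMs) and per-cell activity scoring.

Each driver regulator yields an out-degree module (its GRN targets) and an
in-degree module (its GRN regulators), filtered to significantly
differentially expressed genes; modules smaller than ten members are not
emitted.  Member signs (activated / repressed) come from the Pearson
correlation of member and regulator expression.  Activity per cell is an
AUCell-style area under the recovery curve of module members within the
top-ranked genes of that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import LineageExpression
from .grn import LineageGRN
from .lineage import DiffExpProfile

logger = logging.getLogger("celldriver")

MIN_MODULE_SIZE = 10


@dataclass
class RegulonModule:
    regulator: str
    kind: str                 # "out_degree" | "in_degree"
    members: list[str]        # excludes the regulator
    signs: dict[str, str]     # member -> "activated" | "repressed"

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        return f"{self.regulator}({'+' if self.kind == 'out_degree' else '-'})"


@dataclass
class ActivityMatrix:
    cell_ids: list[str]
    module_names: list[str]
    values: np.ndarray  # (cells, modules) in [0, 1]


def extract_rgms(grn: LineageGRN, drivers: list[str], de: DiffExpProfile,
                 expr: LineageExpression,
                 min_size: int = MIN_MODULE_SIZE) -> list[RegulonModule]:
    """Build out-/in-degree modules for each driver regulator, keeping only
    significantly differentially expressed members and modules of size >=
    min_size."""
    sig = {g for g, s in zip(de.gene_symbols, de.significant) if s}
    expr_idx = {g: i for i, g in enumerate(expr.gene_symbols)}
    succ: dict[str, set] = {g: set() for g in grn.nodes}
    pred: dict[str, set] = {g: set() for g in grn.nodes}
    for i, j in grn.edges:
        succ[grn.nodes[i]].add(grn.nodes[j])
        pred[grn.nodes[j]].add(grn.nodes[i])

    modules = []
    for reg in drivers:
        if reg not in succ:
            continue
        for kind, neigh in (("out_degree", succ[reg]), ("in_degree", pred[reg])):
            members = sorted((neigh & sig) - {reg})
            if len(members) < min_size:
                continue
            signs = {}
            reg_x = expr.values[:, expr_idx[reg]]
            for m in members:
                mx = expr.values[:, expr_idx[m]]
                if np.ptp(mx) == 0 or np.ptp(reg_x) == 0:
                    logger.warning("zero-variance gene in sign call (%s/%s); "
                                   "defaulting to activated", reg, m)
                    r = 0.0
                else:
                    r = float(np.corrcoef(reg_x, mx)[0, 1])
                signs[m] = "repressed" if r < 0 else "activated"
            modules.append(RegulonModule(regulator=reg, kind=kind,
                                         members=members, signs=signs))
    return modules


def aucell_activity(expr: LineageExpression, modules: list[RegulonModule],
                    top_frac: float = 0.05, seed: int = 0) -> ActivityMatrix:
    """Area under the recovery curve of module members within the top
    ceil(top_frac * N) expression ranks of each cell, normalized by the
    maximum attainable area.  Expression ties are broken by a seeded jitter
    so ranks (and activities) are deterministic given the seed."""
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    n_genes = expr.n_genes
    n_top = int(np.ceil(top_frac * n_genes))
    rng = np.random.default_rng(seed)
    logger.info("AUCell tie-break jitter seed: %d", seed)

    gene_idx = {g: i for i, g in enumerate(expr.gene_symbols)}
    member_idx = [np.array([gene_idx[m] for m in mod.members if m in gene_idx],
                           dtype=np.int64) for mod in modules]

    values = np.zeros((expr.n_cells, len(modules)))
    max_area = {}  # module size -> best attainable area

    for ci in range(expr.n_cells):
        x = expr.values[ci] + rng.uniform(0.0, 1e-9, size=n_genes)
        # rank 0 = highest expression
        rank_of_gene = np.empty(n_genes, dtype=np.int64)
        rank_of_gene[np.argsort(-x, kind="stable")] = np.arange(n_genes)
        for mi, idx in enumerate(member_idx):
            if len(idx) == 0:
                continue
            ranks = np.sort(rank_of_gene[idx])
            ranks = ranks[ranks < n_top]
            # recovery curve R(t) = members with rank < t, t = 1..n_top;
            # area = sum_t R(t) = sum over hit ranks of (n_top - rank)
            area = float(np.sum(n_top - ranks))
            m = len(idx)
            if m not in max_area:
                best = np.arange(min(m, n_top))
                max_area[m] = float(np.sum(n_top - best))
            values[ci, mi] = area / max_area[m]
    return ActivityMatrix(cell_ids=list(expr.cell_ids),
                          module_names=[m.name for m in modules],
                          values=values)


def write_modules_gmt(modules: list[RegulonModule], path):
    """GMT-style text: name, description, tab-separated members."""
    with open(path, "w") as fh:
        for m in modules:
            desc = ",".join(f"{g}:{m.signs[g][0]}" for g in m.members)
            fh.write("\t".join([m.name, desc] + m.members) + "\n")


def write_activity(act: ActivityMatrix, path):
    import pandas as pd
    df = pd.DataFrame(act.values, index=act.cell_ids, columns=act.module_names)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")
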