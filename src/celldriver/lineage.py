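"""Pseudotime binning and differential-expression encoding.

Cells are split into K near-equal developmental states along pseudotime.
For every gene, the magnitude l_j is the mean |log2 fold change| between the
start state and each later state, computed on de-logged values with a
pseudocount; significance is a two-sided Wilcoxon rank-sum test on the
log-normalized values with Benjamini-Hochberg control across genes
(FDR <= 0.01 in at least one start-vs-later comparison).  Non-significant
genes get l_j = 0, so their learned attention scaling falls back to the
shared baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import LineageExpression

logger = logging.getLogger("celldriver")


@dataclass
class DiffExpProfile:
    gene_symbols: list[str]
    l: np.ndarray            # (N,) mean |log2FC| vs start state; 0 if not significant
    significant: np.ndarray  # (N,) bool
    k_states: int

    def __post_init__(self):
        self.l = np.asarray(self.l, dtype=np.float64)
        self.significant = np.asarray(self.significant, dtype=bool)
        if np.any(~np.isfinite(self.l)) or np.any(self.l < 0):
            raise ValueError("l must be finite and >= 0")
        if np.any(self.l[~self.significant] != 0):
            raise ValueError("non-significant genes must have l = 0")


def bin_pseudotime(expr: LineageExpression, k_states: int) -> LineageExpression:
    """Assign state labels 1..K by splitting cells, sorted by
    (pseudotime, cell_id), into K contiguous near-equal groups."""
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if expr.n_cells < k_states:
        raise ValueError("fewer cells than states")
    if expr.pseudotime is None:
        raise ValueError("pseudotime not set")
    if np.all(expr.pseudotime == expr.pseudotime[0]):
        logger.warning("all pseudotimes identical; binning by cell id order")
    order = sorted(range(expr.n_cells),
                   key=lambda i: (expr.pseudotime[i], expr.cell_ids[i]))
    labels = np.empty(expr.n_cells, dtype=np.int64)
    # first (M mod K) states get the extra cell
    sizes = np.full(k_states, expr.n_cells // k_states)
    sizes[: expr.n_cells % k_states] += 1
    pos = 0
    for k, sz in enumerate(sizes, start=1):
        labels[order[pos:pos + sz]] = k
        pos += sz
    expr.state_labels = labels
    return expr


def compute_logfc(expr: LineageExpression, fdr_cutoff: float = 0.01,
                  pseudocount: float = 1.0) -> DiffExpProfile:
    """Differential-expression magnitudes and significance flags.

    Fold changes are taken between per-state means of expm1-transformed
    values (+ pseudocount); significance per start-vs-state comparison is a
    Wilcoxon rank-sum on the log-normalized values, BH-corrected across
    genes within each comparison.
    """
    if expr.state_labels is None:
        raise ValueError("state labels not set; run bin_pseudotime first")
    labels = expr.state_labels
    k_states = int(labels.max())
    linear = np.expm1(expr.values)
    start_mask = labels == 1
    start_mean = linear[start_mask].mean(axis=0)

    abs_lfc = []
    sig_any = np.zeros(expr.n_genes, dtype=bool)
    for k in range(2, k_states + 1):
        mask = labels == k
        if mask.sum() < 2 or start_mask.sum() < 2:
            logger.warning("state %d comparison skipped (<2 cells)", k)
            continue
        mean_k = linear[mask].mean(axis=0)
        lfc = np.log2((mean_k + pseudocount) / (start_mean + pseudocount))
        abs_lfc.append(np.abs(lfc))
        a, b = expr.values[start_mask], expr.values[mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = stats.mannwhitneyu(a, b, axis=0,
                                       alternative="two-sided").pvalue
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # all-tied columns
        qvals = stats.false_discovery_control(pvals, method="bh")
        sig_any |= qvals <= fdr_cutoff

    if not abs_lfc:
        raise ValueError("no valid start-vs-state comparison")
    l = np.mean(abs_lfc, axis=0)
    l[~sig_any] = 0.0
    return DiffExpProfile(gene_symbols=list(expr.gene_symbols), l=l,
                          significant=sig_any, k_states=k_states)
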