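"""Directional graph-attention encoder trained by contrastive
mutual-information maximization.

Architecture: two layers; in each layer the prior network is split into an
in-coming channel (each gene aggregates from its regulators) and an
out-going channel (from its targets).  Per channel, multi-head attention
with a cosine score |cos(W_a h_i, W_b h_j)| scaled by a learnable sigmoid
encoding D_j of the neighbor's differential-expression magnitude, sharpened
by a temperature-tau softmax over each neighborhood plus self.  Batch
normalization precedes each layer and a position-wise feedforward (GELU)
follows it; the two channel outputs are concatenated.  Training maximizes
mutual information between gene embeddings and a global summary vector
(deep-graph-infomax objective) with feature-shuffled negatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor, backward, concat, segment_softmax, spmm
from .data_io import GeneGraph, LineageExpression
from .lineage import DiffExpProfile

logger = logging.getLogger("celldriver")

_NORM_EPS = 1e-24  # inside sqrt of projection norms; zero vectors score 0


# ---------------------------------------------------------------------------
# Config and result containers
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    hidden_dim: int = 128     # per-direction width of layer 1 (split across heads)
    out_dim: int = 64         # total embedding width (both directions)
    heads: int = 4
    tau: float = 0.25         # softmax temperature; < 1 sharpens attention
    epochs: int = 350
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    seed: int = 0
    use_de_encoding: bool = True   # ablation switch: False freezes D_j = 0.5
    resample_corruption: bool = True  # fresh feature shuffle each epoch

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.heads < 1 or self.hidden_dim < 1 or self.out_dim < 1:
            raise ValueError("dims and heads must be >= 1")
        if self.hidden_dim % self.heads or (self.out_dim // 2) % self.heads:
            raise ValueError("hidden_dim and out_dim/2 must divide by heads")


@dataclass
class AttentionRecord:
    """Normalized attention over (center, neighbor) pairs.

    Pair arrays per direction have length E + N: the first E entries follow
    the graph's edge order (in-channel center = target, out-channel center =
    source), the last N are self pairs.  ``alpha[(layer, direction)]`` is a
    (E + N, heads) array.
    """

    n_nodes: int
    n_edges: int
    center: dict[str, np.ndarray]
    neighbor: dict[str, np.ndarray]
    alpha: dict[tuple[int, str], np.ndarray]

    def check_normalized(self, tol: float = 1e-6) -> float:
        """Max deviation of any neighborhood sum from 1."""
        worst = 0.0
        for (_, direction), a in self.alpha.items():
            cen = self.center[direction]
            for k in range(a.shape[1]):
                sums = np.zeros(self.n_nodes)
                np.add.at(sums, cen, a[:, k])
                worst = max(worst, float(np.abs(sums - 1.0).max()))
            if a.min() < -tol or a.max() > 1 + tol:
                raise ValueError("attention coefficient outside [0, 1]")
        return worst


@dataclass
class DEEncoding:
    c: float
    d: float
    D: np.ndarray  # per-gene sigmoid(c*l + d), in (0, 1)


@dataclass
class GeneEmbeddings:
    genes: list[str]
    values: np.ndarray  # (N, out_dim)


# ---------------------------------------------------------------------------
# Reference (plain NumPy) forms of the core operations
# ---------------------------------------------------------------------------

def de_scalar(l: np.ndarray, c: float, d: float) -> np.ndarray:
    """D_j = sigmoid(c * l_j + d), in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-(c * np.asarray(l, dtype=float) + d)))


def attention_score(hi: np.ndarray, hj: np.ndarray, Wa: np.ndarray,
                    Wb: np.ndarray, Dj: float) -> float:
    """D_j * |cos(W_a h_i, W_b h_j)|; zero-norm projections score 0."""
    a = np.asarray(Wa) @ np.asarray(hi)
    b = np.asarray(Wb) @ np.asarray(hj)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-norm projection in attention score; returning 0")
        return 0.0
    return float(Dj * abs(a @ b / (na * nb)))


def normalize_attention(scores: np.ndarray, tau: float) -> np.ndarray:
    """Temperature softmax over one neighborhood (self included by caller)."""
    s = np.asarray(scores, dtype=float) / tau
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def corrupt_features(h: np.ndarray, seed: int) -> np.ndarray:
    """Shuffle gene feature rows (topology untouched elsewhere)."""
    if h.shape[0] < 2:
        raise ValueError("need at least 2 genes to corrupt")
    rng = np.random.default_rng(seed)
    return h[rng.permutation(h.shape[0])]


def dgi_loss_reference(h_real: np.ndarray, h_corrupt: np.ndarray,
                       summary: np.ndarray, M: np.ndarray) -> float:
    """Binary cross-entropy form of the infomax objective (to minimize)."""
    pos = h_real @ M @ summary
    neg = h_corrupt @ M @ summary
    softplus = lambda x: np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    n = h_real.shape[0]
    return float((softplus(-pos).sum() + softplus(neg).sum()) / (2.0 * n))


# ---------------------------------------------------------------------------
# Trainable model
# ---------------------------------------------------------------------------

class _Layer:
    """One GNN block: batch-norm -> two-channel multi-head attention -> FFN.

    The K per-head projections are stored stacked column-wise, so one
    matmul projects all heads at once."""

    def __init__(self, rng, in_dim: int, out_dim_total: int, heads: int):
        self.heads = heads
        self.head_dim = out_dim_total // 2 // heads
        self.gamma = Tensor(np.ones(in_dim), requires_grad=True)
        self.beta = Tensor(np.zeros(in_dim), requires_grad=True)
        self.Wa = {d: _glorot_heads(rng, in_dim, self.head_dim, heads)
                   for d in ("in", "out")}
        self.Wb = {d: _glorot_heads(rng, in_dim, self.head_dim, heads)
                   for d in ("in", "out")}
        self.Wf = _glorot(rng, out_dim_total, out_dim_total)
        self.bf = Tensor(np.zeros(out_dim_total), requires_grad=True)

    def params(self):
        return ([self.gamma, self.beta, self.Wf, self.bf]
                + list(self.Wa.values()) + list(self.Wb.values()))


def _glorot(rng, fan_in: int, fan_out: int) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def _glorot_heads(rng, fan_in: int, head_dim: int, heads: int) -> Tensor:
    """Per-head Glorot init, heads stacked along the output axis."""
    limit = math.sqrt(6.0 / (fan_in + head_dim))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, heads * head_dim)),
                  requires_grad=True)


def _batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=0, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=0, keepdims=True)
    return gamma * (xc / (var + eps).sqrt()) + beta


class GRNAttentionEncoder:
    """Two-layer directional attention encoder over a fixed prior graph."""

    def __init__(self, graph: GeneGraph, n_features: int, cfg: EncoderConfig):
        self.graph = graph
        self.cfg = cfg
        self.n = graph.n_nodes
        rng = np.random.default_rng(cfg.seed)
        self.layers = [
            _Layer(rng, n_features, 2 * cfg.hidden_dim, cfg.heads),
            _Layer(rng, 2 * cfg.hidden_dim, cfg.out_dim, cfg.heads),
        ]
        self.c = Tensor(np.array(1.0), requires_grad=True)
        self.d = Tensor(np.array(0.0), requires_grad=True)
        self.M = _glorot(rng, cfg.out_dim, cfg.out_dim)
        self.rng = rng

        # pair lists: first E entries in graph edge order, then N self pairs
        e = graph.edges
        selfs = np.arange(self.n)
        self.center = {
            "in": np.concatenate([e[:, 1], selfs]) if len(e) else selfs.copy(),
            "out": np.concatenate([e[:, 0], selfs]) if len(e) else selfs.copy(),
        }
        self.neighbor = {
            "in": np.concatenate([e[:, 0], selfs]) if len(e) else selfs.copy(),
            "out": np.concatenate([e[:, 1], selfs]) if len(e) else selfs.copy(),
        }
        # selection matrices: gather_*[direction] @ X == X[pairs]; the
        # transpose of gather_cen scatter-adds pair values onto centers
        from scipy.sparse import csr_matrix
        n_pairs = len(self.center["in"])
        ones = np.ones(n_pairs)
        rows = np.arange(n_pairs)
        self._gather_cen = {}
        self._gather_nbr = {}
        self._scatter_cen = {}
        for d in ("in", "out"):
            gc = csr_matrix((ones, (rows, self.center[d])), shape=(n_pairs, self.n))
            gn = csr_matrix((ones, (rows, self.neighbor[d])), shape=(n_pairs, self.n))
            self._gather_cen[d] = gc
            self._gather_nbr[d] = gn
            self._scatter_cen[d] = gc.T.tocsr()

    def params(self):
        ps = [self.c, self.d, self.M]
        for layer in self.layers:
            ps += layer.params()
        return ps

    def de_encoding(self, l: np.ndarray) -> Tensor:
        if not self.cfg.use_de_encoding:
            return Tensor(np.full(self.n, 0.5))
        return (self.c * Tensor(l) + self.d).sigmoid()

    def forward(self, x: Tensor, D: Tensor, collect: bool = False):
        """Return (embeddings, attention dict {(layer, dir): (P, heads)})."""
        att: dict[tuple[int, str], np.ndarray] = {}
        n, heads = self.n, self.cfg.heads
        h = x
        for li, layer in enumerate(self.layers, start=1):
            h = _batchnorm(h, layer.gamma, layer.beta)
            dh = layer.head_dim
            dir_outs = []
            for direction in ("in", "out"):
                cen = self.center[direction]
                gc, gn = self._gather_cen[direction], self._gather_nbr[direction]
                sc = self._scatter_cen[direction]
                p = len(cen)
                ha = h @ layer.Wa[direction]   # (N, heads*dh), heads stacked
                hb = h @ layer.Wb[direction]
                na = (((ha * ha).reshape(n, heads, dh)).sum(axis=2) + _NORM_EPS).sqrt()
                nb = (((hb * hb).reshape(n, heads, dh)).sum(axis=2) + _NORM_EPS).sqrt()
                han = spmm(gn, ha)             # neighbor-side projections per pair
                dot = (spmm(gc, ha).reshape(p, heads, dh)
                       * han.reshape(p, heads, dh)).sum(axis=2)
                cos = dot / (spmm(gc, na) * spmm(gn, nb))          # (P, heads)
                score = spmm(gn, D.reshape(-1, 1)) * cos.abs()
                # temperature softmax over each center's neighborhood + self
                s = score * (1.0 / self.cfg.tau)
                seg_max = np.full((n, heads), -np.inf)
                np.maximum.at(seg_max, cen, s.data)
                z = (s - Tensor(seg_max[cen])).exp()
                alpha = z / spmm(gc, spmm(sc, z))
                msgs = (alpha.reshape(p, heads, 1)
                        * han.reshape(p, heads, dh)).reshape(p, heads * dh)
                dir_outs.append(spmm(sc, msgs).gelu())
                if collect:
                    att[li, direction] = alpha.data.copy()
            h = concat(dir_outs, axis=1)
            h = (h @ layer.Wf + layer.bf).gelu()
        return h, att

    def dgi_loss(self, emb_real: Tensor, emb_corrupt: Tensor) -> Tensor:
        s = emb_real.mean(axis=0).sigmoid()
        ms = self.M @ s.reshape(-1, 1)
        pos = (emb_real @ ms).reshape(-1)
        neg = (emb_corrupt @ ms).reshape(-1)
        return ((-pos).softplus().sum() + neg.softplus().sum()) * (1.0 / (2.0 * self.n))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def node_features(expr: LineageExpression, graph: GeneGraph) -> np.ndarray:
    """Per-gene standardized log expression; rows are genes, columns cells."""
    idx = {g: i for i, g in enumerate(expr.gene_symbols)}
    cols = [idx[g] for g in graph.nodes]
    x = expr.values[:, cols].T.copy()  # (N genes, M cells)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def train_encoder(graph: GeneGraph, expr: LineageExpression,
                  de: DiffExpProfile, cfg: EncoderConfig
                  ) -> tuple[GeneEmbeddings, AttentionRecord, DEEncoding]:
    """Optimize the infomax objective; return converged embeddings,
    attention coefficients for both layers/directions/heads, and the learned
    differential-expression encoding.  Deterministic given cfg.seed."""
    x_np = node_features(expr, graph)
    de_index = {g: i for i, g in enumerate(de.gene_symbols)}
    l = np.array([de.l[de_index[g]] for g in graph.nodes])

    model = GRNAttentionEncoder(graph, x_np.shape[1], cfg)
    opt = Adam(model.params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    x = Tensor(x_np)
    perm = model.rng.permutation(model.n)
    first_loss = last_loss = None
    for epoch in range(cfg.epochs):
        if cfg.resample_corruption or epoch == 0:
            perm = model.rng.permutation(model.n)
        D = model.de_encoding(l)
        emb_real, _ = model.forward(x, D)
        emb_corr, _ = model.forward(Tensor(x_np[perm]), D)
        loss = model.dgi_loss(emb_real, emb_corr)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite infomax loss at epoch {epoch}: {loss.data}")
        if first_loss is None:
            first_loss = float(loss.data)
        last_loss = float(loss.data)
        opt.zero_grad()
        backward(loss)
        opt.step()
    logger.info("encoder trained: loss %.4f -> %.4f over %d epochs",
                first_loss if first_loss is not None else float("nan"),
                last_loss if last_loss is not None else float("nan"),
                cfg.epochs)

    D = model.de_encoding(l)
    emb, att = model.forward(x, D, collect=True)
    record = AttentionRecord(n_nodes=model.n, n_edges=graph.n_edges,
                             center={d: model.center[d].copy() for d in ("in", "out")},
                             neighbor={d: model.neighbor[d].copy() for d in ("in", "out")},
                             alpha=att)
    encoding = DEEncoding(c=float(model.c.data), d=float(model.d.data),
                          D=D.data.copy())
    embeddings = GeneEmbeddings(genes=list(graph.nodes), values=emb.data.copy())
    return embeddings, record, encoding
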