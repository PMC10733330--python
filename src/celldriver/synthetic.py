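"""Self-contained synthetic fixtures: a prior interaction network with
planted lineage-specific regulation, and pseudotime-structured expression.

The generator emulates the statistical structure the method assumes:
a handful of driver regulators that are out-degree hubs wired into feedback
loops, targets whose expression responds (with sign) to logistic
activation/decay programs of their drivers along pseudotime, decoy prior
edges with no expression support, and pure-noise bystander genes.
Expression is simulated in linear space and log1p-transformed, matching the
fold-change convention of the differential-expression step.

The ``null`` preset is the no-signal control: an Erdos-Renyi prior with no
hub structure, zero effect sizes, and randomly labelled "drivers", so
nothing distinguishes the labelled genes and recovery should sit at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GeneGraph, LineageExpression

MIN_GENES = 50
MIN_CELLS = 100
MIN_DRIVER_OUT_DEGREE = 10


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 200
    m_cells: int = 500
    k_states: int = 4
    n_drivers: int = 5
    targets_per_driver: int = 30   # master-regulator hubs: ~15% of genes
    decoy_ratio: float = 4.0        # decoy : planted edge count
    effect_size: float = 1.0        # driver -> target response strength
    noise_sd: float = 0.5
    frac_activating: float = 0.7    # sign split of planted regulation
    hub_structure: bool = True      # False: Erdos-Renyi prior, random labels


@dataclass
class SyntheticScenario:
    cfg: SyntheticConfig
    prior: GeneGraph
    planted_grn: GeneGraph
    drivers_truth: set[str]
    expression: LineageExpression

    @property
    def gene_names(self) -> list[str]:
        return list(self.prior.nodes)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def make_scenario(cfg: SyntheticConfig) -> SyntheticScenario:
    """Generate a scenario; byte-identical for identical seeds."""
    if cfg.n_genes < MIN_GENES:
        raise ValueError(f"n_genes must be >= {MIN_GENES}")
    if cfg.m_cells < MIN_CELLS:
        raise ValueError(f"m_cells must be >= {MIN_CELLS}")
    if cfg.n_drivers * MIN_DRIVER_OUT_DEGREE > cfg.n_genes:
        raise ValueError("infeasible: n_drivers * 10 exceeds n_genes")
    if cfg.targets_per_driver < MIN_DRIVER_OUT_DEGREE:
        raise ValueError("targets_per_driver must be >= 10")
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    n = cfg.n_genes

    drivers = rng.choice(n, size=cfg.n_drivers, replace=False)
    driver_set = set(int(d) for d in drivers)

    planted: set[tuple[int, int]] = set()
    edge_sign: dict[tuple[int, int], int] = {}
    target_pool = np.array([g for g in range(n) if g not in driver_set])

    if cfg.hub_structure:
        # driver -> target hubs, targets drawn with preferential attachment
        in_deg = np.ones(len(target_pool))
        for d in drivers:
            p = in_deg / in_deg.sum()
            tgts = rng.choice(len(target_pool), size=cfg.targets_per_driver,
                              replace=False, p=p)
            for t in tgts:
                e = (int(d), int(target_pool[t]))
                planted.add(e)
                edge_sign[e] = 1 if rng.random() < cfg.frac_activating else -1
                in_deg[t] += 1.0
        # feedback: driver ring plus two target -> driver back edges each
        for a, b in zip(drivers, np.roll(drivers, -1)):
            if int(a) != int(b):
                planted.add((int(a), int(b)))
        for d in drivers:
            own = [t for (s, t) in planted if s == int(d) and t not in driver_set]
            for t in rng.choice(own, size=min(2, len(own)), replace=False):
                planted.add((int(t), int(d)))
        # scale-free background regulation: sources drawn preferentially by
        # current out-degree, so the planted driver hubs stay the dominant
        # hubs while a heavy-tailed background emerges around them
        n_bg = int(1.0 * n)
        attach = np.ones(n)
        for s, _t in planted:
            attach[s] += 1.0
        for _ in range(n_bg):
            s = int(rng.choice(n, p=attach / attach.sum()))
            t = int(rng.integers(n))
            if s != t and (s, t) not in planted:
                planted.add((s, t))
                attach[s] += 1.0
    else:
        # degree-homogeneous null: uniform planted edges, no hub wiring
        n_bg = cfg.n_drivers * cfg.targets_per_driver + int(1.5 * n)
        while len(planted) < n_bg:
            s, t = int(rng.integers(n)), int(rng.integers(n))
            if s != t:
                planted.add((s, t))

    # decoy prior edges: uniform pairs absent from the planted set
    n_decoy = int(round(cfg.decoy_ratio * len(planted)))
    prior_pairs = set(planted)
    while len(prior_pairs) < len(planted) + n_decoy:
        s, t = int(rng.integers(n)), int(rng.integers(n))
        if s != t:
            prior_pairs.add((s, t))

    planted_edges = np.array(sorted(planted), dtype=np.int64)
    prior_edges = np.array(sorted(prior_pairs), dtype=np.int64)
    planted_grn = GeneGraph(nodes=genes, edges=planted_edges)
    prior = GeneGraph(nodes=genes, edges=prior_edges)

    expr = _simulate_expression(cfg, rng, genes, drivers, planted, edge_sign)
    return SyntheticScenario(cfg=cfg, prior=prior, planted_grn=planted_grn,
                             drivers_truth={genes[d] for d in driver_set},
                             expression=expr)


def _simulate_expression(cfg, rng, genes, drivers, planted, edge_sign):
    n, m = cfg.n_genes, cfg.m_cells
    t = np.sort(rng.uniform(0.0, 1.0, size=m))
    cell_ids = [f"C{i:04d}" for i in range(m)]

    # driver programs: logistic activation or decay along pseudotime
    program: dict[int, tuple[float, float, bool]] = {}
    activity = {}
    for k, d in enumerate(drivers):
        t0 = rng.uniform(0.3, 0.7)
        steep = rng.uniform(8.0, 14.0)
        rising = k % 2 == 0
        program[int(d)] = (t0, steep, rising)
        a = 1.0 / (1.0 + np.exp(-steep * (t - t0)))
        activity[int(d)] = a if rising else 1.0 - a

    base = 2.0
    linear = base + rng.normal(0.0, cfg.noise_sd, size=(m, n))
    for d, a in activity.items():
        linear[:, d] = base + 6.0 * cfg.effect_size * a \
            + rng.normal(0.0, cfg.noise_sd, size=m)

    regulators: dict[int, list[tuple[int, int]]] = {}
    for (s, tt) in planted:
        if s in activity:
            regulators.setdefault(tt, []).append((s, edge_sign.get((s, tt), 1)))
    for tgt, regs in regulators.items():
        if tgt in activity:
            continue
        # per-target kinetic lag and gain: co-regulated targets share the
        # program shape but are not perfectly collinear, as in real data
        lag = rng.normal(0.0, 0.12)
        gain = rng.uniform(0.7, 1.3)
        resp = np.zeros(m)
        for (src, sign) in regs:
            t0, steep, rising = program[src]
            a = 1.0 / (1.0 + np.exp(-steep * (t - (t0 + lag))))
            if not rising:
                a = 1.0 - a
            resp += sign * (a - 0.5)
        resp /= len(regs)
        linear[:, tgt] = base + 6.0 * cfg.effect_size * gain * resp \
            + rng.normal(0.0, cfg.noise_sd, size=m)

    values = np.log1p(np.clip(linear, 0.0, None))
    return LineageExpression(cell_ids=cell_ids, gene_symbols=list(genes),
                             values=values, pseudotime=t)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0) -> SyntheticScenario:
    return make_scenario(SyntheticConfig(seed=seed))


def null_scenario(seed: int = 0) -> SyntheticScenario:
    """No-signal control: no hubs, no expression effect, random labels."""
    return make_scenario(SyntheticConfig(seed=seed, effect_size=0.0,
                                         hub_structure=False))


# ---------------------------------------------------------------------------
# Tiny worked example with hand-checkable control solutions
# ---------------------------------------------------------------------------

TINY_GENES = ["HUB1", "HUB2", "CYC1A", "CYC1B", "CYC2A", "CYC2B",
              "TGT1", "TGT2", "TGT3", "TGT4", "TGT5", "TGT6"]

TINY_EDGES = [
    ("HUB1", "CYC1A"), ("HUB1", "TGT1"), ("HUB1", "TGT2"), ("HUB1", "TGT3"),
    ("HUB2", "CYC2A"), ("HUB2", "TGT4"), ("HUB2", "TGT5"), ("HUB2", "TGT6"),
    ("CYC1A", "CYC1B"), ("CYC1B", "CYC1A"),       # feedback loop 1
    ("CYC2A", "CYC2B"), ("CYC2B", "CYC2A"),       # feedback loop 2
    ("CYC1A", "CYC2B"),                            # cross link
]

# frozen exhaustive-search optima for the tiny graph
TINY_MFVS_SIZE = 2      # one gene per feedback loop
TINY_MDS_SIZE = 3       # {HUB1, HUB2} forced (sources) + CYC1A
TINY_SOURCES = {"HUB1", "HUB2"}


def tiny_worked_example(seed: int = 7) -> SyntheticScenario:
    """Deterministic 12-gene, 40-cell instance whose MFVS/MDS optima are
    small enough to verify by exhaustive search."""
    genes = list(TINY_GENES)
    index = {g: i for i, g in enumerate(genes)}
    edges = np.array([(index[s], index[t]) for s, t in TINY_EDGES],
                     dtype=np.int64)
    graph = GeneGraph(nodes=genes, edges=edges)

    rng = np.random.default_rng(seed)
    m = 40
    t = np.linspace(0.0, 1.0, m)
    a_early = 1.0 - 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))  # HUB1 decays
    a_late = 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))         # HUB2 rises
    linear = 2.0 + rng.normal(0.0, 0.3, size=(m, len(genes)))
    program = {"HUB1": a_early, "HUB2": a_late,
               "CYC1A": a_early, "CYC1B": a_early, "TGT1": a_early,
               "TGT2": a_early, "TGT3": a_early,
               "CYC2A": a_late, "CYC2B": a_late, "TGT4": a_late,
               "TGT5": a_late, "TGT6": a_late}
    for g, a in program.items():
        linear[:, index[g]] += 5.0 * a
    expr = LineageExpression(cell_ids=[f"C{i:02d}" for i in range(m)],
                             gene_symbols=genes,
                             values=np.log1p(np.clip(linear, 0.0, None)),
                             pseudotime=t)
    cfg = SyntheticConfig.__new__(SyntheticConfig)
    cfg.seed, cfg.n_genes, cfg.m_cells = seed, len(genes), m
    cfg.k_states, cfg.n_drivers = 4, 2
    scenario = SyntheticScenario.__new__(SyntheticScenario)
    scenario.cfg = cfg
    scenario.prior = graph
    scenario.planted_grn = graph
    scenario.drivers_truth = {"HUB1", "HUB2"}
    scenario.expression = expr
    return scenario


# ---------------------------------------------------------------------------
# Writing a scenario in the standard input formats
# ---------------------------------------------------------------------------

def write_scenario(scenario: SyntheticScenario, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = scenario.prior
    pd.DataFrame({"source": [g.nodes[i] for i, _ in g.edges],
                  "target": [g.nodes[j] for _, j in g.edges],
                  "directed": 1}).to_csv(out / "prior.tsv", sep="\t", index=False)
    expr = scenario.expression
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_symbols)
    df.index.name = "cell_id"
    df.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame({"cell_id": expr.cell_ids,
                  "pseudotime": expr.pseudotime}).to_csv(
        out / "pseudotime.tsv", sep="\t", index=False)
    p = scenario.planted_grn
    pd.DataFrame({"source": [p.nodes[i] for i, _ in p.edges],
                  "target": [p.nodes[j] for _, j in p.edges]}).to_csv(
        out / "truth_network.tsv", sep="\t", index=False)
    (out / "truth_drivers.txt").write_text(
        "\n".join(sorted(scenario.drivers_truth)) + "\n")
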