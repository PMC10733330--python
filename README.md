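# celldriver

Cell-fate decisions along a developmental lineage are steered by a small
set of driver regulators acting through a cell-lineage-specific gene
regulatory network (GRN). `celldriver` infers that network from
single-cell RNA-seq expression and a prior gene-interaction network, and
then identifies the driver regulators by treating the GRN as a controlled
dynamical system. It is aimed at computational biologists who have a
lineage (cells, log-normalized expression, pseudotime) and want a ranked,
interpretable list of candidate fate regulators plus their gene modules.

## Method at a glance

1. **Lineage-specific GRN.** A two-layer graph-attention encoder runs two
   directional channels over the prior network (aggregating from
   regulators and from targets), scoring each edge with
   `e_ij = D_j · |cos(W_a h_i, W_b h_j)|`, where `D_j = σ(c·l_j + d)`
   encodes gene j's differential expression along pseudotime
   (`l_j` = mean |log2FC| vs the start state) and a temperature softmax
   (τ = 0.25) normalizes each neighborhood. The encoder trains
   unsupervised by maximizing mutual information between gene embeddings
   and a global summary against feature-shuffled negatives. Converged
   attention coefficients, rescaled by node degree
   (`β^in_ij = α^in_ij·indeg(j)`, `β^out_ij = α^out_ij·outdeg(i)`) and
   combined across layers (μ = 0.5), rank the prior edges; the top `k_d·N`
   (k_d = 8) form the lineage GRN.
2. **Driver candidates by network control.** On the GRN topology, the
   minimum feedback vertex set (plus all source nodes) and the minimum
   dominating set are solved exactly where tractable via graph reductions
   and 0–1 integer programming (HiGHS); their union is the candidate set.
3. **Driver regulators.** Genes are ranked by the influence score
   `S_i = λ·ln(1+Σ β^in_ij) + (1−λ)·ln(1+Σ β^out_ji)` (λ = 0.8, sums over
   GRN neighbors); the top-100 intersected with the candidates are the
   driver regulators. Controllability scores (`1 − |D_x|/|V|`), the
   Jaccard index between the two driver sets, and driver coverage
   summarize how controllable the lineage is.
4. **Regulon-like gene modules.** Each driver's GRN successor set
   (out-degree type) and predecessor set (in-degree type), filtered to
   differentially expressed genes (size ≥ 10), with per-cell activities
   scored AUCell-style (area under the recovery curve in the top 5% of
   each cell's expression ranks).

See `docs/methods.md` for assumptions, parameter meanings, and numerical
details.

## Worked example

Simulate a lineage with five planted hub regulators and run the full
pipeline (a few minutes on one CPU):

```sh
celldriver simulate --preset default --seed 1 --out sim/
celldriver run-all --prior sim/prior.tsv --expression sim/expression.tsv \
    --pseudotime sim/pseudotime.tsv --seed 1 --out out/
```

Programmatic equivalent:

```python
import celldriver as cd

scenario = cd.default_scenario(seed=1)          # 200 genes, 500 cells
cfg = cd.RunConfig(seed=1, repeats=1, epochs=350, time_limit=60)
res = cd.run_analysis(scenario.prior, scenario.expression, cfg)
print(res.grn.n_edges, len(res.report.drivers))
print(len(set(res.report.drivers[:20]) & scenario.drivers_truth))
```

prints `1600 62` and `4`: the selected GRN has 1600 edges (k_d·N), 62
genes pass both the influence and control filters, and 4 of the 5 planted
drivers appear in the top 20 — the true hubs rank at a median position of
14 of 200 by influence score. The run's controllability block reports
`controllability_score_mfvs 0.685`, `controllability_score_mds 0.870`,
`jaccard 0.203`, `coverage 0.838`: the dominating-set view needs far fewer
drivers than the feedback view on this feedback-rich network, and the
final regulators cover ~84% of all control candidates. `out/` additionally
contains `grn.tsv` (source, target, weight, origin), `influence.tsv`,
`modules.gmt`, `activity.tsv`, and a `manifest.json` with the config hash
and seeds.

Other subcommands: `grn`, `control`, `drivers`, `rgm`, `eval`
(AUPRC/early-precision-ratio of a GRN against a ground-truth edge list),
and `simulate --preset {tiny,default,null}`.

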