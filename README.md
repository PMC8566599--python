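# funconn

Functional-connectome group analysis for case–control resting-state fMRI
studies: from region-of-interest (ROI) time series to signed weighted
connectivity matrices, graph-theoretic network metrics, and
covariate-adjusted group inference with false-discovery-rate control.

The package is aimed at researchers comparing whole-brain functional
networks between a patient and a control group (e.g. a genetic-risk cohort
such as 22q11 deletion syndrome versus healthy controls) after standard
image preprocessing has produced per-region time series.

## What it computes

**Network construction.** Nodes come from an atlas table (regions filtered
by anatomical class and voxel size; small-but-important subregions merged
into composite nodes). Connectivity is the Pearson correlation between
region time courses, Fisher r-to-z transformed:

    z_ij = atanh( corr(x_i, x_j) )

giving a symmetric signed N × N matrix per subject with zero diagonal.

**Graph metrics** (per subject, handling negative weights per metric):

- weighted degree k_i = Σ_j |w_ij| (unnormalized magnitudes),
- nodal efficiency E_i = (1/(N−1)) Σ_{j≠i} 1/d_ij with shortest-path
  lengths d under edge length 1/w, and global efficiency = mean_i E_i,
- nodal local efficiency (global efficiency of the subgraph induced by a
  node's neighbors) and its network-wide mean,
- signed modularity
  Q = (1/v⁺) Σ_ij (w⁺_ij − e⁺_ij) δ(m_i, m_j)
      − (1/(v⁺+v⁻)) Σ_ij (w⁻_ij − e⁻_ij) δ(m_i, m_j),
  optimized by seeded Louvain restarts.

Efficiencies are computed after normalizing edge weights by the total
network weight, so groups that differ in overall connectivity strength are
compared on organization, not strength.

**Group inference.** Each outcome is regressed on
`[intercept, group, age, sex, psychosis history, mean FD]` (optionally
+ mean FC, + IQ); Benjamini–Hochberg FDR is applied per family (all edges;
each nodal metric's nodes; global metrics uncorrected); effect sizes use
d = 2t/√N with a 95% interval. Edge results are classified by lobe pair
and significant nodes are tested for enrichment among the network's hubs.

**Synthetic cohorts.** A simulation module draws subjects from multivariate
normal distributions with modular/hub correlation structure and plants
group deficits on chosen edges, providing ground truth for calibration and
recovery testing (see `docs/methods.md`).

## Worked example

Run the self-contained demo: a 105-node network, 67 controls + 40 patients,
196 time points per subject, with a 0.3 correlation deficit planted on
every edge incident to 3 hub nodes.

```python
from funconn import RunConfig, run_pipeline

report = run_pipeline(RunConfig(output_dir="demo_out", seed=7))
print(report["comparisons"]["base"]["edges_decreased"])   # 322
print(report["comparisons"]["base"]["edges_increased"])   # 4
print(report["comparisons"]["base"]["nodal"]["weighted_degree"])
#   {'decreased': 13, 'increased': 0}
print(round(report["hub_analysis"]["hub_enrichment_p"], 6))  # 0.000493
```

With seed 7 the edge-wise GLM (covariates: age, sex, psychosis history,
mean FD) finds 322 of 5460 edges significantly decreased in patients at
q ≤ 0.05 — the planted hub deficits radiating through the network — and 13
nodes with significantly reduced weighted degree. The hub-enrichment
p = 0.00049 says those reduced nodes are concentrated among the top-20%
highest-degree nodes of the control group, i.e. the planted hub
vulnerability is recovered. `demo_out/` holds the per-subject matrices,
metric tables, comparison tables for all three covariate sets, the hub
ranking and `report.json`; rerunning with the same seed reproduces every
file byte for byte.

The same pipeline is available from a shell:

```sh
funconn simulate --seed 7 --out cohort/ --n-hubs 3 --effect-delta 0.3
funconn run --config examples/demo.yaml
```

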