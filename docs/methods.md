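# Methods

`funconn` implements a whole-brain functional-network group analysis for
case–control resting-state fMRI studies: from region-of-interest (ROI) time
series to signed weighted connectivity matrices, graph-theoretic metrics at
edge, node and global level, and covariate-adjusted group inference with
false-discovery-rate control. This note records the model, the numerical
conventions, and the design choices where the design was genuinely open.

## Network construction

Nodes come from an anatomical parcellation described as a table with one row
per region (id, name, hemisphere, lobe, voxel size, anatomical class,
optional merge-group key). Two filters are applied before analysis:

- regions of excluded anatomical classes are dropped (default: cerebellar
  regions, which are often only partially covered by the acquisition);
- regions strictly smaller than a voxel threshold (default 57 voxels of
  2.75 × 2.75 × 3 mm) are dropped as too noisy — unless they carry a
  merge-group key, in which case they are retained and collapsed with the
  other members of their group into one composite node (e.g. thalamic
  subnuclei → one thalamus node per hemisphere; bilateral midbrain regions
  may merge across hemispheres, becoming `bilateral`).

Composite time series are the unweighted mean of the member series, matching
the region-mean convention used to extract ROI signals in the first place.
Merging requires homogeneous lobe and anatomical class within a group and is
idempotent. The packaged synthetic 170-row table reproduces the count
structure of a real whole-brain atlas pipeline (26 cerebellar rows, 4 small
unmergeable rows, 40 merge rows in 5 groups of which 24 are below threshold)
and yields exactly 105 nodes; its region identities are synthetic.

Connectivity between two regions is the Pearson correlation of their time
courses, Fisher r-to-z transformed (z = atanh r). Because atanh diverges at
|r| = 1, |z| is capped at `clip_z` (default 6.0 — far above any value
achievable at ~200 samples, so the cap only fires on degenerate inputs such
as duplicated columns); every cap is logged. The per-subject mean FC is the
signed mean of the N(N−1)/2 unique edge weights (an absolute-value variant
exists but is not the default, since the global-strength summary of interest
is signed average strength). Detrending and band-pass filtering belong to
the image-preprocessing stage upstream of this package and are deliberately
absent.

## Graph metrics

Six metrics per subject. Negative weights are handled per metric:

- **weighted degree** k_i = Σ_j |w_ij|, on the *unnormalized* magnitude
  matrix — degree comparisons concern raw strength;
- **nodal efficiency** E_i = (1/(N−1)) Σ_{j≠i} 1/d_ij and **global
  efficiency** (its mean), on the *normalized* magnitude matrix;
- **nodal local efficiency**: the global efficiency of the subgraph induced
  by a node's neighbors (w > 0, subgraph's own weights); nodes with fewer
  than two neighbors score 0. **Network local efficiency** is its mean;
- **signed modularity Q** on the raw signed matrix (a zero-negatives
  confirmatory variant is available).

Conventions, with rationale:

- *Weight → length*: d uses edge length 1/w (strong connections are short),
  the convention of the standard connectome toolbox lineage; shortest paths
  are Dijkstra per source, disconnected pairs contribute zero efficiency.
- *Averaging in nodal efficiency*: the sum of inverse path lengths is
  divided by N−1, so E_i is the inverse of the node's *average* shortest
  path; a literal-sum variant is trivially obtained by multiplying back.
- *Total-weight normalization*: before computing efficiencies, weights are
  divided by Σ_{i<j} |w_ij| (unique-edge sum), making the unique-edge
  absolute mass 1. This removes overall-strength differences between groups
  so that efficiency compares network *organization*; it makes normalized
  efficiency exactly scale-invariant. On a uniform complete graph of N
  nodes, normalized global efficiency is 2/(N(N−1)) ≈ 1.83 × 10⁻⁴ at
  N = 105, which sets the magnitude scale of these metrics. The unique-edge
  (rather than full-matrix) sum is a convention; the two differ by a factor
  of 2 that cancels in any group contrast.
- *Signed modularity*: Q rewards within-module positive weight at scale
  1/v⁺ and penalizes within-module negative weight at scale 1/(v⁺ + v⁻),
  each sign against its own configuration-model null e±_ij = s±_i s±_j / v±.
  The asymmetric scaling means positive structure dominates the partition
  while negative within-module weight still costs. Optimization is a seeded
  Louvain-style greedy (local moves + aggregation), best of 20 restarts,
  resolution fixed at 1; the reported Q is always re-evaluated directly from
  the definition on the final partition, so it is independent of optimizer
  bookkeeping. With no negative weights, Q reduces exactly to Newman
  weighted modularity (cross-checked against networkx in the tests);
  Dijkstra distances and Q are additionally verified against brute-force
  path enumeration and exhaustive partition enumeration on all random test
  graphs with ≤ 6 nodes.

## Group inference

Every outcome (edge z, nodal metric, global metric, mean FC) is regressed on
`[intercept, group, covariates…]` by ordinary least squares; the group
coefficient's t statistic with df = n − p and a two-sided p are reported.
The base covariate set is age, sex, psychosis history and mean framewise
displacement (so n = 107 subjects give t(101)); mean FC and IQ enter in two
additional covariate sets. Covariates are entered untransformed (the group
t is invariant to their scaling). Because edge-wise testing runs thousands
of regressions on one shared design, the engine is a vectorized
multi-outcome least squares (one pseudoinverse, per-column residual
variance), validated column-by-column against statsmodels OLS.

Multiple testing: Benjamini–Hochberg within a family — all unique edges are
one family, each nodal metric's node set is one family, and the three global
metrics are reported uncorrected. The psychosis-history contrast is the
coefficient of the psychosis indicator within the same design.

Effect sizes use the conversion d = 2t/√N with
SE_d = √(4/N + d²/(2N)) and a 1.96·SE normal interval. This is the standard
equal-n conversion applied at the total sample size; it reproduces the
published two-decimal (t, d, CI) triplets this package is checked against,
and an unequal-n variant (d = t√(1/n₁ + 1/n₂)) is provided separately.
Demographic tables are compared with the pooled-variance two-sample t test
and Pearson's chi-square without continuity correction (df = 1).

Edge classification labels each significant edge by its unordered lobe pair
at the granularity frontal / temporal / parietal / occipital / cingulate /
subcortical, pooling anything else as "remaining areas". Hub analysis ranks
nodes by control-group mean weighted degree and tests enrichment of the
significantly reduced nodes among the top 20% hubs with a hypergeometric
tail probability.

## Synthetic cohorts

The generator emulates *post-preprocessing* ROI time series: each subject is
a T × N draw from a zero-mean multivariate normal whose correlation matrix
has five equal modules (r = 0.4 within, 0.1 between; moderate resting-state
coupling), optional hub nodes with +0.15 cross-module correlation, and — in
the patient group — a configurable deficit subtracted from the population
correlation on designated edges. Planting on population correlations rather
than on z mirrors the measurement chain (series → Pearson r → Fisher z).
Defaults: 105 nodes, 196 samples, 67 controls / 40 patients, psychosis flag
in 25% of patients; age, sex and motion are sampled independently of group
(matched by design), with an optional group–motion shift for confound
experiments. Matrices that lose positive definiteness after planting are
repaired by eigenvalue clipping at 10⁻⁸ with rescaling to unit diagonal;
every repair is logged.

What the generator does **not** emulate: between-subject heterogeneity of
the population correlation matrix, hemodynamic autocorrelation, motion
artifacts, scanner drift, or non-Gaussian BOLD features. Passing the
calibration and recovery tests therefore shows that the statistical chain is
correct and well calibrated under its stated model, not that any particular
clinical effect exists in real data.

Calibration and recovery conditions used by the tests:

- *Null calibration*: 200 cohorts with no planted effect; edge-wise raw
  rejection at p < 0.05 is nominal and BH at q < 0.05 returns zero
  discoveries in ≥ 95% of cohorts.
- *Hub recovery*: a 0.3 correlation deficit on every edge incident to 3
  designated hubs; the hubs must occupy the three lowest weighted-degree t
  ranks in ≥ 90% of 50 replicates.
- *Global-scaling adjustment*: the patient group's z matrices scaled by 0.9
  (a pure global-strength deficit, nothing edge-specific). The scaling was
  chosen so the unadjusted edge-wise analysis has high power (hundreds of
  significant edges), making the adjustment's effect measurable; adding
  mean FC as a covariate must shrink the significant set to a small core
  (below a quarter of the unadjusted count; in practice mostly below 5%).
  The shrinkage is incomplete by nature: a multiplicative deficit affects
  strong edges more than weak ones, so a single mean-FC slope cannot absorb
  it exactly — the same reason real analyses retain a residual core of
  connections after mean-FC adjustment.

## Reproducibility and problem sizes

One global seed drives everything; it fans out to per-stage seeds by fixed
offsets (simulation, Louvain restarts), so stages are individually
reproducible and a rerun of the pipeline from the same config is
byte-identical. The packaged demo (105 nodes, 107 subjects, 196 samples,
hub deficits of 0.3 on 3 hubs) runs in a few minutes on one CPU; simulation
suites in the tests use 200 null cohorts and 50 recovery replicates, sizes
at which the binomial error of the checked rates is well below the asserted
margins.

## Known limitations

- Louvain is a greedy heuristic; optimality is verified exhaustively only
  for small graphs, and at realistic sizes only the best of 20 restarts is
  reported.
- The equal-n effect-size conversion d = 2t/√N is a reporting convention;
  with 67/40 groups the unequal-n variant differs by ~4% and is available
  when the convention is not required.
- The GLM assumes homoscedastic Gaussian residuals; no permutation or
  rank-based fallback is provided.
- Edge classification and hub enrichment depend on the node table's lobe
  labels; with the packaged synthetic atlas they exercise the machinery but
  carry no anatomical meaning.
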