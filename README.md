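# psychoweb

Symptom co-occurrence network analysis for ordinal rating-scale data.

Clinician-rated symptom inventories (such as the 65-item CPRS, scored 0–6
per item) describe psychopathology as a patients × symptoms score matrix.
`psychoweb` turns such a matrix into a weighted, undirected symptom
network — the "psychopathology web" — and asks which groups of symptoms
form its natural communities, how those communities relate to the
principal-component structure of the same data, and which individual
symptoms bridge the major syndromes.

## Method

1. **Preprocessing.** Items with no recorded scores are dropped; rare
   missing cells are imputed with column means. The item × item Pearson
   correlation matrix is bootstrapped: patients are resampled with
   replacement (default 10 000 replicates), the point estimate is the mean
   replicate correlation, and each pair's significance is the two-sided
   sign-crossing fraction `p = max(1/B, 2·min(P(r* ≤ 0), P(r* ≥ 0)))`.
   Sampling adequacy (overall KMO and Bartlett's sphericity test) is
   reported for the plain, pre-bootstrap matrix.
2. **Network construction and pruning.** The complete graph on items
   carries signed correlations as edge weights. Edges are pruned one at a
   time in ascending |r|; nodes that lose their last edge become isolates
   and leave the analysis, and percolation (fragmentation into several
   connected components) is tracked.
3. **Community detection.** At every pruning step, network community
   structure (NCS) is found by plain Clauset–Newman–Moore greedy
   modularity maximization on |r| weights, with deterministic
   tie-breaking:

   `Q = (1/2W) Σᵢⱼ [wᵢⱼ − sᵢsⱼ/(2W)] δ(cᵢ, cⱼ)`

4. **Confirmatory components.** Candidate k-component structures
   (default k = 5…10) are extracted from the bootstrapped correlation
   matrix, Varimax-rotated, and turned into item partitions by
   forced-choice assignment (largest absolute loading). Components are
   re-fit on the surviving items whenever a node drops off.
5. **Matching and selection.** Each NCS is compared with each candidate
   principal-component structure (PCS) through the mismatch score
   `|cluster Δ component| / (|cluster| + |component|)`, with clusters
   paired to components by the minimal-mismatch one-to-one assignment.
   The accepted web is the unpercolated solution retaining at least 80 %
   of the items with the smallest mean per-pair mismatch.
6. **Network metrics.** On the accepted web: weighted degree, weighted
   betweenness and closeness (Dijkstra with edge length 1/|r|), clustering
   coefficients, bridge/core classification (any cross-cluster edge makes
   a bridge symptom), small-worldness
   `S = (C/C_rand)/(L/L_rand)` against same-size random graphs, and
   two-factor (CLUSTER × BRIDGE) linear-model comparisons of the
   log-transformed metrics.

A synthetic-data generator with planted modular structure (latent cluster
factors, bridge items, zero-inflated rarity, MCAR missingness, ordinal
discretization) makes every stage testable without patient data.

## Worked example

```python
import psychoweb as pw

cfg = pw.SimulationConfig(
    n_patients=300, cluster_sizes=(8, 8, 8, 8, 8, 8),
    within_loading=0.8, noise_sd=0.6, missing_rate=0.01, seed=3,
)
ds = pw.generate_scores(cfg)               # 300 patients x 48 items, 6 planted clusters
model = pw.PsychopathologyWeb(ds.scores)
res = model.fit(n_boot=2000, seed=1, n_random=100)
print(res.summary())
```

prints

```
Psychopathology Web Results
================================================================
patients:   300    items: 48
bootstrap: n_boot=2000  seed=1
KMO: 0.895    Bartlett chi2: 9156.6 (df=1128, p=0.00e+00)
----------------------------------------------------------------
accepted optimum: k*=6  |r|>=0.0002  (p=9.82e-01)
surviving nodes: 48   clusters: 6
mean per-pair mismatch: 0.0%   disputed items: 0/48 (0.0%)
per-pair mismatch: 1:0.0%  2:0.0%  3:0.0%  4:0.0%  5:0.0%  6:0.0%
global (unconstrained) minimum: 0.0% at |r|=0.0002, k=6, 48 nodes
----------------------------------------------------------------
bridge symptoms: 48 (100%)   core symptoms: 0 (0%)   max external clusters: 5
small-worldness: S=1.00  (C=0.999, L=1.00, 100 random references)
drop-off vs zero-score fraction: r=0.029 (p=0.844)
```

The six planted clusters are recovered exactly (`k* = 6`, zero mismatch
between network clusters and components) at the very first admissible
threshold: with strong planted structure the communities are already
separable on the complete graph, so every per-pair mismatch is 0 % and
all 48 items survive. Because the accepted graph is still complete, every
node has cross-cluster edges (all bridges) and the web is
indistinguishable from its random reference (S ≈ 1); on real data,
pruning sparsifies the web, splits bridge from core symptoms and raises
S above 1. `res.save_outputs("out/")` writes the summary JSON, edge
list, GraphML, partitions, sweep trace, node metrics and scree / pruning /
mismatch plots; the same pipeline is available from the shell via
`psychoweb simulate` and `psychoweb run`.

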