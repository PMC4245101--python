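# Methods

This note documents the statistical procedure implemented by `psychoweb`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model and preprocessing

The input is a patients × items table of ordinal symptom scores
(default range 0–6) with occasional missing cells. Items with no recorded
scores at all carry no information and are dropped at read time. Missing
cells are imputed with their item's mean over recorded scores; imputed
values are deliberately kept real-valued rather than rounded back to the
ordinal scale, so column means are conserved exactly. Only
missing-completely-at-random missingness is supported: in the kind of
clinician-rated data this package targets, missing cells are rare
(well under 1 %), and a richer missingness model would be untestable at
that rate.

## Bootstrapped correlations

The item × item Pearson matrix is estimated by a patient-level bootstrap:
each of `n_boot` replicates (default 10 000) resamples the patient rows
with replacement — one index draw per replicate for the whole matrix, so
a replicate's correlation matrix is internally consistent — and the point
estimate is the element-wise mean over replicates. The mean was chosen
over the median for smoothness; pairs that are degenerate within a
replicate (an item constant in that resample) are skipped for that
replicate only.

Each pair's significance is a two-sided sign test on the replicate
distribution, `p = max(1/n_boot, 2·min(P(r* ≤ 0), P(r* ≥ 0)))`. No
standard estimator is canonical here; the sign test was chosen because it
is assumption-free and monotone in |r| for a fixed pair, which is the
property the pruning procedure relies on. The floor at `1/n_boot` keeps
p-values honest about the bootstrap's resolution.

KMO and Bartlett's sphericity test are computed on the plain
(pre-bootstrap) correlation matrix:
KMO = Σr²ᵢⱼ/(Σr²ᵢⱼ + Σq²ᵢⱼ) over i ≠ j with q the anti-image partial
correlations from the inverse correlation matrix (ridge-regularized by
1e−8 on the diagonal if singular), and
χ² = −(n − 1 − (2m + 5)/6)·ln det R with df = m(m−1)/2.

## Confirmatory components

A candidate k-component structure is the first k eigenvectors of the
bootstrapped correlation matrix scaled by √eigenvalue, Varimax-rotated
with Kaiser row normalization (the default of the statistical packages
this analysis style grew up in). Items are assigned to components by
forced choice on the largest *absolute* rotated loading — absolute rather
than signed, because a strong negative loading is still a strong
association — with ties broken toward the lowest component index and
column signs fixed so each component's dominant loading is positive.
Both conventions exist purely for determinism.

## Graph, pruning, community detection

The unthresholded graph is complete, with signed correlations as weights.
Pruning removes edges in ascending |r| (ties broken lexicographically on
the node pair), so strong negative correlations survive as long as strong
positive ones; accepted webs can therefore retain negative links. Nodes
that lose their last edge become isolates, leave the analysis, and do not
count as clusters; the number of connected components among survivors
tracks percolation.

Community detection is plain Clauset–Newman–Moore greedy modularity
maximization — singleton start, repeatedly merge the connected module
pair with the largest ΔQ, stop when no merge gains — without the
Wakita–Tsurumi balancing heuristics, and with deterministic tie-breaking
(smallest module-label pair; a module is labeled by its smallest item).
Modularity uses |r| edge weights, for the same reason pruning does;
a positive-only variant is available (`use_abs=False`). The test suite
cross-checks the implementation against networkx's CNM variant and
against exhaustive maximum-modularity search on small graphs. On small
graphs *with* modular structure greedy attains the exhaustive optimum;
on unstructured dense random graphs it can be legitimately suboptimal
(as can every CNM implementation), which is why the regression guard is
defined over planted-structure suite graphs.

## Matching and optimum selection

A network cluster and a principal component are compared by
`|cluster Δ component| / (|cluster| + |component|)` — 0 for identical
sets, 1 for disjoint ones. Clusters are paired one-to-one with
components by the assignment minimizing total mismatch
(`scipy.optimize.linear_sum_assignment`); a greedy pairing can be beaten
on small counterexamples and is order-dependent. When counts differ, the
surplus side is paired with an empty placeholder at mismatch 1.0 and
included in the mean. Two summary statistics are reported side by side:
the mean per-pair mismatch (the selection objective) and the share of
disputed items — items whose cluster's paired component does not contain
them, or vice versa, counted once — in the matched universe.

Component structures are re-fit on the surviving items whenever a node
drops off (not at every edge removal), so both sides of every comparison
see the identical item universe.

The accepted optimum is the record with the smallest mean per-pair
mismatch among records that are (a) unpercolated — a fragmented web is
not a single structure — and (b) retain at least `min_fraction` (default
0.8) of the items, which operationalizes rejecting deep but
heavily-pruned minima whose component structure no longer resembles the
full data's. Ties break toward more nodes, then lower threshold, then
lower k. The unconstrained global minimum is reported alongside for
comparison.

## Network metrics

On the accepted web (a single connected component):

* weighted degree `w_D` = Σ|r| over incident edges, plus its
  within-cluster restriction;
* weighted betweenness `w_BS` and closeness `w_CS` from Dijkstra shortest
  paths with edge length 1/|r| (Opsahl-style with α = 1): a stronger
  correlation is a shorter distance. Closeness is reported as the
  positive inverse mean distance;
* local clustering coefficient: unweighted transitivity on the pruned
  graph;
* bridge/core: one or more direct cross-cluster edges makes a bridge
  symptom, together with the count of distinct foreign clusters reached;
* log transforms as ln(1 + x) so that zero-valued betweenness or degree
  stays finite.

Small-worldness compares mean clustering and mean hop path length against
uniformly random graphs with identical node and edge counts (resampled
until connected, at most 100 tries each; default 100 references):
`S = (C/C_rand)/(L/L_rand)`, with S > 1 indicating small-world topology.
The reference model is the maximally agnostic one; degree-preserving
references would give systematically different (usually smaller) S.

Group comparisons are per-metric univariate two-factor fixed-effects
linear models (CLUSTER, BRIDGE, and their interaction when every design
cell has ≥ 2 observations), reported as type-II ANOVA F statistics with
group means and standard errors. A genuinely multivariate GLM adds
nothing at these sample sizes and obscures which metric drives an effect.

## Drop-off diagnostics

Each item's drop-off threshold is the |r| at which it lost its last edge;
items surviving in the accepted web are censored and contribute their
weakest retained link's |r|. The diagnostics correlate this threshold
with each item's zero-score fraction and missing-cell count across items.
Sign convention: rarity-driven early drop-off yields a *negative*
threshold-vs-zero-fraction correlation (rare items have high zero
fractions and low thresholds); analyses phrased in terms of frequency of
occurrence carry the opposite sign for the same relation.

## Synthetic-data generator

The generator emulates a heterogeneous patient sample rated on a
multi-syndrome inventory: K latent cluster severities per patient
(standard normal), items loading `within_loading` on their cluster (plus
a secondary loading for bridge items) with `noise_sd` Gaussian noise,
equal-probability quantile discretization to the 0–6 scale (so every
level is populated without assuming a link function), zero inflation
applied *after* discretization (overwriting with 0, mimicking symptoms
that most patients simply do not have), and MCAR missingness. Defaults
mirror the target data family: 192 patients, six unequal clusters
summing to 63 items, ~0.6 % missing cells. All draws happen in a fixed
order independent of the loadings, so the same seed yields the same
latent sample across loading settings (this is what makes the
monotonicity-in-loading property testable).

What it does not emulate: longitudinal dynamics, rater effects, oblique
(correlated) cluster factors, non-MCAR missingness, and copula-level
control of the ordinal margins. Consequently, passing recovery tests show
that the pipeline identifies modular correlation structure under ordinal
discretization and realistic noise — not that every clinical dataset has
such structure, nor that correlated syndromes (e.g. depression–anxiety)
remain as separable as independent planted factors.

## Problem sizes and numerics

Test and acceptance runs use scaled problem sizes chosen to exercise every
code path at comfortable cost: bootstrap sizes of 150–2 000 replicates for
synthetic checks (10 000 for the seed-stability check, matching the
default), 48-item six-cluster recovery problems with 500 patients, and
100 random references for small-worldness. Eigendecompositions are exact
(`numpy.linalg.eigh`); Varimax iterates the pairwise-SVD update to a
1e−10 relative criterion change; modularity bookkeeping is float64 with a
1e−12 tie tolerance; all RNG flows through `numpy.random.default_rng`
seeds, and every pipeline stage is deterministic given the seed.

## Known limitations

* Greedy modularity is order-dependent in principle; determinism is
  guaranteed, global optimality is not (and cannot be).
* The bootstrap p-value resolution is 1/n_boot; thresholds quoted as p
  values inherit that granularity.
* Column-mean imputation shrinks item variances slightly; at sub-percent
  missingness the effect is negligible, at higher rates it is not.
* The mismatch score treats clusters as flat sets; nested or overlapping
  structure is invisible to it.
* Exact reproduction of legacy NodeXL-era metric scalings (e.g.
  thousands-scaled closeness values) is out of scope; orderings and group
  contrasts are the meaningful quantities.
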