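# Methods

## Model

`clustfuse` implements evidence-accumulation consensus clustering on graphs.
The inputs are partitions, not data matrices: each *input clustering* is a map
from sample IDs to opaque cluster labels, tagged with the method and the
omics/data source(s) that produced it. A clustering is one atomic voting unit
regardless of how many omics it was computed from; omics tags are metadata for
scenario selection and reporting, never weights. Supports are raw counts and
are deliberately *not* normalized by the number of clusterings covering both
samples: fully-measured samples accumulating more supports than partial-data
samples is the intended behavior, since it prioritizes associations confirmed
by more data sources.

Given a scenario of `m` clusterings, the integration graph has edge weights in
`[1, m]` (pairs never co-clustered share no edge). The consensus sweep tests
all `m` thresholds × {LCD, MCL}; each candidate is size-filtered and scored
with wMQ (formula in the README). The node set keeps isolated samples so that
the final accounting — `clustered ⊎ reassigned ⊎ unassigned = all scenario
samples` — is exact.

## Design choices where the design was open

- **wMQ graph dialect.** The wMQ of a candidate is computed by default on the
  *unfiltered* integration graph restricted to the candidate's retained nodes,
  so that candidates obtained at different thresholds are compared on a common
  edge universe; `ConsensusParams(wmq_graph="filtered")` switches to scoring on
  the filtered graph that the candidate was clustered on. With identical
  inputs both dialects agree and score 1.
- **Joint selection.** LCD and MCL candidates compete in one pool; the single
  argmax of wMQ wins. Ties prefer the higher threshold (an equally good
  partition backed by more agreeing inputs), then LCD over MCL, then fewer
  clusters.
- **Size filters.** `min_size_cluster` and `min_size_consensus` accept
  absolute counts (int) or fractions (float in (0, 1]); fractions resolve
  against a user-declarable reference population, defaulting to the graph's
  node set. The `min_size_consensus` check applies to the pre-reassignment
  clustered set, since reassignment is an optional post-processing step whose
  placements need not meet the selected threshold.
- **Reassignment** scores each filtered-out sample against every consensus
  cluster by mean edge weight on the *unfiltered* graph (absent edges count
  0); positive best score wins, ties go to the lexicographically smallest
  cluster label. Samples isolated in the integration graph stay unassigned.
- **Degenerate wMQ shapes.** The formula divides by `|C_i|−1` and `k−1`; a
  singleton cluster contributes internal ratio 0 and a single-cluster
  partition has external term 0. Both are logged as warnings, keeping the
  sweep total rather than aborting it.

## Algorithms

- **LCD** is networkx's seeded Louvain (`louvain_communities`) on the
  support-weighted graph, resolution 1.0 by default. The seed is a required
  pipeline parameter echoed into the report; identical inputs and seed give
  byte-identical outputs.
- **MCL** is implemented in-package as dense-matrix stochastic flow
  simulation: column-normalize the adjacency (self-loops of weight 1 added for
  aperiodicity), then alternate expansion (matrix power 2) and inflation
  (element-wise power, default 2.0) with entry pruning below 1e-5, until the
  iterate changes by less than 1e-8 (max 100 iterations; non-convergence
  raises with the residual). Attractors are nodes retaining diagonal flow;
  connected attractors form one cluster nucleus and every node joins the
  nucleus receiving the largest share of its flow column, ties toward the
  lexicographically smallest system. Integration graphs at this scale are
  small and dense, so a dense implementation is both the simplest and the
  fastest option. MCL parameters are conventional defaults, exposed in
  `ConsensusParams`.
- Cluster labels of candidate partitions are assigned deterministically
  (clusters ordered by their smallest member), making partitions comparable
  across reruns.

## Evaluation statistics

- **ARI** (Hubert–Arabie, via scikit-learn) on the sample intersection of the
  two partitions; the test suite cross-checks it against explicit pair
  counting.
- **Permutation log-rank.** The observed statistic is the standard K-sample
  log-rank chi-square (verified against lifelines to machine precision);
  cluster labels are permuted over samples and the empirical p-value is the
  add-one exceedance fraction `(1 + #{perm ≥ obs}) / (n_perm + 1)`, which can
  never be 0 and is a conservative unbiased estimate. The statistic is
  evaluated in vectorized batches, which is what makes the default
  `n_perm = 100,000` (and the calibration suites) affordable.
- **Clinical enrichment.** Chi-square (discrete) or Kruskal–Wallis (numeric)
  per label, same permutation scheme. Labels missing for more than half of
  the partitioned samples are dropped before testing; samples missing a value
  are excluded pairwise per label. Significance is flagged at raw α = 0.01
  per label — no correction across labels by default, matching the convention
  of reporting each label's empirical p directly. Over/under-representation
  directions come from standardized Pearson residuals `(O−E)/√E` of the
  contingency table.
- **Feature ranking.** Per-feature Kruskal–Wallis across clusters,
  Benjamini–Hochberg adjustment (scipy), adjusted p < 0.001 cutoff, top 1000
  by significance. Constant features get p = 1 by convention.

## Synthetic benchmark

The generator emulates the structure of a multi-omics subtyping cohort, not
any particular dataset. Defaults (chosen once, as the realistic operating
point): 300 samples, 4 planted subtypes of equal expected size, 5 methods × 3
omics = 15 input clusterings, 20% label noise per clustering, omics signal 0.9
(with probability 0.1 an omics reflects an independent partition of its own —
modeling a data source that carries no subtype signal and only adds noise-like
edges), 20% missing samples per omics (shared by all methods of that omics,
mirroring how missingness follows the assay, not the method), and a 10% chance
a clustering splits its largest cluster or merges two (modeling
cluster-number disagreement between methods). Label noise relabels the chosen
fraction of samples to a uniformly drawn *different* label, so the nominal
rate is the effective flip rate. Survival is exponential with cluster-specific
hazards and independent exponential censoring calibrated to the requested
censored fraction at the mean hazard; clinical covariates are cluster-tilted
categoricals and cluster-shifted normals, with `effect = 0` giving exact
independence for calibration nulls.

What the generator does *not* emulate: correlated errors between methods run
on the same omics (real tools disagree less than independent noise would),
non-exponential survival, covariate-dependent censoring, and block missingness
patterns of real cohorts. Passing tests therefore demonstrate the machinery's
correctness and the smoothing behavior under independent noise, not
performance on any real cohort.

## Numerical and testing choices

- Empirical p-values use the add-one estimator throughout; permutation counts
  in the test suite are 2,000 (calibration/power) against the library default
  of 100,000, which is the package's intended production setting.
- Calibration suites run 500 null simulations per test and accept rejection
  counts inside the central 99.9% binomial band around the nominal 1% level.
- The smoothing benchmark uses 50 replicates of 15-clustering ensembles over
  150 samples with noise 0.1–0.3; brute-force oracle equivalence for wMQ/ARI
  runs on 200 random instances of up to 30 nodes. These sizes make the whole
  suite run in about a minute while keeping every statistical check
  well-powered.
- All randomness flows through explicit integer seeds (`numpy.random.default_rng`);
  reruns are byte-identical.

## Limitations

- The threshold sweep is exhaustive in `m`, and graph construction is
  quadratic in cluster sizes; cohorts of a few thousand samples are fine,
  single-cell-scale inputs are not the target.
- MCL's dense-matrix implementation is O(n³) per iteration; for graphs beyond
  ~5,000 nodes a sparse implementation would be needed.
- wMQ compares candidates within one run; its absolute value is not
  comparable across scenarios with different `max(w_IG)` densities, and no
  significance measure is attached to it.
- With fewer than two scenario clusterings there is no evidence to
  accumulate; the scenario type rejects that case outright.
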