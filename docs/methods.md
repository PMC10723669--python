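# Methods

## Model and assumptions

The prioritizer is a supervised guilt-by-association method. Its premise
is that disease genes cluster in the protein–protein interaction network:
if the curated disease genes preferentially interact with one another,
then a gene's topological relationship to that set carries signal about
its own disease involvement. The method makes no use of sequence,
annotation, or expression when ranking — only network topology — so its
power stands or falls with the clustering premise and with the quality of
the curated positive list.

The classification problem is positive/unlabeled in disguise: "negatives"
are genes sampled uniformly from the network outside the curated set, some
of which may be undiscovered disease genes. The resampling protocol
(re-drawing negatives every repetition) averages over this contamination
rather than correcting for it; vote fractions should be read as relative
rankings, not calibrated probabilities.

## Features

All features are computed on the simple undirected graph (self-loops and
duplicate evidence rows dropped at ingest; no edge weights, since
interaction databases report evidence lines, not strengths).

* **D** — degree.
* **N, R** — disease-gene neighbor count and its fraction of the degree
  (R = 0 for isolated genes). A gene never counts itself.
* **B** — betweenness centrality as unnormalized unordered-pair counts:
  Σ_{s<t, s,t≠v} σ_st(v)/σ_st. No normalization is applied; tree-based
  classifiers are scale-insensitive and one fixed convention keeps runs
  comparable.
* **C** — clustering coefficient, 2·e(Γ(v)) / (deg·(deg−1)); defined as 0
  for degree < 2.
* **M** — mean hop distance to the disease genes. The gene itself is
  excluded from its own average and unreachable disease genes are excluded
  from the mean; when no disease gene is reachable M takes the sentinel
  value |V|, strictly larger than any realizable path length, which keeps
  the feature finite and preserves the ordering "closer is smaller".
* **PR** — PageRank by power iteration with damping 0.85 (the value of the
  original algorithm), L1 convergence tolerance 1e-10, cap 1000 sweeps
  (an error carrying the last residual is raised on non-convergence).
  Each undirected edge acts as two directed links; isolated nodes are
  dangling and redistribute uniformly; the vector sums to 1.

Features for positive genes are computed against the full positive set, so
a positive gene's label influences N/R/M of its *neighbors*. This mirrors
the usual protocol but is a mild form of label leakage; the
`mask_self_label` switch on `compute_feature_table` removes each evaluated
gene from the disease set for its own row. Under the self-exclusion rules
above that removal is an identity — the switch exists to make the
convention explicit, not to remove the neighbor-level leakage, which is
inherent to guilt-by-association features.

## Resampling protocol

Defaults: balanced negative sampling (ratio 1.0 — an unbalanced design
would make accuracy uninterpretable), stratified 70/30 train/test split,
10-fold cross-validated grid search by mean CV accuracy (ties break to the
first grid point in deterministic order), 200 repetitions, base seed 123.
Repetition *i* uses seed base_seed + *i* for its negative sample, split,
and any stochastic classifier state, making every run exactly reproducible
and auditable per repetition.

Default grids: SVM (RBF) γ ∈ {0.01, 0.1, 1}, cost ∈ {0.1, 1, 10}; random
forest mtry ∈ {1, 2, 3}, ntree ∈ {100, 500}; kNN k ∈ {1, 3, 5, 7, 9};
naive Bayes has no grid and runs with default parameters. SVM and kNN are
fitted behind a standardization step (RBF distances and nearest-neighbor
votes are meaningless across features with incommensurate scales); trees
and Gaussian NB are scale-equivariant and are fitted on raw features.

Hyperparameters are tuned once per run, on the first repetition's training
set, and the chosen values are re-fitted on every subsequent repetition's
training data (`tune_every_rep=True` restores per-repetition tuning). With
seven features and a few dozen training genes the CV surface is flat
across repetitions, and tuning once keeps a 200-repetition run linear in
the cost of a single model fit.

Candidate calling: every repetition classifies every non-positive network
gene; the default majority rule calls genes predicted positive in more
than half the repetitions. The "any" rule (≥ 1 vote) is provided but over
hundreds of repetitions it approaches "call everything the model can ever
reach"; the "fraction τ" rule interpolates. The three rules are nested:
any ⊇ majority ⊇ fraction(0.9).

## Differential-expression screen

Thresholds: linear fold change > 1.5 and BH-adjusted p < 0.05, both
strict. The fold-change criterion is applied two-sided via
max(FC, 1/FC) > 1.5 so down-regulated genes pass symmetrically. BH is the
adjustment because it is the standard FDR control in expression pipelines;
the raw-p column is adjusted on ingest when no adjusted column is present.
`welch_de` (per-gene Welch t on log2 values) exists so synthetic matrices
can be screened without external tooling; it is deliberately not a
moderated-t/empirical-Bayes method and real studies should import their
own DE table.

## Shortest interaction paths

All distinct shortest paths between the pair are returned (a single
arbitrary path hides parallel routes), sorted lexicographically, capped at
`max_paths` with an explicit truncation flag; a disconnected pair returns
an empty list with status "disconnected" rather than an error.

## Synthetic generator

`generate_network` plants a disease module of `module_size` genes inside
an Erdős–Rényi background: module-internal pairs get edges with
probability `p_in`, all other pairs `p_out`. A `holdout_fraction` of the
module is hidden from the labels — these hidden positives are the
"discoverable candidates" whose recovery measures the whole pipeline.
`generate_expression` draws per-gene log2 baselines ~ N(8, 1) (typical
microarray intensities), adds N(0, noise_sd) noise, and shifts a
`de_fraction` of genes by ±`log2_effect` in cases; the DE truth can be
biased toward the network module so the candidate/DEG intersection has a
planted, recoverable overlap.

Default study conditions: 500 genes, module of 50, p_in = 0.3,
p_out = 0.02, 30% holdout; 10 cases vs 10 controls, 10% DE genes,
log2 effect 2 (fourfold), noise SD 0.5, seed 123. The network side gives
within-module degree ≈ 14.7 against background ≈ 10 — separable but not
trivial; the expression side gives high but not saturated power at
n = 10/10.

What the generator does *not* emulate: heavy-tailed PPI degree
distributions (hubs), assortativity, multiple or overlapping disease
modules, gene–gene expression correlation, and mean–variance trends.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own premise, not that it attains any particular
performance on real interaction or expression data.

## Validation and problem sizes

Feature computations are validated against independent brute-force
oracles (explicit shortest-path enumeration for betweenness, a dense
linear solve for PageRank, naive recomputation for the rest) over 200
random graphs of ≤ 30 nodes at mixed densities; path enumeration against
exhaustive simple-path search on graphs of ≤ 12 nodes. Pipeline-level
tests run the preset above with a random forest and 20 repetitions across
20 replicate seeds (recovery and vote-separation checks), 20 null-network
seeds with p_in = p_out (chance-level accuracy check), and 20 null
expression seeds (false-positive rate of the screen). These sizes are the
package's validation defaults, chosen to give stable Monte-Carlo estimates
on a single CPU; production runs use the 200-repetition default.

## Known limitations

* Negative sampling assumes non-curated genes are mostly non-disease;
  heavily contaminated backgrounds bias accuracy downward and vote
  fractions toward conservatism.
* Exact-symbol matching only; no alias or ortholog resolution. Human and
  mouse networks are processed entirely separately and species tags are
  checked at module boundaries.
* Betweenness and PageRank conventions (unnormalized counts, damping
  0.85) are fixed package conventions; other tools' normalized variants
  will differ by constant factors.
* The candidate list depends on the interaction snapshot and the curated
  positive list; headline counts are not transferable across database
  versions.
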