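# Methods

## The geometric model

The package treats a protein interaction network as a sample from a
popularity-similarity growth process on the hyperbolic disc. Node `i`
arrives at radius `r_i = 2 ln i` and a uniform angle; as later nodes join,
earlier ones drift outward ("popularity fading"):
`r_j(i) = 2β ln j + 2(1−β) ln i`, with `β = 1/(γ−1)` and `γ > 2` the target
exponent of the degree-distribution tail. Each newcomer makes `m`
connections — to the hyperbolically closest nodes at temperature `T = 0`,
or through the Fermi-Dirac connection probability
`p(d) = 1/(1 + exp((d − R_i)/(2T)))` at `T > 0`, where `R_i` is the standard
disc-radius calibration that keeps the expected number of links at `m`.
Distances use the hyperbolic law of cosines at curvature −1:
`d = acosh(cosh r1 cosh r2 − sinh r1 sinh r2 cos Δθ)`.

Under this model the angle is a similarity coordinate: proteins with many
common neighbors sit at nearby angles. The biological premise of the whole
pipeline is that kinases and phosphatases occupy preferred angular regions,
so the coordinates of an interaction's endpoints are informative about
directed (de)phosphorylation activity.

## Embedding inference (LaBNE + HyperMap)

Radii come from the degree ranking: the node of rank `k` (1 = highest
degree, ties broken by identifier) gets `r_k = 2β ln k + 2(1−β) ln N`.
Angles are initialized by Laplacian eigenmaps: the eigenvectors of the
second- and third-smallest eigenvalues of `Lv = λDv` (solved through the
symmetrically normalized operator `D^{-1/2} A D^{-1/2}`; dense solver below
500 nodes, sparse Lanczos with a fixed start vector above) give a planar
layout whose polar angle is taken as θ. A likelihood sweep then visits
nodes in decreasing-degree order and replaces each angle with the best of
`n_candidates = 60` equally spaced candidates within ±π/6 of the incumbent,
scoring `Σ_edges ln p(d) + Σ_non-edges ln(1 − p(d))` with `R` set to the
outermost radius. The incumbent is always among the candidates, so each
update — and, because pair terms are symmetric, the total likelihood —
never decreases. For networks above 2,000 nodes the non-edge sum is a
seeded subsample of at most 2,000 non-neighbors per node; below that the
sum is exact. One pass is the default; passes, window and candidate count
are configurable.

Inferred angles are identified only up to rotation and reflection of the
disc. All accuracy statements therefore use the Fisher–Lee circular
correlation, whose magnitude is invariant to both; the package never
compares raw angles. On generated networks (N = 500, m = 4, γ = 2.5,
T = 0.1) the inferred angles reach circular correlation ≈ 0.98 with the
planted ones, and greedy hyperbolic routing under the inferred map succeeds
nearly as often as under the true one.

Defaults for real interactome runs are `γ = 2.97`, `T = 0.83`, `w = 2π`,
matching the regime in which high-confidence human interactome maps have
been characterized; both are configuration inputs and are not estimated
internally.

## Angular clustering

Nodes are sorted by angle; the circle is cut wherever the gap between
consecutive angles strictly exceeds `g`, and each arc becomes a cluster.
The strict comparison is a deliberate tie-break: a gap exactly equal to `g`
does not cut. A minimum cluster size (default 3; 5 for the finer
subclustering pass at `g = 0.0042`) is enforced because downstream
per-sector analyses are meaningless on near-singleton sectors;
`select_gap_size` scans the observed gap values for the smallest threshold
whose clustering satisfies the constraint, maximizing angular resolution.
Note a subtlety of circular cutting: a single cut still leaves one
contiguous cluster, so the selected threshold can lie below the largest
gap even when only the single-cluster solution is feasible. Within an arc,
subclustering uses only internal gaps (no wrap-around). Duplicate angles
sort stably by node identifier, making the partition deterministic.

## Features and classifier

Each directed candidate (effector → target) is described by 14 features:
`r, θ, DC, BC, CC, EC` of the effector, the same six for the target, then
the pair's hyperbolic distance and `|Δr|`. Centrality conventions — raw
degree, betweenness normalized by `(n−1)(n−2)/2`, closeness
`(n−1)/Σd`, eigenvector centrality max-scaled to 1 — are fixed for
determinism; tree ensembles are invariant to monotone per-feature
transforms, so these choices do not affect discrimination. Eigenvector
centrality is computed by deterministic power iteration (uniform start,
tolerance 1e−10) because ARPACK's randomized start vectors would make
reruns differ in low-order digits and break byte-identical reproduction.

The forest is 500 CART trees with Gini impurity, bootstrap sampling, no
depth limit, and `mtry = 14` — all features considered at every split.
With mtry equal to the feature count the forest loses its usual feature
subsampling and decorrelates only through the bootstrap; the value is kept
as the protocol's stated optimum and is configurable. A pair's score is the
fraction of trees voting positive.

Class imbalance is handled by under-sampling: within each cross-validation
fold's training portion (and in the final refit) the majority class is
randomly down-sampled to the minority size. The protocol is a stratified
70/30 split, then 5-fold cross-validation repeated 10 times on the training
partition; reported `cv_accuracy` is the mean held-out fold accuracy at
the 0.5 threshold. All randomness derives from one seed through named
substreams in a fixed order (split → folds → under-sampling → trees →
permutations), so identical data and seed give identical predictions.

Evaluation reports the confusion matrix at the vote threshold (default
0.5), sensitivity on the positive (phospho-interaction) class, specificity,
the threshold-swept ROC with trapezoid AUC (equal to the
pairwise-concordance probability, ties counting one half), and the
precision-recall curve. Feature importance is permutation importance: the
mean accuracy drop over 20 seeded shuffles of each column, ties broken by
canonical feature order. An impurity-based alternative exists in the
underlying estimator but permutation importance is the package's reported
measure because it is model-agnostic and reproducible. The masking study
trains models on nested feature subsets (by default five models at 14, 12,
10, 8 and 6 features, dropping features in importance order) under the full
cross-validation protocol and reports each subset's test AUC.

## Training-set construction

Positives are interactions annotated with PSI-MI code MI:0217
(phosphorylation reaction) or MI:0203 (dephosphorylation reaction) whose
direction is resolvable: exactly one endpoint in the kinase or phosphatase
catalogs orients the pair effector → target; a kinase paired with a
phosphatase is treated as mutual action and yields both orientations; pairs
with no effector, two same-type effectors, or an endpoint present in both
catalogs (ambiguous type) are discarded. Annotated pairs that are not edges
of the network are dropped with a logged count. The negative pool is every
remaining directed orientation of a network edge; by default the *reverse*
orientation of each positive is also excluded, since its true label is
unknown — classifiers of this kind demonstrably struggle to separate the
two directions of a genuine phospho-edge — and a flag restores the literal
everything-but-the-positives pool. Whether to sample the pool down (the
pipeline default draws 3 negatives per positive before under-sampling) or
use it whole is configurable.

## What the synthetic generator does and does not emulate

The generator reproduces the structural conditions the method relies on:
scale-free degree structure with tunable γ, temperature-controlled
clustering, effector catalogs concentrated in angular sectors (defaults:
kinases 3% of nodes around θ = 1.8, phosphatases 1.5% around θ = 4.0,
sector half-width 0.3, mirroring the observed sizes of human kinase and
phosphatase complements and their angular concentration), and directed
positives drawn from effector-incident edges with weight `exp(−d/λ)`,
λ = 1, so positives sit hyperbolically closer than background edges. The
demonstration study uses N = 1000, m = 4, γ = 2.5, T = 0.3 and 150
positives — large enough for stable metrics, small enough that the whole
suite runs in minutes.

It does not emulate: annotation noise (false or missing PSI-MI labels),
study bias in which interactions get curated, the correlation structure of
real centralities beyond what the growth model induces, multi-domain
effectors acting through shared complexes, or identifier-mapping artifacts.
Passing synthetic tests therefore demonstrates that the pipeline recovers
planted geometric signal under the model's own assumptions, not that real
interactomes satisfy those assumptions.

## Numerical choices and degenerate inputs

- acosh arguments are clamped at 1; pairs with angular separation below
  1e−12 short-circuit to `|Δr|`, avoiding catastrophic cancellation.
- Connection probabilities are clipped to [1e−12, 1 − 1e−12] inside
  log-likelihoods.
- Refinement requires `T ≥ 0.01`; at `T = 0` the likelihood is a step
  function and the sweep is undefined.
- Empty networks are legal for filtering and LCC extraction; embedding,
  centralities and clustering require a connected input and say so.
- Equal-size components tie-break to the lexicographically smallest node
  set; degree ties in radial ranking break by identifier; duplicate angles
  sort by identifier.
- Edge confidences of duplicate records keep the maximum.

## Known limitations

- The embedding likelihood is optimized one node at a time for one pass; it
  is a local refinement, not a global optimum, and exact reproduction of
  any particular published coordinate table is not expected — reference
  coordinates should be supplied as inputs when reproducing numbers tied
  to a specific embedding.
- `mtry = 14` disables feature subsampling (see above).
- Scores of the two orientations of an edge are independent; the model can
  rate both directions high and offers no calibrated comparison between
  them beyond the raw scores.
- Phosphorylation and dephosphorylation are not distinguished at prediction
  time; the classifier answers "directed phospho-interaction, yes or no".
- The four per-node centralities are recomputed exactly; on interactome-
  scale networks (≈15k nodes) betweenness dominates runtime (minutes).
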