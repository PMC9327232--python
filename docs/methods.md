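# Methods

## Problem setting

Given a samples × features expression matrix with binary class labels
and a prior feature-interaction network (nonnegative weighted edge
list), the task is to return a small feature subset with high label
relevance and low mutual redundancy. The pipeline treats redundancy as
a graph-community property — features that co-express and interact
should compete within one cluster, not all enter the panel — and treats
relevance as a consensus over heterogeneous evaluators rather than a
single statistic.

## Prefiltering

Welch's unequal-variance t-test is used rather than Student's pooled
test: microarray classes are routinely unbalanced with unequal
variances, and Welch is the safer default. The 100 smallest p-values
are kept (ties broken lexicographically by probe id so the result is a
deterministic function of the input). Features with zero variance in
both classes receive p = 1 when the class means are equal and p = 0
otherwise. The 0.05/0.01/0.001 significance categories use strict
inequalities at each cutoff.

Dataset unbalance rates (n_pos/n_neg) are truncated — not rounded — to
two decimals, which is how the cohort tables this summary mirrors print
them (26/67 → 0.38).

## Graph construction

Candidate edges are the union of prior edges (weight > 0) and pairs
with |Pearson r| ≥ `r_min` (default 0.7). The raw weight is the
arithmetic mean of the two sources, a missing source contributing 0.
Pearson enters as |r|: strongly anti-correlated features are just as
redundant as correlated ones, and a signed weight inside the softmax
would invert that intent; the signed correlation matrix is still
available for reporting. Constant features get r = 0 off-diagonal.

Normalization is a per-node softmax over incident raw weights (each
node's outgoing shares sum to 1) followed by symmetrization — the edge
weight is the mean of its two directed shares — so weights lie in
(0, 1]. Isolated nodes are legal and simply have no edges.

## Propagation

The aggregate of node i is Σ_j h_j·w_ij / |N(i)| (zero vector for an
isolated node; the division by the neighbour count is kept even though
softmax weights already sum to ≈1, because the final renormalization
absorbs scale anyway). The update concatenates the previous embedding
with the aggregate, applies tanh elementwise, and averages the two
halves so the dimension stays constant; without this collapse the
concatenation would double the dimension each layer and the
layer-to-layer convergence test would compare vectors of different
lengths. There are no trainable weights. Every embedding is
renormalized to unit L2 norm after each step (and at construction, so
the invariant holds from layer 0); a zero-norm update (possible for an
isolated node under odd activations) keeps the previous embedding.

Updates are synchronous — all nodes read layer K−1 — which makes the
result independent of node order and permutation-equivariant.
Convergence is declared when the largest per-node embedding change
drops below ε (default 0.01), with a hard cap of 50 layers. On dense
100-node graphs the change decays monotonically but can still be
slightly above 0.01 at the cap; the result is then flagged
non-converged and used as-is, which in practice leaves the block
structure fully formed. tanh is the default activation because
normalized expression profiles are signed; identity and relu are
available.

## Link prediction

10% of edges (at least one, never all) are removed uniformly as
positives; 5 non-edges per positive are sampled uniformly without
replacement as negatives. Because nothing else in the model has free
parameters, the node embeddings themselves are trained, initialized
from the propagation output. The scorer is cosine similarity and the
loss is the standard negative-sampling objective, mean over positives
of −log σ(sim) − Σ_neg log σ(−sim). Full-batch gradient descent
(learning rate 0.01) with an analytic gradient (verified against
central finite differences at 1e−5 relative tolerance in the tests);
embeddings are renormalized to unit norm each epoch; training stops
when the loss changes by less than 1e−4 or at 200 epochs.

After each epoch the MRR of the positives among their own negatives is
computed — rank = 1 + #strictly-higher negatives, ties contributing
1/2 (mean-rank tie-break) — and the best-MRR snapshot is kept. The
augmented graph G* adds the top ceil(0.1·|E|) non-edges by similarity
(weight = max(similarity, 1e−6)) and restores the held-out positives at
their original weights, so |E(G*)| = |E_reduced| + additions + held-out.

## Spectral clustering

Node similarity is the Gaussian kernel on the best link-prediction
embeddings, W_ij = exp(−‖e_i−e_j‖²/(2Ω²)) with zero diagonal
(self-similarity would only shift all degrees uniformly). Ω defaults to
the median pairwise distance (median heuristic) since no principled
value is implied by the data scale alone. The symmetric normalized
Laplacian's μ smallest eigenvectors are row-normalized and clustered by
k-means (10 restarts, fixed seed). Zero-degree nodes get an identity
row/column in the Laplacian — a unit eigenvalue — so the
zero-eigenvalue multiplicity counts connected components among
non-isolated nodes.

## Rank fusion

Evaluator settings are pinned for cross-ecosystem reproducibility:

| evaluator | importance | settings |
|---|---|---|
| l1, l2 | abs. logistic coefficient | C = 1.0, liblinear |
| linear_regression | abs. OLS coefficient | — |
| ttest | abs. Welch t | — |
| correlation | abs. Pearson r(feature, label) | — |
| decision_tree, random_forest | impurity importance | 100 trees, fixed seed |
| stability_selection | nonzero-l1 frequency | 100 subsamples of 75%, per-feature column scaling U[0.5, 1] |

Features are standardized before the model-based fits; ties are broken
by probe id; a single-feature cluster needs no fit. The L1/L2
evaluators are logistic rather than penalized least-squares: with a
binary label and unit penalty weight, a lasso regression would zero
every coefficient and the evaluator (and stability selection built on
it) would degenerate to the tie-break.

RRA: for each feature the normalized ranks r = rank/m across the n
lists are sorted; ρ = min_k BetaCDF(r₍k₎; k, n−k+1), i.e. the most
surprising order statistic under the null of random rankings (a feature
ranked 1/10 in three of three lists gets ρ = 0.1³ = 0.001). The fused
order is ascending ρ with id tie-break; a Bonferroni-style corrected
score min(1, ρ·m) is reported alongside but does not affect the order.
The rank-1 feature of each non-empty cluster is selected; empty
clusters (possible under degenerate k-means) are skipped with a
warning.

## Synthetic data

The generator emulates small-cohort two-class microarray data: M ≪ N,
configurable class imbalance, correlated blocks, and a partially
observed prior. Defaults: 60 samples, 500 features, 4 blocks of 10,
factor loading λ = 0.8 (within-block correlation λ² = 0.64), class
shift δ = 1.5 within-class sd units applied to every block's latent
factor, balanced classes, prior edge probability 0.8 within blocks
(weight U(0.5, 1)) and 0.02 elsewhere. Labels are assigned by fixed
count (round(balance·M), shuffled) so both classes are always present.
The optional `planted_feature_per_block` mode additionally shifts the
first feature of each block by δ directly, making it the uniquely
strongest marker of its block; recovery of exactly that feature set is
the end-to-end correctness check.

What the generator does **not** emulate: heavy-tailed intensity
distributions, batch effects, probe saturation, missing values, or
overlapping pathway membership. Passing tests therefore demonstrate the
machinery recovers planted low-rank block structure, not that the
pipeline is robust to every artefact of real microarray data.

## Evaluation

Selected panels are scored by stratified 10-fold cross-validation with
an RBF support-vector classifier (C = 1.0, kernel width scaled by
feature count × variance), standardizing inside each training fold to
avoid leakage, with AUC from decision-function scores. The fold count
is reduced with a warning when the smaller class has fewer samples than
folds. The cluster-count sweep reuses the prefilter/graph/propagation/
link-prediction stages and reruns only clustering, selection and CV per
μ.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline on the default
synthetic cohort (60 × 500, 100 retained features, a few hundred edges)
and a compact planted-marker cohort (60 × 60, 40 retained); both
complete in seconds on one CPU and exercise every stage at realistic
density. All randomness flows through explicit integer seeds
(numpy `default_rng`, scikit-learn `random_state`), and two runs with
identical configuration produce byte-identical output files.
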