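# Methods

This note records the model assumptions, the parameters that matter, the
design choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The code hierarchy

A catalog is a forest: every non-chapter code has exactly one parent and
levels increase by one per link (chapter level = 1, at most six levels).
The derived is-a relation is irreflexive and transitive; `parse_catalog`
rejects duplicate ids, unknown parents and cycles with specific errors.
When a catalog carries no explicit parent/level columns, parents are
inferred from dotted digit-group code strings — the parent of a code is
the entry whose digit string is the longest proper prefix of its own — and
levels are depths in the resulting forest, so the shortest codes present
form level 1.  Explicit columns take precedence because catalog dialects
disagree on whether levels count digits or digit groups.  A virtual root
joins the chapter codes for traversal only; it never appears in paths,
metrics or predictions, and codes in different chapter trees have no
defined path distance.

## Training-set construction

The siblings policy turns `(query, code, ±1)` logs into per-node sets:
positives propagate to all ancestors (true path rule), become negatives of
the explicit code's siblings, and a query positive for a node is never
simultaneously a negative there.  Two open points were resolved as
follows:

* sibling negatives are generated at the explicit code's level only;
  upward positive propagation already covers the ancestors, and
  propagating negatives to ancestors' siblings would make the rule
  quadratic in depth without a textual basis;
* downward propagation of explicit negatives to descendants (the negative
  half of the true path rule) is available behind
  `propagate_offspring_negatives` but off by default, since set
  construction is defined by the siblings policy alone.

Trainability requires ≥ 21 positives (inclusive; the bound is the minimum
the oversampler's 5-neighborhood needs inside an n-fold split, and the
comparison convention is configurable).  Merging a mapped secondary corpus
re-labels its records onto primary codes, drops unmapped records with a
logged count, and collapses duplicates keeping the primary source tag.

Class balance: synthetic minority oversampling interpolates uniformly on
segments between a minority point and one of its `k = 5` nearest minority
neighbors (ties broken by index), leaving the majority class untouched and
equalizing counts.  Very large negative sets are first subsampled to 10×
the positives.  Balancing belongs to the per-node training protocol; the
non-terminal multiclass models are trained unbalanced, as the
interpolation definition is binary.

## Representations

*Bag of concepts.*  Tokens (lowercased, whitespace-split) map through the
lexicon to concepts at weight 1; similar concepts join at their similarity
weight in (0, 1]; contributions accumulate additively and word order is
discarded.  The lexicon file is a stand-in for a commercial terminology
server and carries explicit `term` and `similar` rows.

*Linear reduction.*  `VarianceProjection` is PCA with a deterministic sign
convention (largest-magnitude component positive) and a rank check that
names the attainable dimension.  The production-scale figure of a
15,000-dimensional intermediate is a hardware-driven choice; all synthetic
benchmarks use small dimensions, and the stage is optional.

*Stacked denoising autoencoder.*  Nested two-layer autoencoders (ReLU
encoder, linear decoder, squared loss) are pre-trained greedily, each on
the masked-out (corruption 0.1) output of the previous stack, with Adam in
plain numpy; the final width (default 125) is the dense query vector fed
to base classifiers.  Default stack `input → 1000 → 500 → 125`; depth and
widths are configurable since only the output width is fixed by the
design.  Training logs per-epoch reconstruction loss; everything is
deterministic given the seed.

*Self-attentive encoder.*  One encoder per trainable true path, trained on
the pooled positive multiset of all nodes on the path (a query annotating
k path nodes is counted k times — this is what makes deep paths
trainable; three nodes with 910, 681 and 131 positives pool 1,722
examples).  The block is scaled dot-product attention over learned Q/K/V
projections with residual + layer-norm, a ReLU feed-forward of width
`d_f = 4·d_m`, and a second residual + layer-norm; 4 heads by default,
implemented with explicit backpropagation that the test suite checks
against central finite differences.  Pre-training reconstructs clean token
embeddings from corrupted sequences; fine-tuning optimizes a logistic
code-matching head on the path's deepest node, mean-pooling the hidden
sequence (the least-structured pooling choice).  Head count, `d_f`, and
the fine-tuning loss are not fixed by the design and are recorded here as
package choices.

## Base classifiers and strategies

Learner families sit behind a fit/predict_proba contract: bagged trees
(random forest), boosted stumps (AdaBoost), a softmax feed-forward network
(two hidden layers 90–60, dropout-style regularization via sklearn's MLP,
adaptive-moment optimizer) and a fast logistic baseline.  Hyperparameters
stay at library defaults and are pinned in the model manifest.

Per-node: one binary classifier per trainable node.  Non-terminal: per
internal node a multiclass model over trained children plus a residual
class whose examples are the node's positives not positive for any trained
child (a package decision; the residual construction is otherwise
unspecified), plus a virtual-root model over the chapter codes whose
residual collects queries appearing only as negatives there.  Degenerate
one-class sets fall back to a constant scorer.

## Prediction and threshold adaptation

Top-down search evaluates chapter-level classifiers first and recurses
only into accepted nodes' children; argmax accepts one node per level
(lexicographic tie-break) and threshold mode accepts every node with
score strictly above its threshold.  The non-terminal search descends
through the argmax child until the residual wins or a leaf is reached.
Accepted sets are ancestor-closed by construction and closed defensively.

Thresholds initialize to `n_pos/(n_pos+n_neg)` per node (default 0.5
without statistics).  Bottom-up smoothing processes nodes leaves-to-root
and replaces a parent threshold with the mean of its children's whenever
the mean is smaller; the children-minimum variant is available
(`stat="min"`) because the textual description supports both readings;
the mean is the default.  The pass is monotone non-increasing and
idempotent.

Bayesian aggregation estimates `P(ŷ|y)` per node from validation confusion
counts with additive smoothing (symmetric fallback when a node lacks
coverage) and `P(y=1|parent=1)` from training-pair frequencies; the
chapter-level prior is the node's share of positives.  Observations are
the binarized classifier outputs at the current thresholds — the
aggregation model is over binary observed nodes, and continuous scores
never enter the conditionals.  MAP inference is exact max-product on the
tree; the structural zero `P(y=1|parent=0) = 0` forces closed results, the
normalization constant cancels in the argmax and is never computed, and
ties prefer the negative label.  Unobserved nodes are marginalized out;
for small hierarchies all trainable classifiers are evaluated before
aggregation.

## Hierarchical metrics

Precision `|pred ∩ gold| / |pred|` and recall `|pred ∩ gold| / |gold|` on
ancestor-closed sets; an empty prediction scores 0/0 and is counted (it is
exactly the blocked-path failure the threshold adaptations target), while
an empty gold set is an error.  Because "average F1" is ambiguous, both the
harmonic mean of averaged precision/recall and the mean of per-query F1
are reported under explicit names, alongside pooled micro variants and
per-level micro-F1 (levels with no codes on either side are omitted).
Path distance is the undirected tree-path step count between deepest
codes.

## The synthetic generator

The generator emulates the statistical structure the method assumes: a
dotted-code tree (mixed fan-out calibrated so about 45% of internal nodes
have more than five children), disjoint characteristic token sets per
node, queries of 2–6 terms drawn from the target's true-path vocabularies
with a noise fraction ρ from the global vocabulary (the first token always
comes from the target node, making targets identifiable), one positive
record per query and 8 explicit negatives sampled off-path — mirroring the
strong negative imbalance of real logs.  Positive counts per node are
Poisson (mean 40 by default); generation is byte-deterministic given the
seed.

What it does **not** emulate: real clinical vocabulary overlap between
sibling codes, morphological variation, label noise from human judgments,
and power-law query-frequency skew.  Consequences: the zero-noise corpus
is perfectly separable by construction, so the pipeline's hierarchical
F1 of 1.0 there demonstrates correctness of the machinery, not expected
performance on real logs; and multiclass routing among disjoint-vocabulary
siblings is far easier than in production data.

## Benchmark protocol and problem sizes

The strategy benchmark uses depth 4, branching 4, ρ = 0.1, 50 positives
per node (340 codes, ≈150k training pairs), a single 60/40
train/validation split of distinct queries, and boosted stumps as the
common base learner for both strategies.  With strong learners (logistic,
random forest) both strategies saturate on disjoint-vocabulary data and
their ordering is unstable; under a weak learner the (n+1)-way routing
task degrades much more than the binary per-node task, which is the regime
the method was designed for, so the boosted-stump family is the
benchmark's common learner.  Per-level micro-F1 is a base-classifier
measurement: per-node binary confusions binarized at 0.5, non-terminal
argmax routing confusions tallied at the child's level (the residual
class carries no level).

The reachability experiment inflates leaf thresholds by +0.3 on a depth-3
corpus (ρ = 0.05, 40 positives/node, 400 evaluation queries) and compares
threshold-mode search with and without Bayesian MAP relabeling.

## Numerical choices and limitations

Thresholds are compared strictly (`score > t`); layer-norm uses ε = 1e-6;
probability zeros enter MAP scoring as −∞ log-terms rather than being
clipped, so deterministic conditionals remain exact; PCA sign flips make
projections run-to-run identical; all stochastic components take explicit
seeds.  Tree-only inference throughout — no DAG/multi-parent ontologies,
no loopy propagation, no beam search over multiple non-terminal branches,
no online threshold learning, and no GPU path.  The per-node strategy
scales linearly in trainable nodes; batched scoring
(`EnsembleModel.score_matrix`) is used everywhere predictions are made in
bulk.
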