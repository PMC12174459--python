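# Methods

## Model

`molungn` classifies cancer-stage labels from multiple omics views
(mRNA expression, miRNA expression, DNA methylation) measured on the same
patients. The architecture has two levels:

**Omics-specific branches (OSGAT).** Each view m contributes a feature
matrix X_m in R^{N x D_m} and a patient-similarity network over the N
samples. Three fully connected layers (ReLU, per-sample feature
normalization, dropout) reduce D_m to a compact representation; two
multi-head graph-attention layers then propagate information along the
similarity network. For an edge (i, j) the raw score is

    e_ij = LeakyReLU( a^T [W h_i || W h_j] ),     slope 0.2,

normalized by a softmax over the neighborhood N_i (which always contains i
itself), and the node update is the coefficient-weighted sum of the
neighbors' projected features. Hidden attention layers concatenate their
heads and apply ELU; the final attention layer averages heads and stays
linear ahead of a C-class softmax head. All weights are Xavier-uniform
initialized. Each branch therefore emits an initial per-sample class
distribution using only its own omics type.

**Cross-omics fusion (MOVCDN).** For each sample the m branch distributions
are combined into the view-correlation discovery tensor, the order-m outer
product M_j = yhat^1_j (x) ... (x) yhat^m_j of shape C x ... x C. Its entries
are joint view-label products, so cross-view agreement and disagreement
patterns live in distinct cells. The tensor is flattened row-major (view 1
slowest axis — fixed so checkpoints are portable), passed through a
two-layer head (C^m -> 128 -> C, LeakyReLU in between) and softmaxed into
the final distribution. m = 2 is supported for dual-omics ablations; a
single view bypasses fusion, and with fusion disabled (`use_vcdn=False`)
branch distributions are averaged.

**Joint training.** Everything is optimized together by Adam on

    L = sum_i L_Ci + delta * L_MOVCDN,      delta = 1,

where each term is a mean cross-entropy over training samples (averaging,
rather than summing, keeps the learning rate independent of cohort size).
The default hyperparameters are the published settings: 200 epochs,
learning rate 0.008, 32 heads, 16 hidden dimensions, 128 fusion units.
The paper does not name the optimizer; Adam is the standard choice for this
family of models and is config-exposed. There is no branch pretraining by
default (`pretrain_epochs=0`); the joint objective is optimized from the
first epoch.

## Graphs

Edges are cosine similarities between samples' preprocessed feature
vectors; zero-length vectors get similarity 0 by convention. Because
attention needs a neighborhood structure rather than a dense kernel, the
similarity matrix is sparsified to a target mean degree (default 10): with
k = round(avg_degree * n / 2), the threshold tau is the k-th largest
off-diagonal pair similarity and all pairs at or above tau keep their edge
(ties at tau are all retained, so the realized degree can slightly exceed
the target). Self-loops of weight 1 are always present.

Training is transductive by default: the graph spans train and test
samples, losses touch training nodes only. The source method emphasizes
that attention generalizes inductively without rebuilding the adjacency;
this is supported as a prediction mode in which a new sample is attached to
the *training* nodes only, by cosine similarity against the fitted tau, and
scored with the frozen parameters. The two modes coincide exactly when the
attachment reproduces the transductive neighborhoods (verified in tests).

## Preprocessing

Fixed order: low-quality filtering -> correlation-based selection ->
min-max normalization, with every statistic fitted on training samples and
applied to all.

* Filtering drops features whose zero fraction or missing fraction exceeds
  0.2 (both config-exposed; the source text states the rule but no
  thresholds). Surviving missing entries are imputed with the training
  median — deterministic and robust; the source drops "incomplete" data
  without defining the rule.
* Correlation-based feature selection scores each feature by its largest
  absolute Pearson correlation with any one-vs-rest class indicator
  (zero-variance columns score 0) and keeps
  k = min(ceil(0.25 * p_clean), 5000) features, ties broken by feature name.
  This is correlation *ranking* with the published caps, not Hall's
  merit-based greedy subset search: the source specifies only a
  correlation-based criterion plus the 25%/5,000 limits, and greedy merit
  search is O(p^2) at p ~ 20,000 and under-determined by the text.
* Min-max scaling uses training min/max per feature; constant features map
  to 0 and out-of-range values clip to [0, 1]. The source text reads
  "scaled to [0,1] for each sample", but per-sample scaling would destroy
  the cross-sample comparability the similarity graph depends on, so the
  package normalizes per feature. Methylation probe identifiers can be
  renamed to gene symbols through a two-column mapping table; unmapped
  probes are dropped and name collisions keep the highest-variance probe.

## Evaluation protocol and metrics

`run_experiment` repeats a stratified 70/30 split 10 times (stratification
is a deliberate strengthening of "randomly assigned": with a few hundred
samples and 4–5 classes, unstratified splits can lose a class from
training). Each repeat draws its split and fit seeds from independent
substreams of the experiment seed, so runs are bitwise reproducible and
adding repeats never perturbs earlier ones.

Metrics come from the C x C confusion matrix: accuracy (trace/total),
weighted recall, per-class F1, macro F1 (mean over all C classes; absent
classes contribute 0) and weighted F1. For single-label multiclass
predictions weighted recall equals accuracy algebraically; both are still
reported because the reporting contract lists both. Argmax ties resolve to
the lowest class code.

## Biomarker ranking

The source ranks features by a "characteristic attention weight
coefficient" that is not defined operationally (graph-attention weights
live on patient-patient edges, not on features). The package's primary
definition is masking importance: the drop in held-out weighted F1 when one
feature's column is replaced by zeros — the in-domain floor after min-max
scaling, which keeps masked inputs inside the training range (masking with
the mean would instead inject a synthetic typical value). Features removed
by preprocessing never enter the network and score exactly 0. Importance is
computed on the held-out partition only, so overfit features are not
rewarded. A gradient x input saliency score is available behind
`method="gradient_input"` and is reported alongside, never silently
substituted.

Stage-pair discovery recasts K ordered stages as K-1 adjacent binary tasks
(per-pair models, matching how the per-stage biomarker tables are
organized); each pair gets the full split -> train -> mask -> rank pipeline.
A feature is said to *surface* in a table when it has strictly positive
importance inside the top-k: a zero importance means the model provably
ignored the feature in that task, and among exact zero ties the dense
ranking is lexicographic, which carries no evidence.

## Synthetic data

The generator emulates a stage-labelled multi-omics cohort: balanced stage
labels; three views of different dimensionality; per-class mean-shifted
informative features (class c draws N(c * effect * d_j, noise_sd) with a
fixed per-feature sign d_j); methylation-like views squashed through a
logistic sigmoid so entries are strictly inside (0,1) like beta-values.
Defaults are the package's reference study conditions: n=300, C=3, s=10
informative features per view, effect 3, noise 1, with per-view
dimensionalities 200/100/150. One global seed spawns independent per-view
substreams, so adding or removing a view never changes the other views'
draws; feature columns are shuffled so position carries no ground truth.

Two optional structures exist for specific experiments:

* `shared_latent` splits the class code c = r + (C/2) b into a fine part r
  (planted only in view 1) and a coarse bit b (planted in the other views).
  Each view alone is capped at the accuracy of its partition (1/2 for
  C=4) — verified against the exact Bayes rule of the generating model —
  while the views jointly identify c. This gives the fusion ablation a
  regime where combining views provably beats any single view.
* `s_pair` plants step features whose mean shifts only across one adjacent
  stage boundary (strength `pair_effect`); such a feature separates exactly
  its own stage pair, giving the stage-pair ranking a localized ground
  truth.

What the generator does *not* emulate: count noise (values are Gaussian
before normalization — appropriate because the pipeline consumes
already-normalized [0,1] data), feature-feature correlation structure,
batch effects, missingness mechanisms beyond missing-at-random, or real
genomic coordinates. Passing tests therefore demonstrate that the
implementation recovers planted structure under the stated conditions, not
that the method attains any particular accuracy on real cohorts.

## Numerics

The networks run on a small reverse-mode autodiff engine written on NumPy
(`molungn.autodiff`); every backward rule is checked against central finite
differences in the test suite. Attention is evaluated edge-wise (O(E)
rather than O(n^2)) through a fused primitive with a hand-derived backward,
asserted equal to the dense composition of score/normalize/aggregate
operations. Softmaxes subtract the row maximum; cross-entropy probabilities
are floored at 1e-12; the training dtype is float32 (config-exposed
`compute_dtype`, float64 available for high-precision checks — the engine
preserves whatever dtype parameters and inputs carry). Dropout (0.5 by
default) and feature normalization follow each reducer layer; the
normalization is per-sample standardization, chosen over batch statistics
so evaluation is batch-size independent.

Problem sizes in the acceptance checks are the reference conditions above
for the planted-signal and null calibrations, and smaller cohorts
(n=120–180, two views, p=20–40) for the ablation and biomarker checks,
where the properties under test do not pin a cohort size.

## Known limitations

* Tables of real TCGA cohorts (sample counts, feature counts, reported
  accuracies) depend on external downloads and are out of scope; nothing
  in this package asserts performance on them.
* The "Out_dims 2" row of the published hyperparameter table contradicts
  the five-class head and is treated as non-binding bookkeeping.
* The printed aggregation formula indexes the transformed feature of node
  i inside the neighbor sum; read literally the layer would not depend on
  neighbor features, so the package implements the standard neighbor-indexed
  form.
* Masking importance measures marginal contribution; redundant features
  shadow each other, and on saturated tasks (perfect held-out F1) the
  importance of every feature is 0. The stage-pair experiment design in the
  acceptance suite accounts for this by planting individually weak base
  features.
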