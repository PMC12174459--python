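# molungn

Multi-omics cancer-stage classification with graph attention over patient
similarity networks and cross-omics tensor fusion.

## The problem

Staging a tumor from molecular data means integrating several omics views —
mRNA expression, miRNA expression, DNA methylation — measured on the same
patients, each view high-dimensional (big p) on a small cohort (small n).
`molungn` implements a two-level architecture for this task:

1. **Omics-specific graph-attention branches.** Each view X_m ∈ R^{N×D_m}
   induces a patient-similarity network with cosine-similarity edge weights
   (sparsified to a target mean degree, self-loops always present). After a
   three-layer fully connected reduction, multi-head graph-attention layers
   propagate information between similar patients:

       e_ij  = LeakyReLU(aᵀ[W h_i ‖ W h_j])
       α_ij  = softmax_{j∈N_i}(e_ij)
       h'_i  = σ( Σ_{j∈N_i} α_ij W h_j )

   ending in a per-view class distribution ŷ^m ∈ Δ^C.

2. **Cross-omics fusion.** Per sample, the view distributions form the
   discovery tensor M = ŷ¹ ⊗ ŷ² ⊗ ŷ³ (shape C×C×C), which a small two-layer
   head maps to the final stage distribution. Everything trains jointly by
   Adam on L = Σᵢ L_Cᵢ + δ·L_MOVCDN with δ = 1 (defaults: 200 epochs, lr
   0.008, 32 heads, 16 hidden dims, 128 fusion units).

The package also provides the surrounding pipeline — correlation-based
feature selection with the 25% / 5,000-feature caps, train-statistic min-max
normalization, the stratified 70/30 × 10 evaluation protocol, view-subset
and no-fusion ablations, masking-based biomarker ranking per adjacent stage
pair — plus a seeded synthetic multi-omics generator with planted ground
truth, so the whole method is testable with no external data. The neural
components run on a small NumPy reverse-mode autodiff core included in the
package (gradients are finite-difference checked in the tests).

Intended users: computational biologists evaluating multi-omics integration
strategies, and method developers who need a reproducible, dependency-light
reference implementation of this model family.

## Worked example

```python
import molungn as m

# a synthetic stage-labelled cohort with planted informative features
views, labels, truth = m.generate(m.SyntheticSpec(
    n=300, C=3, effect=3.0, noise_sd=1.0, seed=7))

model = m.MultiOmicsGAT(views, labels, m.RunConfig(seed=7))
train_ids, test_ids = m.split(labels, 0.7, seed=7)
res = model.fit(train_ids=train_ids, seed=7)
print(res.summary())
```

prints (abridged):

```
            Multi-omics graph-attention classifier
============================================================
views:            mRNA, miRNA, meth
classes (C):      3 (StageI, StageII, StageIII)
samples:          300 (train 210, test 90)
fusion:           MOVCDN tensor head
epochs/lr:        200 @ 0.008
heads/hidden:     32/16
seed:             7
------------------------------------------------------------
final total loss: 0.3332
------------------------------------------------------------
held-out metrics:
accuracy         1.0000
recall_weighted  1.0000
f1_weighted      1.0000
f1_macro         1.0000
```

With effect 3 at noise 1 the three planted views are individually strong,
so the fitted model separates the stages completely on the held-out 30%;
`final total loss` is the sum of the three branch cross-entropies plus the
fusion cross-entropy after 200 joint epochs. The full protocol
(`m.run_experiment(views, labels, m.RunConfig())`) repeats stratified
splits ten times and aggregates mean ± sd per metric; biomarkers come from
`res.feature_importance()` (masking importance: held-out weighted-F1 drop
per zeroed feature) or `m.stage_pair_biomarkers(...)` for per-stage-pair
tables.

The same pipeline is scriptable from the shell:

```bash
molungn simulate --n 300 --classes 3 --seed 7 --out-dir data/
molungn evaluate --view mRNA=data/mRNA.csv --view miRNA=data/miRNA.csv \
    --view meth=data/meth.csv --labels data/labels.csv --out-dir results/
molungn biomarkers --view mRNA=data/mRNA.csv --view miRNA=data/miRNA.csv \
    --view meth=data/meth.csv --labels data/labels.csv --k 3 --out-dir results/
```

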