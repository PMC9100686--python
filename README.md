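# amni — adaptive multimodal neuroimage integration

`amni` is a research tool for binary diagnosis from multimodal MRI — the
motivating application is separating major depressive disorder (MDD) patients
from healthy controls using resting-state functional MRI together with
T1-weighted structural MRI.  It implements a two-branch deep classifier, the
graph-construction and fusion variants needed for ablation studies, a
repeated-holdout evaluation protocol, and a seeded synthetic cohort generator
so that every stage is testable without access-restricted clinical data.

## The model

**Functional branch.** For each subject, the ROI-mean BOLD series
`Y ∈ R^{N×M}` (N ROIs, M time points) is turned into a Pearson functional
connectivity matrix `B = (b_ij)`,

    b_ij = (y_i − ȳ_i)ᵀ(y_j − ȳ_j) / (‖y_i − ȳ_i‖ ‖y_j − ȳ_j‖),

treated as a graph with node features `X = B`.  The adjacency is sparsified
(KNN graph keeping each node's k strongest connections by default; threshold
and fully-connected variants are available) and encoded by a two-layer
spectral graph convolution on the symmetrically normalized adjacency with
self-loops `Ã = D̂^{-1/2}(A + I)D̂^{-1/2}`:

    H^(l+1) = ReLU(Ã H^(l) W^(l)),     g_F = head( mean_i z_i ‖ max_i z_i ).

**Structural branch.** Gray-matter volumes pass through four 3-D convolution
blocks (3×3×3 same-padding conv, batch norm, ReLU, 2×2×2 stride-2 max-pool;
16/32/64/128 channels), global average pooling, and two fully-connected
layers (128 and 64 units, dropout 0.5), giving `g_S`.  For a 121×145×121
input the spatial chain is 121×145×121 → 60×72×60 → 30×36×30 → 15×18×15 →
7×9×7.

**Adaptation and fusion.** A cross-modal maximum-mean-discrepancy loss

    L_M = ‖ mean φ(g_F) − mean φ(g_S) ‖

(linear kernel φ = id by default) aligns the two 64-dim embeddings; the
concatenation `[g_F; g_S]` feeds a fully-connected head (64 → 2) and a
softmax.  Training minimizes `L = L_C + λ·L_M` with binary cross-entropy
`L_C` and λ = 0.01, using Adam (lr 1e-4, weight decay 0.0015, 100 epochs,
batch 16) at full scale.  Ablation variants: structural-only (`amni_s`),
functional-only (`amni_f`), no adaptation (`amni_womdd`, λ = 0), and
decision-level fusion (`amni_lf`, weighted sum of per-branch softmaxes).

The networks are implemented directly in NumPy with hand-written
backpropagation; every layer's gradients are finite-difference-checked in
the test suite.

## Worked example

A desk-scale experiment on a synthetic cohort (60 subjects, 20 ROIs, 120
time points, 24×28×24 volumes; 30 epochs with a narrow CNN):

```python
import numpy as np
from amni import (
    SyntheticCohortConfig, generate_cohort, pearson_fcn, build_knn_graph,
    TrainConfig, CNNBranchConfig, train_model, compute_metrics,
)
from amni.evaluation import stratified_split

cohort = generate_cohort(SyntheticCohortConfig(n_class0=30, n_class1=30, seed=21))
b = pearson_fcn(cohort[0].time_series)
g = build_knn_graph(b, k=10)
print(f"connectivity: {b.values.shape}, edges kept: {int(g.adjacency.sum() / 2)}")

labels = np.array([s.label for s in cohort])
train_idx, test_idx = stratified_split(labels, 0.2, np.random.default_rng(0))
cfg = TrainConfig(
    learning_rate=1e-3, epochs=30, batch_size=16, seed=0, variant="amni",
    cnn=CNNBranchConfig(conv_channels=[4, 8, 16, 32], fc_widths=(64, 64)),
)
model, history = train_model([cohort[i] for i in train_idx], cfg)
print(f"final epoch: L_C={history.final('l_c'):.4f}  "
      f"L_M={history.final('l_m'):.4f}  train_acc={history.final('train_acc'):.3f}")
m = compute_metrics(model.predict([cohort[i] for i in test_idx]))
print(f"test: ACC={m.acc:.3f}  SEN={m.sen:.3f}  SPE={m.spe:.3f}  AUC={m.auc:.3f}")
```

Output:

```
connectivity: (20, 20), edges kept: 114
final epoch: L_C=0.0804  L_M=2.6364  train_acc=1.000
test: ACC=1.000  SEN=1.000  SPE=1.000  AUC=1.000
```

The 20×20 connectivity matrix keeps 114 of 190 possible edges under k = 10
KNN sparsification; after 30 epochs the cross-entropy is near zero, the
recorded cross-modal discrepancy `L_M` has been driven down by the λ-weighted
adaptation term, and the held-out 12 subjects are classified perfectly —
this synthetic cohort is constructed to be separable when both modalities
are used together.

## Command line

```bash
amni simulate cohort/ --n-class0 150 --n-class1 150 --seed 0
amni connectome cohort/sub-0000_timeseries.tsv conn.tsv --adjacency-out adj.tsv
amni evaluate run.yaml          # repeated 80/20 holdout, eight metrics
amni compare runs/run-aaaa runs/run-bbbb   # paired t-test on probabilities
amni sweep run.yaml --lambdas 0,0.001,0.01,0.1,1
```

`run.yaml` is a schema-validated configuration (unknown keys rejected); see
`amni.io.RunConfig` for the full schema and defaults.

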