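# Methods

This note documents the modeling choices, numerical conventions and known
limitations of `amni`. It is written for a reader who wants to understand
exactly what the package computes and what its tests do and do not show.

## Connectome construction

Pearson connectivity is the centered cosine between ROI time series,
canonicalized after computation: the matrix is symmetrized, clipped to
[−1, 1], and its diagonal set to exactly 1. A zero-variance ROI is a hard
error naming the ROI (1-based, as in all log output) rather than a silent
NaN.

Graph sparsification interprets "connectivity strength" as the **absolute**
Pearson coefficient by default: a strong anticorrelation is a strong
connection, and absolute selection keeps the KNN and threshold strategies
consistent with each other. Signed selection is available behind the
`absolute` switch for both strategies, since the convention is genuinely
ambiguous.

For the KNN graph, k is a free parameter of the method; the default k = 10
is a common sparsity for connectomes of roughly 100 nodes and must be set
deliberately for other graph sizes. Per-node top-k selection is a directed
relation; the adjacency is symmetrized by logical OR (an edge survives if
either endpoint selected it), so every node has degree ≥ k. Ties at the
k-th rank break toward the lower ROI index, making graphs identical across
platforms. The threshold strategy defaults to q = 0.2 on absolute
coefficients; the fully-connected strategy uses |B| as an edge-weighted
adjacency.

Self-loops are never stored in a `ConnectivityGraph`; they are added exactly
once, inside `normalize_adjacency`, which returns
`D̂^{-1/2}(A + I)D̂^{-1/2}` with the degree matrix computed on A + I. Taking
degrees on A + I (rather than on A alone) keeps every degree strictly
positive, so isolated nodes normalize to a unit self-loop instead of a
division by zero, and the spectral radius is bounded by 1.

## The two branches

**Functional (GCN).** Node features are the raw connectivity rows (X = B);
the graph convolution `ReLU(Ã H W)` carries no bias. Two 64-unit layers are
the default; depth and width are configurable for the architecture studies,
and an over-smoothing property test documents why depth beyond two stops
helping (tied-weight propagation provably shrinks the spread of node
representations on connected graphs). The mean‖max readout is invariant
under node permutation, which the suite verifies end to end (permuting
adjacency and both axes of the node features, with first-layer weight rows
permuted identically, leaves the embedding unchanged). A single
fully-connected layer with bias and ReLU maps the 2×64 readout to a 64-dim
embedding so the two modality features are like-sized for the adaptation
loss; its width mirrors the CNN branch's 64-unit final FC layer.

**Structural (3-D CNN).** Convolutions are stride-1 with same-padding
(padding 1 for the 3×3×3 kernel), which is what makes conv stages
size-preserving; pooling is 2×2×2 stride 2 with floor division and no
padding, reproducing the 121→60→30→15→7 and 145→72→36→18→9 chains of the
full-scale architecture. `propagate_shapes` computes the whole chain
symbolically and is property-tested against actual forward shapes, so
configurations are validated before any weights are allocated. Batch
normalization uses eps 1e-5 and running-moment momentum 0.1 (unbiased
variance in the running estimate, biased in the normalization); dropout 0.5
follows *each* of the two FC layers. Input volumes are z-scored per subject
(config-exposed) since gray-matter maps arrive in arbitrary intensity
units. The branch is size-parameterized: the architecture, not the input
size, is the contract, and all desk-scale work uses 24×28×24 volumes.

**Implementation.** Both branches, the losses and the optimizer are written
directly in NumPy with explicit backpropagation; volumetric activations use
a channels-last layout so convolution im2col/col2im and batch-norm
reductions stay contiguous. Every layer's backward pass is checked against
central finite differences, and forward passes against scalar-loop oracles.
Training runs in float32; the oracle tests run the same code in float64.

## Adaptation, fusion, losses

The adaptation loss is the maximum mean discrepancy between the batch of
functional embeddings and the batch of structural embeddings of the *same*
mini-batch of subjects (batch-level alignment is the only tractable reading
of a loss term; the paired design makes the two batches equal-sized). The
default kernel map is the identity, so L_M is the Euclidean distance
between the two batch mean embeddings — the deep-domain-confusion form; an
RBF kernel with median-heuristic bandwidth (no gradient through the
bandwidth) is available. The loss is the *unsquared* norm by default,
matching its printed form; a squared option exists for smoother gradients
near zero. At zero discrepancy the subgradient 0 is used.

Feature-level fusion concatenates functional-then-structural (an arbitrary
but fixed and logged order) into FC(64)+ReLU, FC(2), softmax.
Cross-entropy is computed from the class-1 softmax probability with
probabilities clipped to [1e-7, 1−1e-7]; for two classes this is identical
to categorical cross-entropy. The total objective is `L = L_C + λ·L_M`
with λ = 0.01 by default.

Variants: `amni_s` / `amni_f` keep one branch and shrink the fusion head to
one 64-dim input (FC 64→64→2), keeping head capacity comparable;
`amni_womdd` sets λ = 0 but still *records* L_M each epoch so the effect of
the adaptation term is measurable; `amni_lf` trains two independent
per-branch classifiers (each FC 64→64→2, joint loss CE_f + CE_s, no
adaptation term) and fuses softmax outputs at decision level with weight
w_f on the functional branch.

## Training

Adam with learning rate 1e-4, weight decay 0.0015, 100 epochs and
mini-batches of 16 is the full-scale recipe. Weight decay is added to the
gradient (classic Adam + L2) for weights only — biases and batch-norm
scale/shift are exempt. There is no learning-rate schedule and no early
stopping. The last incomplete mini-batch is kept; a singleton batch is
merged into its predecessor so train-mode batch statistics stay defined.
The seed controls parameter initialization (fan-based uniform), batch
shuffling and dropout masks, via independent generators spawned from one
seed sequence; identical seeds give bit-identical parameters, history and
predictions on one machine. Evaluation always runs in eval mode (dropout
off, batch-norm running moments).

Desk-scale experiments (the synthetic-cohort studies and the acceptance
tests) use 30 epochs at learning rate 1e-3 with a narrowed CNN
([4, 8, 16, 32] channels, FC widths 64/64): a short schedule needs a larger
step size, and the narrow CNN keeps the four-block architecture while
matching the 24×28×24 inputs. These are the package's chosen desk-scale
conditions, stated here so results are reproducible.

## Evaluation protocol

Repeated random holdout: 20% test, 10 repeats by default, per-repeat seed =
base seed + repeat index, summary mean and n−1 standard deviation per
metric. Splits are stratified by class by default (a config switch restores
plain random splitting): on small cohorts unstratified 20% test sets can
lose a class entirely, which would make half the metrics undefined.

Eight metrics with the patient class (label 1) positive: ACC, SEN, SPE,
BAC = (SEN+SPE)/2, PPV, NPV, F1 (harmonic mean of PPV and SEN), and AUC by
the rank-based Mann–Whitney estimator with half-credit for ties. Metrics
whose denominator is empty are reported as NaN and *named* in an
`undefined` field, never silently zeroed. The classification threshold is
the softmax argmax (equivalently 0.5).

The paired t-test uses t = mean(d)/(sd(d)/√n) with the n−1 sample standard
deviation and a two-sided p from the t distribution with n−1 degrees of
freedom; zero-variance differences raise a dedicated error instead of
propagating NaN. For comparing two runs, per-subject class-1 test
probabilities are pooled across repeats (each test occurrence is one pair,
aligned by repeat and subject id); this pooling rule is a documented
convention of this package, since the pairing unit is otherwise
underdetermined.

## Synthetic cohorts

The generator reproduces the statistical structure the classifier assumes
and nothing more.

*Functional modality*: zero-mean multivariate normal series over a
community-block base covariance (unit variances, 0.35 within consecutive
5-ROI blocks). The patient class adds `functional_effect_delta` to a chosen
edge set; the default effect couples **two whole communities** (all 25
pairs between the first two blocks, delta 0.4). A distributed inter-network
coupling was chosen over a handful of isolated anomalous edges because it
is the standard "network dysconnectivity" regime and it matches the
inductive bias of a weight-shared graph convolution, which aggregates over
neighborhoods rather than memorizing individual edges. Positive
definiteness is enforced by convex shrinkage of the perturbation toward the
base covariance, with the smallest sufficient coefficient found by
bisection on the minimum eigenvalue (60 iterations, floor 1e-6). AR(1)
smoothing (coefficient 0.3) models temporal autocorrelation of BOLD while
leaving the stationary covariance untouched — only the covariance matters
to Pearson connectivity, so no hemodynamic response model is needed.

*Structural modality*: a smooth ellipsoidal intensity profile plus Gaussian
noise (sd 0.1); the patient class adds offsets inside spherical blobs
(default: one atrophy-like blob of −0.4 and one +0.35 blob), validated to
lie inside the volume.

*Signal routing.* `modality_signal_split` routes, per patient, which
modality expresses the class effect: a fraction `split` of patients express
only the covariance effect, the rest only the blob effect; controls express
neither. At split = 1 the class-conditional volume distributions are
identical, at split = 0 the time series carry no class signal, and at
split = 0.5 each single modality can at best identify its own half of the
patients (single-modality Bayes accuracy ≈ 0.75 on a balanced cohort) while
both together separate the classes almost perfectly. This construction
makes multimodal superiority a property of the data-generating process, not
an artifact of optimization — which is exactly what the behavioral
acceptance tests measure.

Default cohort conditions are the desk-scale study: 150+150 subjects, 20
ROIs × 120 time points, 24×28×24 volumes, split 0.5, seed-deterministic
down to the bit (subject-level generators are spawned from one seed
sequence).

*What the generator does not emulate*: hemodynamic response, motion and
physiological artifacts, site/scanner effects, registration error,
correlated confounds between modalities, class imbalance of real clinical
cohorts, and the much weaker effect sizes of real psychiatric neuroimaging
(real-data accuracies in this problem class are near 0.65, not 1.0).
Passing behavioral tests therefore show that the architecture and losses do
what they claim under their own assumptions — not that comparable accuracy
is attainable on clinical data.

## Numerical conventions and degenerate inputs

- Probabilities are renormalized in float64 after float32 softmax so stored
  prediction pairs sum to 1 within 1e-9.
- `pearson_fcn` requires nonzero-variance ROIs; readers validate
  exhaustively (manifest files, duplicate ids, non-numeric cells with
  row/column coordinates) before any training starts.
- Max-pool argmax ties take the first window position; KNN rank ties take
  the lower ROI index; both choices are deterministic.
- MMD gradients at exactly zero discrepancy use subgradient 0.
- Batch-norm in train mode requires ≥ 2 values per channel; the batching
  logic guarantees this by merging singleton batches.

## Known limitations

- Pure-NumPy training is CPU-bound; full-scale volumes (121×145×121, 16–128
  channels, 100 epochs) are far slower than a GPU implementation of the
  same architecture. The package is sized for method verification and
  desk-scale simulation studies.
- The RBF-kernel MMD ignores the gradient through its median-heuristic
  bandwidth (standard practice, but a bias near zero discrepancy).
- No attention, Chebyshev filters, edge-weighted convolution on binary
  graphs, dynamic connectivity, or image preprocessing (slice timing,
  realignment, segmentation, spatial normalization) — preprocessing is
  upstream of this package by design.
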