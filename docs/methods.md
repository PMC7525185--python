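# Methods

`circlink` predicts circRNA–disease associations from heterogeneous
similarity evidence. This note documents the model, the numerical choices,
and what the synthetic studies used for testing do and do not demonstrate.

## Problem and model

Given three binary association matrices — circRNA×disease `A` (nc×nd),
circRNA×miRNA `Y` (nc×nm) and disease×miRNA `O` (nd×nm) — the task is to
score the unobserved cells of `A`. The method has four stages.

**1. Similarity kernels.** Four circRNA kernels and up to seven disease
kernels, each a symmetric matrix with entries in [0, 1]:

* `SC_Seq` — global affine-gap alignment similarity of circRNA sequences
  (match +5, mismatch −4 as in EDNAFULL; gap open 16, gap extend 4; a gap of
  length L costs 16 + 4(L−1)). The reported value is the fraction of
  alignment columns with positive substitution score, i.e. the familiar
  "Similarity" percentage of global alignment tools, as a fraction. `N`
  scores 0 against every symbol, a deliberate collapse of the ambiguity
  rows: it makes unknown bases neutral rather than weakly penalized.
  Alignment is delegated to Biopython's `PairwiseAligner` (Gotoh
  three-state recurrence); the test suite checks it against an exhaustive
  alignment enumerator.
* `SC_RG` — regulatory similarity from shared miRNA partner sets. The
  default is the Ochiai/cosine form |Mᵢ∩Mⱼ|/√(|Mᵢ||Mⱼ|), which is 1 for
  identical sets — the property a similarity kernel's diagonal needs. The
  plain product-normalized form |Mᵢ∩Mⱼ|/(|Mᵢ||Mⱼ|) is available via
  `form="product"` for strict replication of the alternative reading.
* `SC_EP` — Pearson correlation of expression profiles, clipped below at 0.
  Clipping (rather than rescaling (r+1)/2) maps "uncorrelated or opposed"
  to "not similar", and keeps the kernel nonnegative as the fusion stage
  requires. circRNAs without a usable profile get zero rows; coverage is
  logged.
* `SC_GIP` / `SD_GIP` — Gaussian interaction-profile kernels
  K[i,j] = exp(−γ‖pᵢ−pⱼ‖²) over the rows of `Y` (resp. `O`), with the
  bandwidth γ = n / Σᵢ‖pᵢ‖² set from the mean squared profile norm.
  All-zero profiles are kept and scored by the same formula; only a fully
  zero profile *matrix* is an error (undefined bandwidth).
* `SD_Dss` — DAG-based semantic similarity. Each disease term contributes
  1 to itself and Δ per generation to its ancestors (contribution of an
  ancestor = Δ · max over its in-closure children), Δ = 0.5 by default;
  similarity is the shared-ancestor contribution mass over the two semantic
  values.
* Additional disease kernels (symptom co-occurrence, Lin, Resnik, PSB,
  SemFunSim and similar) are consumed as precomputed labeled TSV matrices;
  computing them from their primary sources is out of scope.

**2. Kernel fusion (SKF).** Each kernel is column-normalized (`NS`, the
anchor) and row-normalized over each entity's top-k neighborhood including
itself (`F`, the diffusion operator). Status matrices start at `NS` and
iterate

    S_m ← α · F_m · mean_{r≠m}(S_r) · F_mᵀ + (1−α) · mean_{r≠m}(NS_r)

with α = 0.1, k = 36 neighbors (clamped to n−1 on small entity sets) and
10 iterations. The mean over the *other* kernels uses divisor K−1; a fixed
divisor of 2 cannot be right for both a 4-kernel and a 7-kernel stack.
Because the anchor term is iteration-invariant, the update is an affine
contraction and the per-kernel relative change
‖S_m^{t+1}−S_m^t‖_F / ‖S_m^t‖_F decays geometrically at rate ≈ α; at the
defaults it is below 1e−10 by iteration 10, which is why a fixed iteration
count is used instead of a stopping tolerance. The Frobenius norm is used
for the trace. The fused kernel is the mean of the final status matrices,
masked elementwise by mutual-neighbor weights (1 mutual, 0.5 one-sided,
0 neither; neighborhoods derived from the averaged matrix itself, self
included) and then symmetrized — the cross-diffusion update does not
guarantee symmetry and downstream feature rows assume it. An element-wise
mean (`average_fusion`) is provided as the comparison baseline.

**3. Pair features.** Each (cᵢ, dⱼ) pair becomes a 2×(nc+nd+np) matrix:
fused circRNA similarities over A's column for dⱼ; A's row for cᵢ over
fused disease similarities; and the two miRNA profiles Y[i,·], O[j,·]
compressed to np = 50 principal-component scores. The PCA is fitted once on
the mean-centered row-stack of Y and O (no whitening, scores used raw) —
the stack carries no pair labels, so one fit is shared across folds without
leakage. As literally assembled, the feature matrix contains A[i,j] itself
twice; `mask_label=True` (the default for training and CV) zeroes those two
cells so the classifier cannot read its target off its input. The unmasked
construction remains available for replication.

**4. Classifier.** A two-layer CNN: 8 filters of 2×32 (spanning both
feature rows), 8 filters of 1×16, both valid (no padding) with ReLU; global
max-pooling per filter map; dropout 0.5 on the pooled 8-vector; a dense
layer to two softmax units. For feature width W the maps are
1×(W−31)×8 then 1×(W−46)×8. The network is implemented directly in numpy —
forward, analytic backpropagation and Adam — which keeps training
bit-reproducible from a single seed; the analytic gradients are verified
against central differences (tolerance 1e−4) in the test suite. Training
defaults — Adam, learning rate 1e−3, 50 epochs, batch 32, cross-entropy —
are this package's choices for the small-sample regime; they are not
dictated by the method and are all exposed in `CnnConfig`. Inverted
dropout is used (activations scaled by 1/keep at train time), so inference
needs no rescaling and is deterministic.

## Evaluation protocol

Positives are the known pairs of `A`; each repetition of cross-validation
draws a fresh negative sample, uniform without replacement over the zero
cells, of the same size as the positive set, and splits positives and
negatives into parallel folds (one negative fold accompanies each positive
test fold). Metrics: precision, sensitivity, accuracy, F1, Matthews
correlation at threshold 0.5 (softmax argmax), and AUC by the Mann–Whitney
rank statistic with midranks. Metrics with a zero denominator are reported
as NaN with a warning and excluded from means. Candidate ranking averages
the scores of several trained models — conventionally the ten models from
the repeated-CV negative samples — with deterministic tie-breaking by
(score desc, circRNA id asc).

One protocol question is open in the method's description: whether one
negative sample is shared by the 5 folds of a repetition or resampled per
fold. We sample once per repetition — resampling per fold would let a
pair appear as a training negative and a test negative within the same
repetition.

## Synthetic studies

Real inputs of this kind (curated association databases, expression
compendia, sequence databases, disease ontologies) cannot ship with a test
suite, so the generator plants the very structure the method's premises
assume: circRNAs, diseases and miRNAs fall into communities; association
probability is `within_block` (0.6) inside a community and `background`
(0.02) across; expression rows are community centroids plus Gaussian noise
(σ = 0.5); sequences are community consensi with 10% point mutations
(length 240); the disease DAG places each disease under its community's
parent term; and five noisy block-structured matrices stand in for the
externally precomputed disease kernels, giving the disease side its full
complement of seven. Default sizes are 40 circRNAs × 15 diseases × 60
miRNAs in 3 blocks — large enough for every stage to operate (including
np = 50 PCA scores and clamped 14-neighbor fusion) while keeping a full
repeated-CV run in tens of seconds. Expression profiles have 90 conditions,
matching the width of the exosomal profiles the expression kernel is
designed for. Every miRNA-profile row is guaranteed at least one link so
no kernel degenerates.

What passing on these studies shows: each kernel ranks within-community
pairs above cross-community pairs; fusion converges and preserves that
signal; the classifier recovers held-out planted associations well above
chance (mean AUC ≥ 0.8 at the default spec) while a label-shuffled control
stays at chance (AUC ≈ 0.5). What it does not show: performance on real
curated data, whose degree distributions are heavy-tailed, whose kernels
disagree more, and whose "negatives" are merely unobserved. The planted
blocks are an easier, cleaner world; results here validate the machinery,
not the biology.

## Numerical choices and edge cases

* Registries sort identifiers lexicographically; all matrices are
  byte-reproducible from the same inputs. Identifiers are opaque and
  case-sensitive; no vocabulary normalization is attempted.
* Kernel TSVs are written at 17 significant digits; read→write→read is the
  identity to better than 1e−12 relative. Read kernels are symmetrized
  (K+Kᵀ)/2 — an exact no-op for symmetric input — with a warning when the
  asymmetry exceeds 1e−8; negative entries are refused.
* Top-k neighborhoods break ties by registry order (stable argsort), making
  sparsification and the mutual-neighbor mask deterministic.
* Column normalization refuses all-zero columns; sparsification refuses
  rows with zero neighborhood mass — both name the offending entity.
* Entities missing an input (sequence, expression profile, DAG term) get
  zero similarity rows and a logged coverage warning; a kernel stack with
  fewer than two kernels on a side is a configuration error.
* Global max-pool ties resolve to the first index (numpy argmax), so
  scoring is deterministic; batch and per-sample scoring agree to
  summation-order rounding.
* All stochastic stages (generation, negative sampling, fold assignment,
  weight init, batch shuffling, dropout) draw from seeded
  `numpy.random.Generator`s; derived seeds stay below 2³¹.

## Limitations

* The two-class softmax head follows the method's published form; a single
  sigmoid unit would be equivalent and cheaper.
* The numpy CNN targets small studies (hundreds to thousands of pairs);
  it does not use a GPU and is not meant for large-scale screens.
* Sequence similarity is O(L²) per pair and O(n²) pairs; for hundreds of
  full-length circRNAs this is the dominant kernel cost.
* The label-masking default departs from the literal feature construction;
  unmasked replication mode exists but reports optimistic metrics, since
  the input then contains the answer.
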