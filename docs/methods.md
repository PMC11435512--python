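# Methods

This note documents the model implemented by the package, the
conventions chosen where the method family leaves details open, and
what the synthetic fixtures do and do not demonstrate.

## Model overview

The package adapts a frozen vision–language encoder pair to C-way
few-shot classification. All quantities live in the encoder's
D-dimensional embedding space; every embedding is kept at unit L2 norm
(the wrappers renormalize defensively), so inner products are cosines.

Four classifiers share one pipeline, each adding a component:

1. **Zero-shot**: `logits = s · f W_Cᵀ`, with `s` the logit temperature
   (default 1.0 in core math; a real encoder adapter would supply its
   learned temperature).
2. **Cache adapter**: adds `α · exp(−β(1 − f Fᵀ)) L`, where the cache
   keys F are the CK shot embeddings in class-major order and L their
   one-hot labels. The affinity `exp(−β(1−cos))` lies in
   `[e^(−2β), 1]` for unit vectors.
3. **Trilateral (training-free)**: restricts the cache comparison to
   the E most informative channels and reweights each cache key by
   `exp(γ·KL(label ∥ prediction))`, its zero-shot "difficulty" score.
4. **Trained branch**: learns per-class residuals on the refined
   channels, the per-key cache scores, and a squeeze-and-excitation
   gate over the classifier-weight channels, with everything else
   frozen.

## Prompt fusion

Per class, M prompt embeddings `X_i (M×D)` are fused by self-similarity
cross-attention: `A = softmax(X_i X_iᵀ)` row-wise, `a_i` = column mean
of `A X_i`, renormalized. Conventions:

- **Softmax axis**: row-wise — each prompt attends over all prompts of
  its class. The row mean then makes the result permutation-invariant.
- **No 1/√D scaling** by default: the attention scores are cosines in
  [−1, 1] already, so no variance correction is needed; a scaled
  variant is available (`scaled=True`).
- **Renormalization of `a_i`**: enabled by default so the zero-shot
  term stays a bounded cosine classifier; disable with
  `normalize=False`.
- **Average mode** (`mode="average"`) replaces attention with the plain
  row mean — the average-ensemble baseline used in ablations.

The fused vector is a convex combination of the prompt rows before
renormalization (attention weights are row-stochastic), which the test
suite checks by non-negative least squares.

## Prior refinement (channel selection)

Channel `d` is scored by the inter-class dispersion of the classifier
weights, `S_d = Σ_{i≠j} (W_C[i,d] − W_C[j,d])² / (C(C−1))`
(equivalently `2C²·Var_d/(C(C−1))`), and the top-E channels are kept,
ties breaking to the lower index. This score is this package's
definition of "most informative": channels on which the class
prototypes disagree most are the ones a cosine classifier can use.
Masked views of `f`, `F` and `W_C` are renormalized to unit length so
`(1 − cos)` stays in [0, 2] and affinity bounds still hold. Selecting
all D channels is implemented as an exact identity (no renormalization
round-off), so refinement can be switched off without numerical
side-effects.

## Cache scores

For cache key k, the prediction is `softmax(s·F'[k] W_C'ᵀ)` and the
label distribution is its one-hot row smoothed by ε = 1e-6. The score
is `exp(γ·D_KL(label ∥ prediction))`; the KL is taken in this direction
because it is always finite (≈ −log p_true up to smoothing). With
γ > 0 the score *up-weights* keys the zero-shot classifier gets wrong
— the sign convention follows the formula as printed in this method
family — and γ < 0 is allowed in configuration for the opposite
convention. γ = 0 gives exactly all-ones (the unweighted cache).

## Trained branch

- **Squeeze**: the excitation input `y` is the D-vector of per-channel
  means of `W_C` over classes. A literal single-scalar pooling would
  collapse λ to one global gate and could not re-rank channels; the
  scalar reading remains selectable (`squeeze="scalar"`) for audit.
- **Gate**: `λ = sigmoid(W₂ ReLU(W₁ y))` with hidden width
  `max(1, D // r)`; reduction r defaults to 32.
- **Residuals**: `Res (C×E)` is padded with zeros into the D-channel
  weight matrix at the refined-channel positions and broadcast onto
  each class's K cache keys. Residual-shifted cache keys are *not*
  renormalized — the residual is a learned offset off the sphere.
- **Loss**: cross-entropy on the final logits (the standard choice for
  this adapter family; the method leaves it unstated).
- **Optimizer**: AdamW (weight decay 0 by default at this parameter
  count), cosine decay from the base rate to 0 across epochs, no
  warmup. Batch size 256 exceeds nearly every shot set, so training is
  effectively full-batch.
- **Initialization**: `Res = 0`, `W₂ = 0` (so λ ≡ 0.5 exactly: a pure
  rescale of the zero-shot term that preserves its argmax), cache
  scores at their training-free KL values, `W₁` random scaled by 1/√D.
  Epoch-0 behavior is therefore analytically checkable. Note that
  initial-state argmax agreement with the training-free classifier is a
  property of fixtures where the zero-shot and cache terms agree on the
  winner (all anchored fixtures here), not an algebraic identity: the
  0.5-scaled zero-shot term could in principle flip a decision where
  the two terms disagree strongly.
- **Gradients** are computed analytically in numpy (the computation
  graph is short: two linear maps, a sigmoid, an exponential affinity,
  a softmax) and validated against central finite differences to 2e-5
  in the test suite. SE weights are trained jointly with the residuals
  and scores, since the gate matrices are declared learnable.
- The cache F and L are bit-frozen: the trainer never writes to them,
  and tests compare raw bytes before and after.

Trainable scalar count: `C·E + CK + 2·D·⌊D/r⌋` with the gate,
`C·E + CK` without.

## Synthetic fixtures

The generators emulate the *geometry* the adapters rely on, not real
encoders:

- Class prototypes are random orthonormal unit vectors (random unit
  vectors with a distinctness guarantee when C > D).
- Image and prompt embeddings are `normalize(prototype + σ·gaussian)` —
  an approximate von-Mises–Fisher draw with a single noise dial σ.
  σ = 0 gives exactly separable data (nearest-prototype accuracy 1.0);
  σ ≈ 0.3 is the standard "noisy" condition used in the experiment
  harness and acceptance report.
- Toy images give each class a distinct base color and stripe period
  (zero-mean modulation, so the mean color identifies the class and the
  co-occurrence contrast identifies the period), which is what the
  color/GLCM clustering needs to recover planted appearance clusters.
- The mock encoder hashes content into a seeded unit vector; anchored
  mode places labeled items near their class prototype. The mock
  captioner emits a deterministic sentence embedding the class name and
  coarse color/texture statistics.

Consequences: passing tests demonstrate the *mathematics* of the
pipeline — oracle equivalence, reduction identities, invariances,
recovery on separable geometry, training convergence — on conditions
where the optimal classifier is known. They do not demonstrate
performance on real leaf imagery, real CLIP-style embedding geometry
(anisotropy, hubness), or real captioner quality; those require
pretrained encoders and a live captioner, which are deliberately
outside the offline test scope.

## Feature extraction conventions

- Grayscale for the co-occurrence matrix: ITU-R 601 luma, uniformly
  quantized to 8 levels; distance {1}; angles {0°, 45°, 90°, 135°}
  averaged; symmetric, normalized matrix; Haralick contrast,
  correlation, energy, homogeneity. All exposed in `GLCMConfig`.
- Correlation of a constant image is the 0/0 case and is defined as 1.
- Before clustering, features are z-scored within the class
  (zero-variance dimensions dropped) so 0–255 color scales do not
  dominate texture statistics; k equals M so each cluster contributes
  exactly one representative (the image nearest its centroid, ties and
  collisions to the lowest unused index). K-means uses k-means++ with
  10 restarts and a fixed seed.

## Experiment harness

Splits are per-class 8:1:1 (proportional floors, ≥ 1 per partition,
remainder to train); shot sets are drawn from the train partition
without replacement; validation and test are evaluated on their full
partitions. The hyperparameter grid is α log-spaced over [0.1, 5]
(8 points), β linear over [1, 10] (6 points),
γ ∈ {0, ±0.1, ±0.5, ±1}; ties break to the smallest (α, β, |γ|), so
the search is enumeration-order independent. Reported accuracies are
rounded half-up to two decimals. Every random draw descends from the
experiment seed through named sub-streams.

## Problem sizes

The test suite and acceptance script run on small instances chosen to
make exhaustive oracles practical: C ≤ 4 classes, D ≤ 32 dimensions,
K ≤ 4 shots, 50 random instances for oracle comparisons, 25 test items
per class, and 30-epoch training runs. These sizes exercise every code
path (the implementation is vectorized and scales to realistic C, D in
the thousands) while keeping the full suite under a few seconds.

## Known limitations

- The real-encoder adapter is an interface only; no pretrained weights
  ship with the package and CI never exercises a real model.
- The captioner interface is single-turn; multi-turn querying or
  prompt-quality scoring is out of scope.
- The cache design requires shots for every known class and does not
  generalize to unseen classes.
- `exp(γ·KL)` can overflow for extreme γ with confidently-wrong cache
  keys; the implementation raises rather than clamping.
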