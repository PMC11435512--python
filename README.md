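# vlcd

Few-shot crop-disease classification over frozen vision–language
embeddings.

Identifying plant leaf diseases from images normally takes thousands of
labeled examples per disease. Pre-trained vision–language models change
the economics: a frozen image encoder and text encoder map leaf photos
and disease descriptions into a shared D-dimensional space, and a
classifier can be assembled from a handful of labeled images ("shots")
per class plus a few sentences describing each disease. This package
implements that adapter family end to end — representative-image
selection, prompt-ensemble classifier weights, a training-free
key-value cache classifier, and a lightweight trained branch — over a
pluggable encoder interface, with deterministic mock backends so the
whole pipeline runs and is tested entirely offline.

## The method

Let `f ∈ R^D` be a unit-norm test-image embedding, `W_C ∈ R^{C×D}` the
per-class classifier weights, and the cache hold keys
`F ∈ R^{CK×D}` (embeddings of the K shots per class, class-major) with
one-hot values `L ∈ R^{CK×C}`.

**Classifier weights from prompt ensembles.** Each class `i` has M
free-text descriptions, encoded to `X_i ∈ R^{M×D}`. They are fused by
cross-attention over the prompt axis:

    S_i = X_i X_iᵀ,  A = softmax(S_i),  a_i = mean-rows(A X_i),

renormalized to unit length, and stacked into `W_C = [a_1; …; a_C]`.
Descriptions are produced by a captioner backend queried about
representative images of each class — M per class, chosen by K-means
over mean-color + GLCM texture features — or supplied directly as JSON.

**Training-free inference.** Three relations combine into the logits:

    R_fW    = s·f W_Cᵀ                                (zero-shot)
    R_f'F'  = exp(−β(1 − f' F'ᵀ))                     (cache affinity)
    R_F'W'  = exp(γ·KL(L ∥ softmax(s·F' W_C'ᵀ)))      (cache scores)

    logits  = R_fW + α · R_f'F' (diag(R_F'W') L)

where primes denote prior refinement: the E channels of `W_C` with the
largest inter-class dispersion, with masked vectors renormalized.

**Trained branch.** Keeping F and L frozen, training learns per-class
residuals `Res ∈ R^{C×E}` (padded into `W_C`, broadcast onto cache
keys), per-key cache scores, and a squeeze-and-excitation gate
`λ = σ(W₂ ReLU(W₁ y))` that rescales the channels of `W_C`. The loss is
cross-entropy on the combined logits, optimized with AdamW and a cosine
schedule (30 epochs, lr 0.001, SE reduction r = 32 by default).

## Worked example

```python
import numpy as np
from vlcd import (SyntheticSpec, make_class_prototypes, make_synthetic_embeddings,
                  make_synthetic_prompt_embeddings, build_classifier_weights,
                  ZeroShotClassifier, TrilateralCacheClassifier, ResidualTunedClassifier)
from vlcd.synthetic import make_test_embeddings

spec = SyntheticSpec(n_classes=4, shots_per_class=4, dim=32,
                     prompts_per_class=3, noise_scale=0.3, seed=0)
protos = make_class_prototypes(spec)
train = make_synthetic_embeddings(spec, protos)
test = make_test_embeddings(spec, protos, per_class=25)
W_C = build_classifier_weights(make_synthetic_prompt_embeddings(spec, protos))

zs = ZeroShotClassifier(weights=W_C).fit()
vlcd = TrilateralCacheClassifier(weights=W_C, alpha=1.0, beta=5.5, gamma=0.1,
                                 n_channels=16).fit(train.features, train.labels)
vlcdt = ResidualTunedClassifier(weights=W_C, alpha=1.0, beta=5.5, gamma=0.1,
                                n_channels=16, epochs=30, reduction=4,
                                random_state=0).fit(train.features, train.labels)
for name, est in [("zero-shot", zs), ("vlcd", vlcd), ("vlcd-t", vlcdt)]:
    acc = 100 * (est.predict(test.features) == test.labels).mean()
    print(f"{name:9s} test accuracy: {acc:.2f}%")
```

prints

```
zero-shot test accuracy: 79.00%
vlcd      test accuracy: 87.00%
vlcd-t    test accuracy: 86.00%
```

Four synthetic disease classes, four shots each, at noise 0.3: the
prompt-only zero-shot classifier reaches 79%, and blending in the
few-shot cache lifts accuracy by 8 points. (At this noise level and
shot count the trained branch matches the training-free one; its
advantage grows with harder fixtures and more epochs.)

The same pipeline is scriptable from the shell — see `vlcd --help` for
the stage-by-stage subcommands (`fixtures`, `features`, `reps`,
`prompts`, `encode`, `fuse`, `cache`, `eval`, `train`, `experiment`).

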