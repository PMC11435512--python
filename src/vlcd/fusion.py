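"""Cross-attention fusion of per-class prompt ensembles into classifier
weights.

For class i with prompt embeddings X_i (M x D, unit rows), the fused
weight row is

    S_i = X_i X_i^T                (pairwise prompt similarities)
    A   = softmax(S_i)             (row-wise; each prompt attends over all)
    AW  = A X_i                    (attention-weighted prompt vectors)
    a_i = mean over rows of AW     (then renormalized to unit length)

Stacking a_i over classes gives the classifier weight matrix W_C
(C x D).  With ``mode="average"`` the attention step is skipped and a_i
is the plain mean of the prompt rows — the average-ensemble baseline.

No 1/sqrt(D) attention scaling is applied by default (the similarity
scores are cosines in [-1, 1] already); a scaled variant is available
behind ``scaled=True``.  Renormalization of a_i keeps the zero-shot
logits within [-logit_scale, logit_scale]; it can be disabled.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

__all__ = ["intra_class_attention", "build_classifier_weights"]


def intra_class_attention(
    X: np.ndarray,
    mode: str = "attention",
    scaled: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Fuse an (M, D) prompt-embedding matrix into a single D-vector."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"expected a non-empty (M, D) matrix, got shape {X.shape}")
    if mode not in ("attention", "average"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    if mode == "average":
        a = X.mean(axis=0)
    else:
        S = X @ X.T
        if scaled:
            S = S / np.sqrt(X.shape[1])
        A = softmax(S, axis=1)
        a = (A @ X).mean(axis=0)
    if normalize:
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("fused vector is zero; cannot normalize")
        a = a / n
    return a


def build_classifier_weights(
    X_list: list[np.ndarray],
    mode: str = "attention",
    scaled: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Stack per-class fused vectors into the (C, D) weight matrix W_C,
    preserving class order."""
    if not X_list:
        raise ValueError("need at least one class")
    dims = {np.asarray(X).shape[-1] for X in X_list}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding dimensions across classes: {sorted(dims)}")
    return np.vstack(
        [intra_class_attention(X, mode=mode, scaled=scaled, normalize=normalize) for X in X_list]
    )
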