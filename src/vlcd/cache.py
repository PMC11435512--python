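"""Training-free cache-model inference.

Given unit-norm test features f, classifier weights W_C (one fused
prompt row per class) and a few-shot cache (keys F: CK x D unit rows in
class-major order, values L: CK x C one-hot), the final logits combine
three relations:

    R_fW    = s * f W_C^T                     zero-shot cosine logits
    R_f'F'  = exp(-beta (1 - f' F'^T))        test-to-cache affinity
    R_F'W'  = exp(gamma * KL(L || softmax(s * F' W_C'^T)))
                                              per-key cache scores

    logits  = R_fW + alpha * R_f'F' (diag(R_F'W') L)

where primes denote the prior-refinement view: the E most informative
channels (ranked by inter-class dispersion of W_C), with masked vectors
renormalized to unit length so affinities stay within [e^(-2 beta), 1].
``alpha`` balances cache against zero-shot evidence, ``beta`` sharpens
the affinity, and ``gamma`` scales how strongly cache keys that the
zero-shot classifier handles poorly are reweighted (it may be negative,
which down-weights them instead).

Setting alpha=0 recovers pure zero-shot logits; gamma=0 makes all cache
scores 1; E=D makes the refined view identical to the full one.  The
plain cache adapter (no refinement, no scores) is ``tip_adapter_logits``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = [
    "CacheModel",
    "TrilateralParams",
    "build_cache",
    "zero_shot_logits",
    "refine_channels",
    "apply_mask",
    "cache_affinity",
    "cache_scores",
    "vlcd_logits",
    "tip_adapter_logits",
]

KL_EPS = 1e-6


@dataclass(frozen=True)
class TrilateralParams:
    """Scalars of the trilateral combination.

    alpha >= 0 balances the cache term; beta > 0 smooths the affinity;
    gamma scales the KL cache scores (sign selects up-/down-weighting);
    logit_scale > 0 is the cosine-logit temperature (1.0 in core math).
    """

    alpha: float = 1.0
    beta: float = 5.5
    gamma: float = 0.1
    logit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.logit_scale <= 0:
            raise ValueError("logit_scale must be > 0")


@dataclass
class CacheModel:
    """Frozen key-value cache: unit keys F (CK x D, class-major) and
    one-hot values L (CK x C)."""

    F: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.F.ndim != 2 or self.L.ndim != 2 or self.F.shape[0] != self.L.shape[0]:
            raise ValueError("F and L must be matrices with equal row counts")
        row_sums = self.L.sum(axis=1)
        if not (np.all(row_sums == 1) and np.all((self.L == 0) | (self.L == 1))):
            raise ValueError("L rows must be one-hot")
        if not np.allclose(np.linalg.norm(self.F, axis=1), 1.0, atol=1e-6):
            raise ValueError("F rows must be unit norm")

    @property
    def n_classes(self) -> int:
        return self.L.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.L.argmax(axis=1)

    @property
    def shots(self) -> int:
        return self.F.shape[0] // self.n_classes


def build_cache(features: np.ndarray, labels: np.ndarray, K: int | None = None) -> CacheModel:
    """Assemble the cache from labeled unit features.

    Takes the first K rows of every class (in input order), stacking
    class-major.  K defaults to the smallest class count; a class with
    fewer than K rows is an error.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.arange(labels.max() + 1)
    counts = np.bincount(labels, minlength=len(classes))
    if K is None:
        K = int(counts.min())
    if K < 1:
        raise ValueError("K must be >= 1")
    short = [int(c) for c in classes if counts[c] < K]
    if short:
        raise ValueError(f"classes {short} have fewer than K={K} labeled rows")
    rows, value_rows = [], []
    C = len(classes)
    for c in classes:
        idx = np.flatnonzero(labels == c)[:K]
        rows.append(features[idx])
        one_hot = np.zeros((K, C))
        one_hot[:, c] = 1.0
        value_rows.append(one_hot)
    return CacheModel(np.vstack(rows), np.vstack(value_rows))


def _as_batch(f: np.ndarray) -> tuple[np.ndarray, bool]:
    f = np.asarray(f, dtype=float)
    if f.ndim == 1:
        return f[None, :], True
    if f.ndim == 2:
        return f, False
    raise ValueError(f"expected a vector or matrix of features, got ndim={f.ndim}")


def zero_shot_logits(f: np.ndarray, W: np.ndarray, logit_scale: float = 1.0) -> np.ndarray:
    """Cosine logits: logit_scale * f W^T (per class)."""
    fb, single = _as_batch(f)
    W = np.asarray(W, dtype=float)
    if fb.shape[1] != W.shape[1]:
        raise ValueError(f"feature dim {fb.shape[1]} != weight dim {W.shape[1]}")
    out = logit_scale * fb @ W.T
    return out[0] if single else out


def refine_channels(W_C: np.ndarray, E: int) -> np.ndarray:
    """Indices of the E channels with the largest inter-class dispersion.

    The score of channel d is the mean squared difference of W_C[:, d]
    over all ordered class pairs, sum_{i != j} (W_id - W_jd)^2 / (C(C-1)).
    Ties break toward the lower channel index; the returned mask is
    strictly increasing.
    """
    W_C = np.asarray(W_C, dtype=float)
    C, D = W_C.shape
    if not 1 <= E <= D:
        raise ValueError(f"E must be in [1, {D}], got {E}")
    if C < 2:
        raise ValueError("need at least two classes to rank channels")
    # sum_{i != j} (w_i - w_j)^2 = 2 C^2 Var_d  (population variance)
    scores = 2.0 * C * C * W_C.var(axis=0) / (C * (C - 1))
    order = np.lexsort((np.arange(D), -scores))  # score desc, index asc
    return np.sort(order[:E])


def apply_mask(X: np.ndarray, mask: np.ndarray, renormalize: bool = True) -> np.ndarray:
    """Restrict features to the masked channels; by default renormalize
    rows to unit length so cosine geometry is preserved on the subspace."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask)
    if mask.size == X.shape[-1]:
        return X  # full mask: selection is the identity, skip renormalization
    sub = X[..., mask]
    if renormalize:
        norms = np.linalg.norm(sub, axis=-1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("masked feature has zero norm; mask too aggressive")
        sub = sub / norms
    return sub


def cache_affinity(f_masked: np.ndarray, F_masked: np.ndarray, beta: float) -> np.ndarray:
    """exp(-beta (1 - f' F'^T)): in (0, 1], equal to 1 iff f' equals a key."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    fb, single = _as_batch(f_masked)
    out = np.exp(-beta * (1.0 - fb @ np.asarray(F_masked, dtype=float).T))
    return out[0] if single else out


def cache_scores(
    F_masked: np.ndarray,
    W_masked: np.ndarray,
    L: np.ndarray,
    gamma: float,
    logit_scale: float = 1.0,
    eps: float = KL_EPS,
) -> np.ndarray:
    """Per-key scores exp(gamma * KL(smoothed label || prediction)).

    The prediction for key row k is softmax over classes of
    logit_scale * F'[k] W'^T; the label distribution is the one-hot row
    of L smoothed by eps.  gamma = 0 gives all-ones (unweighted cache);
    positive gamma up-weights keys the zero-shot classifier gets wrong.
    """
    F_masked = np.asarray(F_masked, dtype=float)
    W_masked = np.asarray(W_masked, dtype=float)
    L = np.asarray(L, dtype=float)
    C = W_masked.shape[0]
    p = softmax(logit_scale * F_masked @ W_masked.T, axis=1)
    q = (1.0 - eps) * L + eps / C
    d = np.sum(q * (np.log(q) - np.log(p)), axis=1)
    with np.errstate(over="ignore"):
        scores = np.exp(gamma * d)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite cache score; |gamma| too large")
    return scores


def vlcd_logits(
    f: np.ndarray,
    W_C: np.ndarray,
    cache: CacheModel,
    mask: np.ndarray,
    params: TrilateralParams,
) -> np.ndarray:
    """Trilateral logits: full-D zero-shot term plus the refined,
    score-reweighted cache term."""
    fb, single = _as_batch(f)
    r_fw = zero_shot_logits(fb, W_C, params.logit_scale)
    fp = apply_mask(fb, mask)
    Fp = apply_mask(cache.F, mask)
    Wp = apply_mask(W_C, mask)
    aff = cache_affinity(fp, Fp, params.beta)
    scores = cache_scores(Fp, Wp, cache.L, params.gamma, params.logit_scale)
    out = r_fw + params.alpha * aff @ (scores[:, None] * cache.L)
    return out[0] if single else out


def tip_adapter_logits(
    f: np.ndarray,
    W: np.ndarray,
    cache: CacheModel,
    params: TrilateralParams,
) -> np.ndarray:
    """Plain cache-adapter logits: R_fW + alpha * R_fF L on all channels,
    without channel refinement or cache scores."""
    fb, single = _as_batch(f)
    r_fw = zero_shot_logits(fb, W, params.logit_scale)
    aff = cache_affinity(fb, cache.F, params.beta)
    out = r_fw + params.alpha * aff @ cache.L
    return out[0] if single else out
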