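"""Training-required branch: SE channel attention over classifier
weights, learnable per-class residuals, and learnable cache scores.

The cache (keys F, values L) stays frozen.  The trainable state is

* ``res``          — per-class residuals on the E refined channels (C x E),
* ``cache_scores`` — one scalar per cache key (CK), initialized from the
  KL-based training-free scores,
* ``W1``/``W2``    — the squeeze-and-excitation gate: per-channel means of
  W_C are squeezed through a bottleneck of width max(1, D // r) and a
  sigmoid produces per-channel gates lambda in (0, 1) that rescale W_C.

Forward pass (batch f, refined view f'):

    W_att  = lambda * W_C                       (or W_C with SE off)
    R_fW   = s * f (W_att + Pad(res))^T
    R_f'F' = exp(-beta (1 - f' (F' + Expand(res))^T))
    logits = R_fW + alpha * R_f'F' (diag(cache_scores) L)

``Pad`` scatters the E residual channels into the D-channel weight
matrix (zeros elsewhere); ``Expand`` broadcasts the per-class residual
onto that class's K cache keys.  The loss is cross-entropy on the
logits, optimized with AdamW and a cosine learning-rate schedule.

Because every trainable parameter enters the logits through a short,
explicit computation graph, the gradients are computed analytically in
numpy (no autodiff dependency); they are validated against central
finite differences in the test suite.

Initialization is chosen so that epoch 0 is analytically checkable:
res = 0, W2 = 0 (hence lambda = 0.5 uniformly, a pure rescale that
preserves the zero-shot argmax) and cache scores equal to their
training-free values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cache import CacheModel, TrilateralParams, apply_mask, cache_scores

__all__ = [
    "SEModule",
    "TrainState",
    "TrainConfig",
    "se_forward",
    "apply_residuals_text",
    "apply_residuals_cache",
    "init_train_state",
    "vlcdt_logits",
    "train_vlcdt",
    "count_trainable_parameters",
]


@dataclass
class SEModule:
    """Squeeze-and-excitation gate over the channel axis of W_C."""

    W1: np.ndarray  # (hidden, D)
    W2: np.ndarray  # (D, hidden)
    r: int
    squeeze: str = "vector"  # "vector": per-channel means; "scalar": audit mode

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("reduction ratio r must be >= 1")
        if self.W1.shape[0] != self.W2.shape[1] or self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError("W1 and W2 shapes are not transpose-compatible")
        if self.squeeze not in ("vector", "scalar"):
            raise ValueError(f"unknown squeeze mode {self.squeeze!r}")

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]


def make_se_module(dim: int, r: int, seed: int = 0, squeeze: str = "vector") -> SEModule:
    """Fresh SE module: W1 random (scaled 1/sqrt(D)), W2 zero so the
    initial gates are exactly 0.5."""
    import warnings

    hidden = dim // r
    if hidden < 1:
        warnings.warn(f"r={r} exceeds dim={dim}; clamping hidden width to 1", stacklevel=2)
        hidden = 1
    rng = np.random.default_rng([seed, 10])
    W1 = rng.standard_normal((hidden, dim)) / np.sqrt(dim)
    W2 = np.zeros((dim, hidden))
    return SEModule(W1, W2, r, squeeze)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _squeeze_vector(W_C: np.ndarray, mode: str) -> np.ndarray:
    if mode == "scalar":
        # literal global average pooling to one scalar, broadcast back
        return np.full(W_C.shape[1], W_C.mean())
    return W_C.mean(axis=0)


def se_forward(W_C: np.ndarray, se: SEModule) -> np.ndarray:
    """Gated weights W_att = lambda * W_C with lambda = sigmoid(W2 relu(W1 y))."""
    W_C = np.asarray(W_C, dtype=float)
    if W_C.shape[1] != se.W1.shape[1]:
        raise ValueError("SE module dimension does not match W_C")
    y = _squeeze_vector(W_C, se.squeeze)
    lam = _sigmoid(se.W2 @ np.maximum(se.W1 @ y, 0.0))
    return W_C * lam[None, :]


def se_gates(W_C: np.ndarray, se: SEModule) -> np.ndarray:
    """The per-channel gates lambda in (0, 1)."""
    y = _squeeze_vector(np.asarray(W_C, dtype=float), se.squeeze)
    return _sigmoid(se.W2 @ np.maximum(se.W1 @ y, 0.0))


def apply_residuals_text(W_att: np.ndarray, res: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """W_att + Pad(res): residual channel j lands on full channel mask[j]."""
    W_att = np.asarray(W_att, dtype=float)
    res = np.asarray(res, dtype=float)
    if res.shape != (W_att.shape[0], len(mask)):
        raise ValueError(
            f"res shape {res.shape} incompatible with C={W_att.shape[0]}, E={len(mask)}"
        )
    padded = np.zeros_like(W_att)
    padded[:, np.asarray(mask)] = res
    return W_att + padded


def apply_residuals_cache(F_masked: np.ndarray, res: np.ndarray) -> np.ndarray:
    """F' + Expand(res): class c's residual row is added to each of that
    class's K cache rows (class-major ordering assumed)."""
    F_masked = np.asarray(F_masked, dtype=float)
    res = np.asarray(res, dtype=float)
    CK, E = F_masked.shape
    C = res.shape[0]
    if res.shape[1] != E or CK % C != 0:
        raise ValueError(f"cannot broadcast res {res.shape} onto cache {F_masked.shape}")
    K = CK // C
    return F_masked + np.repeat(res, K, axis=0)


@dataclass
class TrainState:
    """All trainable parameters plus bookkeeping; cache F/L stay frozen."""

    res: np.ndarray  # (C, E)
    cache_score: np.ndarray  # (CK,)
    se: SEModule
    use_se: bool = True
    epoch: int = 0
    seed: int = 0

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"res": self.res, "cache_score": self.cache_score}
        if self.use_se:
            params["W1"] = self.se.W1
            params["W2"] = self.se.W2
        return params


def count_trainable_parameters(state: TrainState) -> int:
    return sum(int(p.size) for p in state.parameters().values())


def init_train_state(
    W_C: np.ndarray,
    cache: CacheModel,
    mask: np.ndarray,
    params: TrilateralParams,
    r: int = 32,
    use_se: bool = True,
    seed: int = 0,
    squeeze: str = "vector",
) -> TrainState:
    """res = 0, cache scores at their training-free values, SE gate at 0.5."""
    C, D = np.asarray(W_C).shape
    E = len(mask)
    Fp = apply_mask(cache.F, mask)
    Wp = apply_mask(W_C, mask)
    scores0 = cache_scores(Fp, Wp, cache.L, params.gamma, params.logit_scale)
    se = make_se_module(D, r, seed=seed, squeeze=squeeze)
    return TrainState(
        res=np.zeros((C, E)), cache_score=scores0.copy(), se=se, use_se=use_se, seed=seed
    )


def _forward(
    f: np.ndarray,
    fp: np.ndarray,
    W_C: np.ndarray,
    state: TrainState,
    Fp: np.ndarray,
    L: np.ndarray,
    mask: np.ndarray,
    params: TrilateralParams,
):
    """Batch forward pass; returns logits and the intermediates needed
    for backprop."""
    if state.use_se:
        y = _squeeze_vector(W_C, state.se.squeeze)
        u = state.se.W1 @ y
        h = np.maximum(u, 0.0)
        lam = _sigmoid(state.se.W2 @ h)
        W_att = W_C * lam[None, :]
    else:
        y = u = h = lam = None
        W_att = W_C
    W_eff = apply_residuals_text(W_att, state.res, mask)
    r_fw = params.logit_scale * f @ W_eff.T
    F_eff = apply_residuals_cache(Fp, state.res)
    aff = np.exp(-params.beta * (1.0 - fp @ F_eff.T))
    logits = r_fw + params.alpha * aff @ (state.cache_score[:, None] * L)
    return logits, dict(y=y, u=u, h=h, lam=lam, aff=aff)


def vlcdt_logits(
    f: np.ndarray,
    W_C: np.ndarray,
    state: TrainState,
    cache: CacheModel,
    mask: np.ndarray,
    params: TrilateralParams,
) -> np.ndarray:
    """Inference-time logits of the trained branch."""
    f = np.asarray(f, dtype=float)
    single = f.ndim == 1
    fb = f[None, :] if single else f
    fp = apply_mask(fb, mask)
    Fp = apply_mask(cache.F, mask)
    logits, _ = _forward(fb, fp, np.asarray(W_C, dtype=float), state, Fp, cache.L, mask, params)
    return logits[0] if single else logits


def _loss_and_grads(
    f: np.ndarray,
    fp: np.ndarray,
    labels: np.ndarray,
    W_C: np.ndarray,
    state: TrainState,
    Fp: np.ndarray,
    L: np.ndarray,
    mask: np.ndarray,
    params: TrilateralParams,
):
    B = f.shape[0]
    C = W_C.shape[0]
    key_class = L.argmax(axis=1)
    logits, mid = _forward(f, fp, W_C, state, Fp, L, mask, params)

    # cross-entropy and dL/dlogits
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(B), labels].mean()
    G = np.exp(logp)
    G[np.arange(B), labels] -= 1.0
    G /= B

    grads: dict[str, np.ndarray] = {}

    # zero-shot branch: dW_eff = s * G^T f
    dW_eff = params.logit_scale * G.T @ f  # (C, D)
    g_res = dW_eff[:, np.asarray(mask)].copy()  # Pad^T

    if state.use_se:
        lam, h, u, y = mid["lam"], mid["h"], mid["u"], mid["y"]
        dlam = (dW_eff * W_C).sum(axis=0)  # (D,)
        dz_gate = dlam * lam * (1.0 - lam)
        grads["W2"] = np.outer(dz_gate, h)
        dh = state.se.W2.T @ dz_gate
        du = dh * (u > 0)
        grads["W1"] = np.outer(du, y)

    # cache branch
    aff = mid["aff"]  # (B, CK)
    M = state.cache_score[:, None] * L  # (CK, C)
    dAff = params.alpha * G @ M.T  # (B, CK)
    grads["cache_score"] = params.alpha * np.einsum("bk,bk->k", aff, G[:, key_class])
    dF_eff = (dAff * aff * params.beta).T @ fp  # (CK, E)
    K = Fp.shape[0] // C
    g_res += dF_eff.reshape(C, K, -1).sum(axis=1)  # Expand^T
    grads["res"] = g_res

    acc = float((logits.argmax(axis=1) == labels).mean())
    return loss, grads, acc


@dataclass
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 256
    weight_decay: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0


def _cosine_lr(base_lr: float, epoch: int, total: int) -> float:
    if total <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / (total - 1)))


def train_vlcdt(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    W_C: np.ndarray,
    cache: CacheModel,
    mask: np.ndarray,
    params: TrilateralParams,
    config: TrainConfig = TrainConfig(),
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    use_se: bool = True,
    r: int = 32,
    squeeze: str = "vector",
):
    """Optimize residuals, cache scores and SE weights by cross-entropy.

    Full-batch when the shot set is smaller than the batch size (the
    usual case).  Returns the trained state and a per-epoch metric
    table (epoch, lr, train_loss, train_acc, val_acc).
    """
    import pandas as pd

    f = np.asarray(train_features, dtype=float)
    labels = np.asarray(train_labels, dtype=int)
    if f.shape[0] == 0:
        raise ValueError("empty training set")
    W_C = np.asarray(W_C, dtype=float)
    state = init_train_state(
        W_C, cache, mask, params, r=r, use_se=use_se, seed=config.seed, squeeze=squeeze
    )
    fp = apply_mask(f, mask)
    Fp = apply_mask(cache.F, mask)
    vp = None
    if val_features is not None:
        val_features = np.asarray(val_features, dtype=float)
        vp = apply_mask(val_features, mask)

    # AdamW moments
    m = {k: np.zeros_like(v) for k, v in state.parameters().items()}
    v = {k: np.zeros_like(p) for k, p in state.parameters().items()}
    t = 0
    rng = np.random.default_rng([config.seed, 11])
    N = f.shape[0]
    bs = min(config.batch_size, N)
    records = []
    for epoch in range(config.epochs):
        lr = _cosine_lr(config.lr, epoch, config.epochs)
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, bs):
            idx = order[start : start + bs]
            loss, grads, _ = _loss_and_grads(
                f[idx], fp[idx], labels[idx], W_C, state, Fp, cache.L, mask, params
            )
            losses.append(loss)
            t += 1
            plist = state.parameters()
            for k, g in grads.items():
                m[k] = config.adam_beta1 * m[k] + (1 - config.adam_beta1) * g
                v[k] = config.adam_beta2 * v[k] + (1 - config.adam_beta2) * g * g
                mhat = m[k] / (1 - config.adam_beta1**t)
                vhat = v[k] / (1 - config.adam_beta2**t)
                plist[k] -= lr * (
                    mhat / (np.sqrt(vhat) + config.adam_eps) + config.weight_decay * plist[k]
                )
        full_logits, _ = _forward(f, fp, W_C, state, Fp, cache.L, mask, params)
        train_acc = float((full_logits.argmax(axis=1) == labels).mean())
        rec = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": train_acc,
        }
        if vp is not None:
            vl, _ = _forward(val_features, vp, W_C, state, Fp, cache.L, mask, params)
            rec["val_acc"] = float((vl.argmax(axis=1) == np.asarray(val_labels)).mean())
        records.append(rec)
        state.epoch = epoch + 1
    return state, pd.DataFrame(records)
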