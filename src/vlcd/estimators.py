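"""Scikit-learn-style estimators over frozen embeddings.

All estimators consume unit-norm embedding rows X (n_samples, D) and
integer labels y; the per-class classifier weights W_C (built from
prompt ensembles) are a constructor parameter, so the estimators
compose with sklearn model selection (clone, grid search) without
re-encoding text.

=====================================  =======================================
Estimator                              Method
=====================================  =======================================
``ZeroShotClassifier``                 cosine logits against W_C only
``TipAdapterClassifier``               + key-value cache affinity (all
                                       channels, unweighted)
``TrilateralCacheClassifier``          + prior refinement (top-E channels)
                                       and KL cache scores, training-free
``ResidualTunedClassifier``            + learned residuals, cache scores and
                                       SE gate (lightweight training)
=====================================  =======================================
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cache import (
    CacheModel,
    TrilateralParams,
    apply_mask,
    build_cache,
    cache_scores,
    refine_channels,
    tip_adapter_logits,
    vlcd_logits,
    zero_shot_logits,
)
from .train import TrainConfig, train_vlcdt, vlcdt_logits

__all__ = [
    "ZeroShotClassifier",
    "TipAdapterClassifier",
    "TrilateralCacheClassifier",
    "ResidualTunedClassifier",
]


def _check_embeddings(X: np.ndarray, dim: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D (n_samples, dim), got shape {X.shape}")
    if dim is not None and X.shape[1] != dim:
        raise ValueError(f"X has dim {X.shape[1]}, expected {dim}")
    return X


class ZeroShotClassifier(ClassifierMixin, BaseEstimator):
    """Cosine classifier against fixed per-class weights; fit is a no-op
    beyond validation (there is nothing to learn)."""

    def __init__(self, weights: np.ndarray = None, logit_scale: float = 1.0):
        self.weights = weights
        self.logit_scale = logit_scale

    def fit(self, X=None, y=None):
        if self.weights is None:
            raise ValueError("weights (C x D classifier matrix) must be provided")
        self.weights_ = np.asarray(self.weights, dtype=float)
        self.classes_ = np.arange(self.weights_.shape[0])
        self.n_features_in_ = self.weights_.shape[1]
        return self

    def decision_function(self, X):
        X = _check_embeddings(X, getattr(self, "n_features_in_", None))
        return zero_shot_logits(X, self.weights_, self.logit_scale)

    def predict(self, X):
        return self.decision_function(X).argmax(axis=1)


class _CacheClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit logic: validate inputs and build the frozen cache."""

    def _fit_cache(self, X, y, shots):
        if self.weights is None:
            raise ValueError("weights (C x D classifier matrix) must be provided")
        W = np.asarray(self.weights, dtype=float)
        X = _check_embeddings(X, W.shape[1])
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) != W.shape[0]:
            raise ValueError(
                f"y covers {len(np.unique(y))} classes but weights have {W.shape[0]} rows"
            )
        self.weights_ = W
        self.classes_ = np.arange(W.shape[0])
        self.n_features_in_ = W.shape[1]
        self.cache_ = build_cache(X, y, shots)
        return X, y

    def predict(self, X):
        return self.decision_function(X).argmax(axis=1)


class TipAdapterClassifier(_CacheClassifierBase):
    """Training-free key-value cache adapter on all channels.

    Parameters
    ----------
    weights : (C, D) array
        Per-class classifier weights (e.g. encoded "a photo of a [CLASS]"
        prompts, or a fused prompt ensemble).
    alpha, beta : float
        Cache balance and affinity sharpness.
    shots : int or None
        Cache size per class; None keeps every provided row.
    """

    def __init__(
        self,
        weights: np.ndarray = None,
        alpha: float = 1.0,
        beta: float = 5.5,
        logit_scale: float = 1.0,
        shots: int | None = None,
    ):
        self.weights = weights
        self.alpha = alpha
        self.beta = beta
        self.logit_scale = logit_scale
        self.shots = shots

    def _params(self) -> TrilateralParams:
        return TrilateralParams(
            alpha=self.alpha, beta=self.beta, gamma=0.0, logit_scale=self.logit_scale
        )

    def fit(self, X, y):
        self._fit_cache(X, y, self.shots)
        return self

    def decision_function(self, X):
        X = _check_embeddings(X, self.n_features_in_)
        return tip_adapter_logits(X, self.weights_, self.cache_, self._params())


class TrilateralCacheClassifier(_CacheClassifierBase):
    """Training-free trilateral classifier: refined channels, KL cache
    scores, and the zero-shot term, combined per the cache-model logits.

    ``n_channels`` is E, the refined-channel count (None means all D,
    i.e. refinement disabled).  Fitted attributes: ``cache_``,
    ``channel_mask_``, ``cache_scores_``.
    """

    def __init__(
        self,
        weights: np.ndarray = None,
        alpha: float = 1.0,
        beta: float = 5.5,
        gamma: float = 0.1,
        n_channels: int | None = None,
        logit_scale: float = 1.0,
        shots: int | None = None,
    ):
        self.weights = weights
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.n_channels = n_channels
        self.logit_scale = logit_scale
        self.shots = shots

    def _params(self) -> TrilateralParams:
        return TrilateralParams(
            alpha=self.alpha, beta=self.beta, gamma=self.gamma, logit_scale=self.logit_scale
        )

    def fit(self, X, y):
        self._fit_cache(X, y, self.shots)
        E = self.n_channels or self.n_features_in_
        self.channel_mask_ = refine_channels(self.weights_, E)
        Fp = apply_mask(self.cache_.F, self.channel_mask_)
        Wp = apply_mask(self.weights_, self.channel_mask_)
        self.cache_scores_ = cache_scores(Fp, Wp, self.cache_.L, self.gamma, self.logit_scale)
        return self

    def decision_function(self, X):
        X = _check_embeddings(X, self.n_features_in_)
        return vlcd_logits(X, self.weights_, self.cache_, self.channel_mask_, self._params())


class ResidualTunedClassifier(_CacheClassifierBase):
    """Trained branch: learns per-class residuals, per-key cache scores
    and an SE channel gate on top of the frozen cache.

    Fitted attributes: ``state_`` (trained parameters), ``metrics_``
    (per-epoch loss/accuracy table), plus the cache/mask attributes of
    the training-free classifier.  ``use_se=False`` disables the SE gate
    (the residual-only baseline); everything else is shared.
    """

    def __init__(
        self,
        weights: np.ndarray = None,
        alpha: float = 1.0,
        beta: float = 5.5,
        gamma: float = 0.1,
        n_channels: int | None = None,
        logit_scale: float = 1.0,
        shots: int | None = None,
        use_se: bool = True,
        reduction: int = 32,
        epochs: int = 30,
        lr: float = 1e-3,
        batch_size: int = 256,
        random_state: int = 0,
    ):
        self.weights = weights
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.n_channels = n_channels
        self.logit_scale = logit_scale
        self.shots = shots
        self.use_se = use_se
        self.reduction = reduction
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    def _params(self) -> TrilateralParams:
        return TrilateralParams(
            alpha=self.alpha, beta=self.beta, gamma=self.gamma, logit_scale=self.logit_scale
        )

    def fit(self, X, y, val_X=None, val_y=None):
        X, y = self._fit_cache(X, y, self.shots)
        E = self.n_channels or self.n_features_in_
        self.channel_mask_ = refine_channels(self.weights_, E)
        config = TrainConfig(
            epochs=self.epochs,
            lr=self.lr,
            batch_size=self.batch_size,
            seed=self.random_state,
        )
        self.state_, self.metrics_ = train_vlcdt(
            X,
            y,
            self.weights_,
            self.cache_,
            self.channel_mask_,
            self._params(),
            config=config,
            val_features=val_X,
            val_labels=val_y,
            use_se=self.use_se,
            r=self.reduction,
        )
        return self

    def decision_function(self, X):
        X = _check_embeddings(X, self.n_features_in_)
        return vlcdt_logits(
            X, self.weights_, self.state_, self.cache_, self.channel_mask_, self._params()
        )
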