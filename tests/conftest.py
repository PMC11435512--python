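"""Shared fixtures: anchored synthetic problems and random instances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from vlcd.cache import CacheModel, TrilateralParams, build_cache, refine_channels
from vlcd.fusion import build_classifier_weights
from vlcd.synthetic import (
    SyntheticSpec,
    make_class_prototypes,
    make_synthetic_embeddings,
    make_synthetic_prompt_embeddings,
    make_test_embeddings,
)


@dataclass
class Problem:
    """A fully-materialized synthetic few-shot problem."""

    spec: SyntheticSpec
    prototypes: np.ndarray
    train: object  # LabeledEmbeddingSet
    test: object
    prompt_embeddings: list
    weights: np.ndarray  # cross-attention fused W_C
    cache: CacheModel
    mask: np.ndarray
    params: TrilateralParams


def make_problem(
    n_classes=4,
    shots=4,
    dim=16,
    prompts=3,
    noise=0.0,
    seed=0,
    n_channels=None,
    params=None,
) -> Problem:
    spec = SyntheticSpec(
        n_classes=n_classes,
        shots_per_class=shots,
        dim=dim,
        prompts_per_class=prompts,
        noise_scale=noise,
        seed=seed,
    )
    protos = make_class_prototypes(spec)
    train = make_synthetic_embeddings(spec, protos)
    test = make_test_embeddings(spec, protos, per_class=6)
    pe = make_synthetic_prompt_embeddings(spec, protos)
    W = build_classifier_weights(pe)
    cache = build_cache(train.features, train.labels, shots)
    E = n_channels or dim
    mask = refine_channels(W, E)
    return Problem(
        spec=spec,
        prototypes=protos,
        train=train,
        test=test,
        prompt_embeddings=pe,
        weights=W,
        cache=cache,
        mask=mask,
        params=params or TrilateralParams(alpha=1.0, beta=5.5, gamma=0.1),
    )


def random_instance(rng, C=None, K=None, D=None, E=None, M=None):
    """A small random (non-anchored) instance for oracle comparisons."""
    C = C or int(rng.integers(2, 5))
    K = K or int(rng.integers(1, 4))
    D = D or int(rng.integers(max(4, C), 17))
    E = E or int(rng.integers(1, min(D, 8) + 1))
    M = M or int(rng.integers(1, 5))

    def unit_rows(n):
        X = rng.standard_normal((n, D))
        return X / np.linalg.norm(X, axis=1, keepdims=True)

    W = unit_rows(C)
    F = unit_rows(C * K)
    L = np.zeros((C * K, C))
    for c in range(C):
        L[c * K : (c + 1) * K, c] = 1.0
    f = unit_rows(1)[0]
    X_list = [unit_rows(M) for _ in range(C)]
    params = TrilateralParams(
        alpha=float(rng.uniform(0.1, 3.0)),
        beta=float(rng.uniform(1.0, 8.0)),
        gamma=float(rng.uniform(-1.0, 1.0)),
    )
    return dict(C=C, K=K, D=D, E=E, M=M, W=W, F=F, L=L, f=f, X_list=X_list, params=params)


@pytest.fixture
def separable_problem():
    """Noise-free anchored fixture: embeddings sit exactly on prototypes."""
    return make_problem(n_classes=4, shots=4, dim=16, prompts=3, noise=0.0, seed=3)


@pytest.fixture
def noisy_problem():
    """The standard noisy anchored fixture (still well separated)."""
    return make_problem(n_classes=4, shots=4, dim=32, prompts=3, noise=0.05, seed=7, n_channels=16)


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)
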