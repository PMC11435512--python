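"""Synthetic fixtures: class-structured embeddings, prompt embeddings,
textured toy images, and deterministic mock encoder/captioner backends.

Real pipelines encode images and prompt sentences with a frozen
vision-language model; everything downstream only sees unit-norm
D-dimensional vectors.  The generators here emulate that interface with
an analytically transparent geometry: each class has a unit prototype,
and image/prompt embeddings are the prototype plus isotropic Gaussian
noise, renormalized (an approximate von-Mises-Fisher draw).  At
``noise_scale=0`` nearest-prototype classification is exact, which makes
end-to-end recovery checks sharp.

Every generator is a pure function of its spec and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticSpec",
    "LabeledEmbeddingSet",
    "LabeledImageSet",
    "make_class_prototypes",
    "make_synthetic_embeddings",
    "make_synthetic_prompt_embeddings",
    "make_synthetic_images",
    "MockEncoder",
    "MockCaptioner",
]

_NORM_ATOL = 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic few-shot problem.

    Attributes
    ----------
    n_classes : int
        Number of classes C (>= 2).
    shots_per_class : int
        Training embeddings generated per class, K.
    dim : int
        Embedding dimension D (>= 2).
    prompts_per_class : int
        Prompt embeddings per class, M (>= 1).
    noise_scale : float
        Standard deviation of the isotropic perturbation applied to the
        class prototype before renormalization.  0 gives exact
        prototypes; ~0.3 gives a realistically noisy but separable
        problem.
    seed : int
        Base seed; distinct sub-streams are derived per generator.
    """

    n_classes: int = 4
    shots_per_class: int = 4
    dim: int = 16
    prompts_per_class: int = 3
    noise_scale: float = 0.3
    seed: int = 0
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.dim < 2:
            raise ValueError(f"dim must be >= 2, got {self.dim}")
        if self.shots_per_class < 1:
            raise ValueError("shots_per_class must be >= 1")
        if self.prompts_per_class < 1:
            raise ValueError("prompts_per_class must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.n_classes > 2 ** self.dim:
            raise ValueError("n_classes exceeds 2**dim; prototypes cannot be distinct")
        if self.class_names and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")

    @property
    def names(self) -> list[str]:
        if self.class_names:
            return list(self.class_names)
        return [f"class_{i}" for i in range(self.n_classes)]


@dataclass
class LabeledEmbeddingSet:
    """Unit-norm feature rows with integer labels, class-major ordered."""

    features: np.ndarray  # (N, D), unit rows
    labels: np.ndarray  # (N,), values in [0, C)
    class_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels length mismatch")
        norms = np.linalg.norm(self.features, axis=1)
        if not np.allclose(norms, 1.0, atol=_NORM_ATOL):
            raise ValueError("all feature rows must have unit L2 norm")
        n_classes = len(self.class_names)
        counts = np.bincount(self.labels, minlength=n_classes)
        if (counts == 0).any():
            raise ValueError("every class must have at least one row")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class LabeledImageSet:
    """8-bit RGB images with integer labels."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero vector")
    return mat / norms


def make_class_prototypes(spec: SyntheticSpec) -> np.ndarray:
    """C unit prototype vectors with pairwise cosine similarity < 1.

    With C <= D the prototypes are a random orthonormal frame (pairwise
    orthogonal), otherwise independent random unit vectors redrawn until
    distinct.
    """
    rng = np.random.default_rng([spec.seed, 1])
    C, D = spec.n_classes, spec.dim
    if C <= D:
        raw = rng.standard_normal((D, C))
        q, r = np.linalg.qr(raw)
        # fix the sign convention so the frame is deterministic
        q = q * np.sign(np.diag(r))
        return q.T[:C].copy()
    protos = _unit_rows(rng.standard_normal((C, D)))
    gram = protos @ protos.T
    np.fill_diagonal(gram, -np.inf)
    while gram.max() >= 1.0 - 1e-9:  # pragma: no cover - astronomically rare
        protos = _unit_rows(rng.standard_normal((C, D)))
        gram = protos @ protos.T
        np.fill_diagonal(gram, -np.inf)
    return protos


def _perturb(prototype: np.ndarray, n: int, scale: float, rng) -> np.ndarray:
    noise = rng.standard_normal((n, prototype.shape[0]))
    return _unit_rows(prototype[None, :] + scale * noise)


def make_synthetic_embeddings(
    spec: SyntheticSpec, prototypes: np.ndarray | None = None
) -> LabeledEmbeddingSet:
    """K unit embeddings per class around each prototype, class-major.

    Rows for class 0 come first, then class 1, etc.; this ordering is
    what the cache model assumes when broadcasting per-class residuals.
    """
    if prototypes is None:
        prototypes = make_class_prototypes(spec)
    rng = np.random.default_rng([spec.seed, 2])
    K = spec.shots_per_class
    rows = [_perturb(prototypes[c], K, spec.noise_scale, rng) for c in range(spec.n_classes)]
    labels = np.repeat(np.arange(spec.n_classes), K)
    return LabeledEmbeddingSet(np.vstack(rows), labels, spec.names)


def make_test_embeddings(
    spec: SyntheticSpec,
    prototypes: np.ndarray | None = None,
    per_class: int = 8,
    stream: int = 5,
) -> LabeledEmbeddingSet:
    """Held-out embeddings from the same class geometry (separate stream)."""
    if prototypes is None:
        prototypes = make_class_prototypes(spec)
    rng = np.random.default_rng([spec.seed, stream])
    rows = [
        _perturb(prototypes[c], per_class, spec.noise_scale, rng)
        for c in range(spec.n_classes)
    ]
    labels = np.repeat(np.arange(spec.n_classes), per_class)
    return LabeledEmbeddingSet(np.vstack(rows), labels, spec.names)


def make_synthetic_prompt_embeddings(
    spec: SyntheticSpec, prototypes: np.ndarray | None = None
) -> list[np.ndarray]:
    """Per class, an (M, D) matrix of unit prompt embeddings around the
    class prototype, with noise independent of the image embeddings."""
    if prototypes is None:
        prototypes = make_class_prototypes(spec)
    rng = np.random.default_rng([spec.seed, 3])
    return [
        _perturb(prototypes[c], spec.prompts_per_class, spec.noise_scale, rng)
        for c in range(spec.n_classes)
    ]


# ---------------------------------------------------------------------------
# Toy images


def _class_palette(n_classes: int) -> np.ndarray:
    """Distinct base RGB colors, mid-range so stripe modulation stays in gamut."""
    hues = np.linspace(0.0, 1.0, n_classes, endpoint=False)
    colors = np.empty((n_classes, 3))
    for i, h in enumerate(hues):
        # crude HSV->RGB at s=0.6, v=0.7, kept away from 0/255
        import colorsys

        colors[i] = colorsys.hsv_to_rgb(h, 0.6, 0.7)
    return np.round(colors * 255.0 * 0.7 + 32).astype(int)


def make_synthetic_images(
    n_classes: int,
    per_class: int,
    size: tuple[int, int] = (32, 32),
    seed: int = 0,
    noise: float = 4.0,
) -> LabeledImageSet:
    """Toy textured images: one base color and one stripe period per class.

    Class c gets vertical stripes of period ``2**(1 + c % 4)`` columns with
    amplitude +/-24 gray levels (zero-mean over a full period) plus
    optional Gaussian pixel noise.  Colors and periods differ between
    classes, so mean-color + GLCM features separate them.
    """
    H, W = size
    if H < 16 or W < 16:
        raise ValueError("images must be at least 16x16")
    rng = np.random.default_rng([seed, 4])
    palette = _class_palette(n_classes)
    periods = [2 ** (1 + (c % 4)) for c in range(n_classes)]
    images: list[np.ndarray] = []
    labels = []
    amp = 24
    x = np.arange(W)
    for c in range(n_classes):
        p = periods[c]
        stripe = np.where((x // (p // 2)) % 2 == 0, amp, -amp)  # zero-mean if p | W
        base = palette[c][None, None, :].astype(float)
        for _ in range(per_class):
            img = np.broadcast_to(base, (H, W, 3)).copy()
            img += stripe[None, :, None]
            if noise > 0:
                img += rng.normal(0.0, noise, size=(H, W, 3))
            images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
            labels.append(c)
    names = [f"class_{i}" for i in range(n_classes)]
    return LabeledImageSet(images, np.asarray(labels), names)


# ---------------------------------------------------------------------------
# Mock backends


def _content_digest(item) -> int:
    if isinstance(item, str):
        payload = item.encode("utf-8")
    elif isinstance(item, np.ndarray):
        payload = item.tobytes() + str(item.shape).encode()
    else:
        raise TypeError(f"cannot encode item of type {type(item).__name__}")
    if len(payload) == 0:
        raise ValueError("cannot encode an empty item")
    return int.from_bytes(hashlib.blake2b(payload, digest_size=8).digest(), "big")


class MockEncoder:
    """Deterministic stand-in for a frozen vision-language encoder.

    Plain mode maps any item (string or image array) to a pseudo-random
    unit vector via a stable content hash, so identical inputs always
    produce identical embeddings.  Anchored mode additionally places
    items attributed to class ``c`` near ``prototypes[c]`` (exactly on it
    at ``noise_scale=0``); for text, the class is inferred from the
    longest class name occurring in the string.
    """

    def __init__(
        self,
        dim: int,
        prototypes: np.ndarray | None = None,
        class_names: list[str] | None = None,
        noise_scale: float = 0.0,
        name: str = "mock",
    ):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        if prototypes is not None and prototypes.shape[1] != dim:
            raise ValueError("prototype dimension does not match dim")
        self.dim = dim
        self.prototypes = prototypes
        self.class_names = class_names or []
        self.noise_scale = noise_scale
        self.name = name
        self.version = "1"

    @property
    def anchored(self) -> bool:
        return self.prototypes is not None

    def _hash_vector(self, item) -> np.ndarray:
        rng = np.random.default_rng(_content_digest(item))
        return _unit_rows(rng.standard_normal(self.dim))

    def _anchor(self, item, label: int) -> np.ndarray:
        proto = self.prototypes[label]
        if self.noise_scale == 0:
            return proto.copy()
        rng = np.random.default_rng(_content_digest(item))
        return _unit_rows(proto + self.noise_scale * rng.standard_normal(self.dim))

    def _infer_text_label(self, text: str) -> int | None:
        best = None
        for i, name in enumerate(self.class_names):
            if name and name in text:
                if best is None or len(name) > len(self.class_names[best]):
                    best = i
        return best

    def encode_image(self, image: np.ndarray, label: int | None = None) -> np.ndarray:
        if self.anchored and label is not None:
            return self._anchor(image, label)
        return self._hash_vector(image)

    def encode_text(self, text: str, label: int | None = None) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode an empty string")
        if self.anchored:
            if label is None:
                label = self._infer_text_label(text)
            if label is not None:
                return self._anchor(text, label)
        return self._hash_vector(text)


class MockCaptioner:
    """Deterministic captioner: echoes the class name plus a coarse
    color/texture summary of the image, so downstream text embeddings
    carry class-correlated content without any external model."""

    name = "mock"

    def describe(self, image: np.ndarray, query: str) -> str:
        mean = np.asarray(image, dtype=float).mean(axis=(0, 1))
        gray = image[..., 0].astype(int)
        edges = int(np.abs(np.diff(gray, axis=1)).mean())
        return (
            f"{query} It is a leaf with mean color "
            f"({mean[0]:.0f}, {mean[1]:.0f}, {mean[2]:.0f}) "
            f"and horizontal texture roughness {edges}."
        )
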