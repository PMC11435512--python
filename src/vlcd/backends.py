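"""Uniform encoder contract: anything with ``dim``, ``encode_image`` and
``encode_text`` producing D-dimensional vectors can drive the pipeline.

The wrappers here renormalize defensively, so the cosine-geometry
assumptions of the cache and zero-shot logits hold regardless of the
backend.  CI exercises only the deterministic mock encoder; a real
frozen vision-language encoder plugs in through the same surface.
"""

from __future__ import annotations

from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .prompts import PromptBank

__all__ = ["EncoderBackend", "encode_image_batch", "encode_prompt_bank"]

_NORM_ATOL = 1e-6


@runtime_checkable
class EncoderBackend(Protocol):
    dim: int
    name: str

    def encode_image(self, image: np.ndarray, label: int | None = None) -> np.ndarray: ...

    def encode_text(self, text: str, label: int | None = None) -> np.ndarray: ...


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise ValueError(f"backend returned a degenerate embedding for {what}")
    return v / n


def encode_image_batch(
    backend: EncoderBackend,
    images: Sequence[np.ndarray],
    labels: Sequence[int] | None = None,
) -> np.ndarray:
    """Encode images to an (N, D) matrix of unit rows, input order kept."""
    if len(images) == 0:
        raise ValueError("empty image batch")
    rows = []
    for i, img in enumerate(images):
        try:
            lab = None if labels is None else int(labels[i])
            rows.append(_unit(backend.encode_image(img, label=lab), f"image {i}"))
        except Exception as exc:
            raise RuntimeError(f"backend {backend.name!r} failed on image index {i}: {exc}") from exc
    return np.vstack(rows)


def encode_prompt_bank(backend: EncoderBackend, bank: PromptBank) -> list[np.ndarray]:
    """Per class i, the (M, D) matrix whose row j encodes prompt T_i[j]."""
    if not bank.is_uniform():
        raise ValueError("prompt bank is not uniform; call bank.normalize(M) first")
    out = []
    for ci, name in enumerate(bank.class_names):
        rows = []
        for j, text in enumerate(bank.prompts[name]):
            try:
                rows.append(_unit(backend.encode_text(text, label=ci), f"{name}[{j}]"))
            except Exception as exc:
                raise RuntimeError(
                    f"backend {backend.name!r} failed on prompt {j} of class {name!r}: {exc}"
                ) from exc
        out.append(np.vstack(rows))
    return out
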