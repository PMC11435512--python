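"""Plain-text matrix container: a TSV of floats plus a JSON sidecar
carrying shape and provenance metadata (backend name, class names,
seed).  Round-trips at float64 precision via repr formatting."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_matrix", "load_matrix"]


def save_matrix(path: str | Path, matrix: np.ndarray, **meta) -> None:
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    np.savetxt(path, matrix, fmt="%.17g", delimiter="\t")
    sidecar = {"shape": list(matrix.shape), **meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    matrix = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if "shape" in meta and list(matrix.shape) != meta["shape"]:
        raise ValueError(f"matrix shape {matrix.shape} does not match sidecar {meta['shape']}")
    return matrix, meta
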