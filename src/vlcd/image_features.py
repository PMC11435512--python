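"""Per-image color/texture features and K-means representative selection.

Each image is summarized by its per-channel mean color and four Haralick
statistics (contrast, correlation, energy, homogeneity) of a symmetric,
normalized gray-level co-occurrence matrix, averaged over a set of
angles.  Within each class the combined 7-dimensional features are
z-scored and clustered with K-means; the image nearest each centroid
becomes a representative.  M thus directly controls how many distinct
appearance modes per class are covered.

GLCM parameterization (grayscale conversion, quantization levels,
displacements, angles) is config-exposed; the defaults are the standard
minimal Haralick setup: ITU-R 601 luma, 8 gray levels, distance 1,
angles {0, 45, 90, 135} degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import graycomatrix, graycoprops
from sklearn.cluster import KMeans

__all__ = [
    "GLCMConfig",
    "compute_color_features",
    "compute_glcm_features",
    "compute_image_features",
    "select_representatives",
    "load_image_tree",
    "features_to_frame",
]

GLCM_FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 8
    distances: tuple[int, ...] = (1,)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    return image


def compute_color_features(image: np.ndarray) -> np.ndarray:
    """Arithmetic mean of each RGB channel over all pixels (0-255 scale)."""
    image = _check_rgb(image)
    return image.reshape(-1, 3).astype(float).mean(axis=0)


def _to_gray_levels(image: np.ndarray, levels: int) -> np.ndarray:
    # ITU-R 601 luma, then uniform quantization into `levels` bins
    rgb = image.astype(float)
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    q = np.floor(gray * levels / 256.0).astype(np.uint8)
    return np.clip(q, 0, levels - 1)


def compute_glcm_features(
    image: np.ndarray, config: GLCMConfig = GLCMConfig()
) -> np.ndarray:
    """Contrast, correlation, energy and homogeneity of the symmetric,
    normalized co-occurrence matrix, averaged over all (distance, angle)
    pairs.

    Correlation of a constant image is the degenerate 0/0 case; it is
    defined as 1 (a constant field is perfectly self-correlated).
    """
    image = _check_rgb(image)
    H, W = image.shape[:2]
    if max(config.distances) >= min(H, W):
        raise ValueError("image smaller than the largest GLCM distance")
    q = _to_gray_levels(image, config.levels)
    angles = np.deg2rad(config.angles_deg)
    glcm = graycomatrix(
        q,
        distances=list(config.distances),
        angles=list(angles),
        levels=config.levels,
        symmetric=True,
        normed=True,
    )
    out = []
    for name in GLCM_FEATURE_NAMES:
        vals = graycoprops(glcm, name)  # (n_dist, n_angle)
        if name == "correlation":
            # constant image -> zero variance; define as perfectly correlated
            vals = np.where(np.isnan(vals), 1.0, vals)
        out.append(float(vals.mean()))
    return np.asarray(out)


def compute_image_features(
    image: np.ndarray, config: GLCMConfig = GLCMConfig()
) -> np.ndarray:
    """Combined 7-vector: (R, G, B means, contrast, correlation, energy,
    homogeneity)."""
    return np.concatenate([compute_color_features(image), compute_glcm_features(image, config)])


def _zscore_drop_constant(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        # all images identical in feature space; clustering is arbitrary
        return np.zeros((X.shape[0], 1))
    return (X[:, keep] - mu[keep]) / sd[keep]


def select_representatives(
    features_per_class: dict[str, np.ndarray],
    M: int,
    seed: int = 0,
) -> dict[str, list[int]]:
    """Per class, choose min(M, class size) representative image indices.

    Features are z-scored within the class (zero-variance dimensions
    dropped) and clustered with seeded K-means (k-means++ init, 10
    restarts).  Each cluster contributes the image nearest its centroid
    in Euclidean distance; ties and collisions resolve to the lowest
    unused index.  If the class has at most M images, all are returned.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    result: dict[str, list[int]] = {}
    for cls, X in features_per_class.items():
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError(f"class {cls!r} has no feature rows")
        n = X.shape[0]
        if n <= M:
            result[cls] = list(range(n))
            continue
        Z = _zscore_drop_constant(X)
        km = KMeans(n_clusters=M, n_init=10, random_state=seed)
        km.fit(Z)
        chosen: list[int] = []
        for centroid in km.cluster_centers_:
            d = np.linalg.norm(Z - centroid[None, :], axis=1)
            order = np.lexsort((np.arange(n), d))  # distance, then lowest index
            pick = next(i for i in order if i not in chosen)
            chosen.append(int(pick))
        result[cls] = chosen
    return result


# ---------------------------------------------------------------------------
# Directory-tree I/O helpers (used by the CLI)


def load_image_tree(root: str | Path) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Read a one-directory-per-class tree of PNG/JPEG images.

    Returns {class_name: [(relative path, HxWx3 uint8 array), ...]},
    classes and files in sorted order for reproducibility.
    """
    from PIL import Image

    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"image root {root} is not a directory")
    tree: dict[str, list[tuple[str, np.ndarray]]] = {}
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        items = []
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                arr = np.asarray(Image.open(f).convert("RGB"))
                items.append((str(f.relative_to(root)), arr))
        if items:
            tree[cls_dir.name] = items
    if not tree:
        raise ValueError(f"no class directories with images under {root}")
    return tree


def features_to_frame(tree, config: GLCMConfig = GLCMConfig()):
    """Feature table for an image tree: one row per image, named columns."""
    import pandas as pd

    rows = []
    for cls, items in tree.items():
        for rel, arr in items:
            feat = compute_image_features(arr, config)
            rows.append(
                {
                    "class": cls,
                    "path": rel,
                    "mean_r": feat[0],
                    "mean_g": feat[1],
                    "mean_b": feat[2],
                    "contrast": feat[3],
                    "correlation": feat[4],
                    "energy": feat[5],
                    "homogeneity": feat[6],
                }
            )
    return pd.DataFrame(rows)


def save_representatives(reps: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(reps, indent=2, sort_keys=True) + "\n")


def load_representatives(path: str | Path) -> dict[str, list[str]]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("representatives file must be a JSON object")
    return data
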