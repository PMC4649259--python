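"""Stimulus-image complexity features and class assignment.

Each art piece photograph is summarized by luminance statistics, Gabor
texture responses, gradient-magnitude statistics and composite block
deviations; images are then grouped into three complexity classes (complex,
moderate, baseline) by agglomerative clustering with a cosine distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.signal import fftconvolve
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skimage.filters import gabor_kernel

#: ITU-R BT.601 luma weights used to collapse RGB to luminance.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Pixels darker than this 8-bit intensity count as "dark".
DARK_THRESHOLD = 64


def to_luminance(image: np.ndarray) -> np.ndarray:
    """RGB -> luminance Y = 0.299 R + 0.587 G + 0.114 B (float, 0-255 scale)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    r, g, b = (img[..., k].astype(float) for k in range(3))
    return LUMA_WEIGHTS[0] * r + LUMA_WEIGHTS[1] * g + LUMA_WEIGHTS[2] * b


def luminance_features(image: np.ndarray) -> dict[str, float]:
    """Mean/SD/kurtosis/skewness of luminance plus the dark-pixel fraction."""
    y = to_luminance(image)
    flat = y.ravel()
    return {
        "lum_mean": float(flat.mean()),
        "lum_sd": float(flat.std()),
        "lum_kurtosis": float(stats.kurtosis(flat, fisher=False)) if flat.std() > 0 else 0.0,
        "lum_skewness": float(stats.skew(flat)) if flat.std() > 0 else 0.0,
        "dark_fraction": float(np.mean(flat < DARK_THRESHOLD)),
    }


def gabor_bank(scales: int = 4, orientations: int = 4) -> list[tuple[float, float]]:
    """(frequency cycles/px, orientation rad) pairs: dyadic scales x 4 angles."""
    freqs = [0.25 / (2 ** s) for s in range(scales)]
    thetas = [np.pi * k / orientations for k in range(orientations)]
    return [(f, th) for f in freqs for th in thetas]


def gabor_texture_features(image: np.ndarray, scales: int = 4,
                           orientations: int = 4) -> dict[str, float]:
    """Mean and variance of Gabor magnitude per (scale, orientation) filter."""
    y = to_luminance(image)
    y = y - y.mean()
    out: dict[str, float] = {}
    for f, th in gabor_bank(scales, orientations):
        kern = gabor_kernel(frequency=f, theta=th)
        if min(y.shape) < max(kern.shape):
            raise ValueError("image smaller than Gabor filter support")
        resp = fftconvolve(y, kern, mode="same")
        mag = np.abs(resp)
        deg = int(round(np.degrees(th)))
        out[f"gabor_f{f:.4f}_t{deg}_mean"] = float(mag.mean())
        out[f"gabor_f{f:.4f}_t{deg}_var"] = float(mag.var())
    return out


def gradient_features(image: np.ndarray, operator: str = "central") -> dict[str, float]:
    """Summary statistics of the finite-difference gradient-magnitude map."""
    y = to_luminance(image)
    if operator == "central":
        gy, gx = np.gradient(y)
    elif operator == "sobel":
        gx = ndimage.sobel(y, axis=1) / 8.0
        gy = ndimage.sobel(y, axis=0) / 8.0
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    mag = np.hypot(gx, gy)
    return {"grad_mean": float(mag.mean()), "grad_sd": float(mag.std()),
            "grad_max": float(mag.max())}


def composite_block_features(image: np.ndarray, n_blocks: int = 16) -> np.ndarray:
    """Per-block mean gray level minus the global mean gray level.

    The image is cut into a square grid of ``n_blocks`` blocks (n must be a
    perfect square); trailing rows/columns that do not fill a block are
    cropped. Invariant to global additive brightness changes.
    """
    y = to_luminance(image)
    side = int(round(np.sqrt(n_blocks)))
    if side * side != n_blocks:
        raise ValueError("n_blocks must be a perfect square")
    if n_blocks > y.size:
        raise ValueError("more blocks than pixels")
    h = (y.shape[0] // side) * side
    w = (y.shape[1] // side) * side
    y = y[:h, :w]
    blocks = y.reshape(side, h // side, side, w // side)
    block_means = blocks.mean(axis=(1, 3))
    return (block_means - y.mean()).ravel()


def image_feature_vector(image: np.ndarray, n_blocks: int = 16) -> pd.Series:
    """Full feature vector for one image (fixed length and ordering)."""
    feats: dict[str, float] = {}
    feats.update(luminance_features(image))
    feats.update(gabor_texture_features(image))
    feats.update(gradient_features(image))
    for i, v in enumerate(composite_block_features(image, n_blocks)):
        feats[f"block_dev_{i}"] = float(v)
    return pd.Series(feats)


def image_feature_table(images: dict[str, np.ndarray], n_blocks: int = 16) -> pd.DataFrame:
    """Rows = image ids, columns = features."""
    return pd.DataFrame({k: image_feature_vector(v, n_blocks)
                         for k, v in images.items()}).T


def linkage_to_nested_text(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a linkage tree as a Newick-style nested string with heights."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return (f"({render(node.left)},{render(node.right)})"
                f":{node.dist:.6g}")

    return render(root) + ";"


@dataclass
class ComplexityClasses:
    labels: dict[str, str]          # image id -> complex | moderate | baseline
    linkage: np.ndarray
    metric: str
    image_ids: list[str]


def cluster_images(features: pd.DataFrame, baseline_id: str,
                   n_classes: int = 3, metric: str = "cosine",
                   linkage_method: str = "average") -> ComplexityClasses:
    """Agglomerative clustering of z-scored image features into 3 classes.

    The cluster containing ``baseline_id`` (the blank-wall image) is labeled
    "baseline"; of the remaining clusters the one with higher mean luminance
    SD is "complex", the other "moderate".
    """
    if len(features) < n_classes:
        raise ValueError("need at least as many images as classes")
    if baseline_id not in features.index:
        raise KeyError(f"baseline image {baseline_id!r} not in feature table")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    dist = pdist(z, metric=metric)
    if not np.all(np.isfinite(dist)):
        raise ValueError("degenerate feature set: identical feature vectors "
                         "collapse and fewer than 3 groups would emerge")
    link = hierarchy.linkage(dist, method=linkage_method)
    assign = hierarchy.fcluster(link, t=n_classes, criterion="maxclust")
    if len(np.unique(assign)) < n_classes:
        raise ValueError(
            f"degenerate feature set: only {len(np.unique(assign))} groups "
            f"emerge (identical feature vectors collapse)")

    ids = list(features.index)
    base_cluster = assign[ids.index(baseline_id)]
    rest = [c for c in np.unique(assign) if c != base_cluster]
    mean_sd = {c: features.loc[[i for i, a in zip(ids, assign) if a == c],
                               "lum_sd"].mean() for c in rest}
    rest_sorted = sorted(rest, key=lambda c: -mean_sd[c])
    name = {base_cluster: "baseline", rest_sorted[0]: "complex"}
    for c in rest_sorted[1:]:
        name[c] = "moderate"
    labels = {i: name[a] for i, a in zip(ids, assign)}
    return ComplexityClasses(labels=labels, linkage=link, metric=metric,
                             image_ids=ids)
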