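"""Rotation-invariant texture baselines: GLCM/Haralick and LBP.

GLCMs are accumulated symmetrically with ``d = 1`` at the four standard
angles (0, 45, 90, 135 degrees) on intensities uniformly quantized to ``L``
gray levels (default 8).  Thirteen Haralick statistics are computed per
angle, giving the 52-value ``HARri`` vector (angle-major order).

LBP uses the 8-neighbor, radius-1 circular neighborhood with the
``neighbor >= center`` threshold and the min-over-rotations mapping; the 36
rotation-equivalence classes of 8-bit patterns index the histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.feature import graycomatrix, local_binary_pattern

from .base import FeatureVector, validate_image

__all__ = [
    "GLCMatrix",
    "LBPHistogram",
    "GLCM_ANGLES",
    "HARALICK_NAMES",
    "compute_glcm",
    "haralick_features",
    "rotation_invariant_haralick",
    "lbp_class_representatives",
    "lbp_ri_histogram",
    "lbp_feature_vector",
]

GLCM_ANGLES = (0, 45, 90, 135)

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)


@dataclass
class GLCMatrix:
    levels: int
    matrix: np.ndarray  # (L, L), normalized to sum 1
    offset: Tuple[int, int]  # (d, angle in degrees)


@dataclass
class LBPHistogram:
    bins: np.ndarray  # 36 counts
    neighborhood: Tuple[int, int] = (1, 8)


def _quantize(f: np.ndarray, L: int) -> np.ndarray:
    q = np.floor(f * L).astype(np.uint8)
    return np.minimum(q, L - 1)


def compute_glcm(image: np.ndarray, d: int = 1, angle: int = 0, levels: int = 8) -> GLCMatrix:
    """Normalized symmetric gray-level co-occurrence matrix at offset (d, angle)."""
    if d < 1:
        raise ValueError("distance must be >= 1")
    if angle not in GLCM_ANGLES:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    f = validate_image(image, min_size=2)
    if min(f.shape) <= d:
        raise ValueError("image smaller than the co-occurrence offset")
    q = _quantize(f, levels)
    P = graycomatrix(
        q, distances=[d], angles=[np.deg2rad(angle)], levels=levels,
        symmetric=True, normed=True,
    )[:, :, 0, 0]
    return GLCMatrix(levels=levels, matrix=P, offset=(d, angle))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def haralick_features(glcm: GLCMatrix) -> np.ndarray:
    """The 13 classic Haralick statistics of a normalized GLCM.

    Order follows :data:`HARALICK_NAMES`.  Natural logarithms; 0*log(0) = 0;
    degenerate denominators (constant marginals) yield 0 for the correlation
    statistics.
    """
    P = np.asarray(glcm.matrix, dtype=float)
    if abs(P.sum() - 1.0) > 1e-8 or np.any(P < 0):
        raise ValueError("GLCM must be normalized to sum 1")
    L = P.shape[0]
    i = np.arange(L)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # sum / difference distributions p_{x+y}, p_{|x-y|}
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (I + J).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    asm = float(np.sum(P**2))
    contrast = float(np.sum((I - J) ** 2 * P))
    if sd_x > 0 and sd_y > 0:
        correlation = float((np.sum(I * J * P) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(np.sum((I - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (I - J) ** 2)))
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    sum_ent = _entropy(p_sum)
    ent = _entropy(P.ravel())
    diff_avg = float(np.sum(k_diff * p_diff))
    diff_var = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    diff_ent = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = np.outer(px, py)
    nz = (P > 0) & (pxy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log(pxy[nz])))
    nz2 = pxy > 0
    hxy2 = float(-np.sum(pxy[nz2] * np.log(pxy[nz2])))
    denom = max(hx, hy)
    ic1 = (ent - hxy1) / denom if denom > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, ent, diff_var, diff_ent, ic1, ic2,
    ])


def rotation_invariant_haralick(image: np.ndarray, levels: int = 8) -> FeatureVector:
    """HARri: 13 Haralick statistics on each of the four d=1 GLCMs (52 values,
    angle-major order)."""
    values = []
    labels = []
    for angle in GLCM_ANGLES:
        g = compute_glcm(image, d=1, angle=angle, levels=levels)
        values.append(haralick_features(g))
        labels.extend(f"glcm{angle}_{name}" for name in HARALICK_NAMES)
    return FeatureVector(
        descriptor_name="HARri", labels=labels, values=np.concatenate(values)
    )


def lbp_class_representatives() -> np.ndarray:
    """Sorted representatives (min over circular bit-rotations) of the 36
    rotation-equivalence classes of 8-bit patterns."""
    reps = set()
    for c in range(256):
        reps.add(min(((c << k) | (c >> (8 - k))) & 0xFF for k in range(8)))
    return np.array(sorted(reps))


def lbp_ri_histogram(image: np.ndarray) -> LBPHistogram:
    """Rotation-invariant LBP histogram (8 neighbors, radius 1, 36 bins).

    Diagonal samples are bilinearly interpolated; each 8-bit code is mapped
    to the minimum over its circular bit-rotations; only interior pixels are
    scored so the bin total equals ``(H-2) * (W-2)``.
    """
    f = validate_image(image)
    with warnings.catch_warnings():
        # float input is intentional; codes only feed a coarse histogram
        warnings.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(f, P=8, R=1, method="ror")
    interior = codes[1:-1, 1:-1].astype(int)
    reps = lbp_class_representatives()
    idx = np.searchsorted(reps, interior.ravel())
    bins = np.bincount(idx, minlength=reps.size)
    return LBPHistogram(bins=bins)


def lbp_feature_vector(image: np.ndarray) -> FeatureVector:
    """LBPri: the 36-bin rotation-invariant histogram, normalized to sum 1."""
    hist = lbp_ri_histogram(image)
    reps = lbp_class_representatives()
    total = hist.bins.sum()
    values = hist.bins / total if total else hist.bins.astype(float)
    labels = [f"lbp_{r:03d}" for r in reps]
    return FeatureVector(descriptor_name="LBPri", labels=labels, values=values)
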