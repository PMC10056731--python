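"""Unified descriptor registry: name -> feature extraction.

Covers the 20 moment descriptors plus the two texture baselines, with the
expected feature-vector lengths at the default order (5).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np

from .base import (
    ALL_MOMENT_FAMILIES,
    CARTESIAN_FAMILIES,
    CIRCULAR_FAMILIES,
    FeatureVector,
    MomentSpec,
)
from .cartesian import compute_cartesian_moments
from .circular import compute_circular_moments, magnitudes
from .texture import lbp_feature_vector, rotation_invariant_haralick

__all__ = [
    "ALL_DESCRIPTORS",
    "EXPECTED_SIZES",
    "extract_features",
    "extract_feature_matrix",
]

ALL_DESCRIPTORS = ALL_MOMENT_FAMILIES + ("HARri", "LBPri")

#: feature-vector lengths at order 5 (n_max = m_max = 5)
EXPECTED_SIZES = {
    "LM": 28, "CHM": 21, "CH2M": 21,
    "ZM": 21, "PZM": 36, "OFMM": 66, "CHFM": 66, "PJFM": 66, "JFM": 66,
    "FrJFM": 66, "BFM": 66,
    "RHFM": 66, "EFM": 121, "PCET": 121, "PCT": 66, "PST": 55,
    "FrRHFM": 66, "FrPCET": 121, "FrPCT": 66, "FrPST": 55,
    "HARri": 52, "LBPri": 36,
}


def extract_features(
    image: np.ndarray,
    descriptor: str,
    spec: Optional[MomentSpec] = None,
    glcm_levels: int = 8,
    **spec_overrides,
) -> FeatureVector:
    """Extract one descriptor's feature vector from a grayscale image."""
    if descriptor == "HARri":
        return rotation_invariant_haralick(image, levels=glcm_levels)
    if descriptor == "LBPri":
        return lbp_feature_vector(image)
    if descriptor not in ALL_MOMENT_FAMILIES:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    spec = spec or MomentSpec(family=descriptor, **spec_overrides)
    if spec.family != descriptor:
        raise ValueError("spec family does not match descriptor name")
    if descriptor in CARTESIAN_FAMILIES:
        return compute_cartesian_moments(image, spec)
    return magnitudes(compute_circular_moments(image, spec))


def extract_feature_matrix(
    images: Iterable[np.ndarray],
    descriptor: str,
    spec: Optional[MomentSpec] = None,
    **kwargs,
):
    """Stack one descriptor's features for a collection of images.

    Returns ``(matrix, labels)`` where ``labels`` are the feature labels.
    """
    rows: List[np.ndarray] = []
    labels: List[str] = []
    for img in images:
        fv = extract_features(img, descriptor, spec=spec, **kwargs)
        if not labels:
            labels = fv.labels
        rows.append(fv.values)
    if not rows:
        raise ValueError("no images supplied")
    return np.vstack(rows), labels
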