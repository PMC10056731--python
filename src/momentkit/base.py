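"""Shared descriptor types: family tags, :class:`MomentSpec`, feature containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

#: Cartesian orthogonal moment families.
CARTESIAN_FAMILIES = ("LM", "CHM", "CH2M")

#: Circular families based on Jacobi polynomials.
JACOBI_FAMILIES = ("ZM", "PZM", "OFMM", "CHFM", "PJFM", "JFM", "FrJFM")

#: Circular families based on harmonic functions.
HARMONIC_FAMILIES = (
    "RHFM", "EFM", "PCET", "PCT", "PST",
    "FrRHFM", "FrPCET", "FrPCT", "FrPST",
)

#: Circular families based on eigenfunctions of the Laplacian (Bessel).
EIGENFUNCTION_FAMILIES = ("BFM",)

CIRCULAR_FAMILIES = JACOBI_FAMILIES + EIGENFUNCTION_FAMILIES + HARMONIC_FAMILIES

ALL_MOMENT_FAMILIES = CARTESIAN_FAMILIES + CIRCULAR_FAMILIES

#: Fractional-order family -> integer-order counterpart (alpha = 1 reduction).
FRACTIONAL_BASE = {
    "FrJFM": "JFM",
    "FrRHFM": "RHFM",
    "FrPCET": "PCET",
    "FrPCT": "PCT",
    "FrPST": "PST",
}


def is_fractional(family: str) -> bool:
    return family in FRACTIONAL_BASE


@dataclass
class MomentSpec:
    """Configuration of a single moment descriptor.

    Parameters
    ----------
    family:
        One of :data:`ALL_MOMENT_FAMILIES`.
    n_max:
        Maximum (radial) order. Default 5.
    m_max:
        Maximum absolute angular repetition for circular families. Default 5.
    alpha:
        Fractional-order parameter. Defaults to 1.0 for integer families and
        1.5 for ``Fr*`` families.
    jacobi_p, jacobi_q:
        Jacobi parameters for JFM/FrJFM (must satisfy ``p > q > 0``).
    bessel_nu:
        Order of the Bessel function for BFM.
    """

    family: str
    n_max: int = 5
    m_max: int = 5
    alpha: Optional[float] = None
    jacobi_p: float = 3.0
    jacobi_q: float = 2.0
    bessel_nu: int = 1

    def __post_init__(self) -> None:
        if self.family not in ALL_MOMENT_FAMILIES:
            raise ValueError(f"unknown moment family {self.family!r}")
        if self.n_max < 0:
            raise ValueError("n_max must be non-negative")
        if self.m_max < 0:
            raise ValueError("m_max must be non-negative")
        if self.alpha is None:
            self.alpha = 1.5 if is_fractional(self.family) else 1.0
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.family in ("JFM", "FrJFM") and not (self.jacobi_p > self.jacobi_q > 0):
            raise ValueError("Jacobi parameters must satisfy p > q > 0")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_max": self.n_max,
            "m_max": self.m_max,
            "alpha": self.alpha,
            "jacobi_p": self.jacobi_p,
            "jacobi_q": self.jacobi_q,
            "bessel_nu": self.bessel_nu,
        }


@dataclass
class FeatureVector:
    """Named, ordered real-valued descriptor output."""

    descriptor_name: str
    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ComplexMomentSet:
    """Map from ``(n, m)`` index pairs to complex circular-moment values."""

    family: str
    entries: Dict[Tuple[int, int], complex]
    spec: MomentSpec = field(repr=False)

    def index_pairs(self) -> List[Tuple[int, int]]:
        """Index pairs in the fixed enumeration order (n ascending, then m)."""
        return sorted(self.entries.keys())

    def __len__(self) -> int:
        return len(self.entries)


def validate_image(pixels: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Validate a grayscale image array: 2-D, finite, values in [0, 1]."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(f"image must be at least {min_size}x{min_size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr
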