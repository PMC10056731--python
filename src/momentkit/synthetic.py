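"""Synthetic labeled texture datasets and analytic fixture images.

Three generator families, each probing a different descriptor strength:

* ``oriented_grating`` — sinusoidal gratings with class-specific frequency
  and orientation (angular/radial content, circular moments).
* ``gaussian_random_field`` — smoothed white noise with class-specific
  correlation length (autocorrelation, GLCM).
* ``blob_mixture`` — sums of Gaussian blobs with class-specific count and
  width (low-order shape, Cartesian moments).

All generators are deterministic given the config seed and clip output to
``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .base import MomentSpec
from .circular import circular_index_set, radial_kernel
from .geometry import map_to_unit_disk

__all__ = [
    "SyntheticDatasetConfig",
    "generate_dataset",
    "BasisImage",
    "basis_image",
    "rotated_pair",
]

TEXTURE_FAMILIES = ("oriented_grating", "gaussian_random_field", "blob_mixture")


@dataclass
class SyntheticDatasetConfig:
    n_classes: int = 3
    n_per_class: int = 20
    size: Tuple[int, int] = (64, 64)
    texture_family: str = "oriented_grating"
    class_params: Optional[Sequence[dict]] = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 1:
            raise ValueError("need at least 1 image per class")
        if min(self.size) < 8:
            raise ValueError("images must be at least 8x8")
        if self.texture_family not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {self.texture_family!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_params is not None and len(self.class_params) != self.n_classes:
            raise ValueError("class_params must have one entry per class")


def _default_params(family: str, c: int, n_classes: int) -> dict:
    if family == "oriented_grating":
        return {
            "frequency": 3.0 + 3.0 * c,
            "orientation_deg": 180.0 * c / n_classes,
        }
    if family == "gaussian_random_field":
        return {"sigma": 1.0 + 2.0 * c}
    return {"n_blobs": 2 + 2 * c, "width": 0.08 + 0.05 * c}


def _grating(H, W, params, rng, noise_sd):
    yy, xx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W), indexing="ij")
    phi = np.deg2rad(params["orientation_deg"])
    phase = rng.uniform(0, 2 * np.pi)
    u = xx * np.cos(phi) + yy * np.sin(phi)
    img = 0.5 + 0.4 * np.sin(2 * np.pi * params["frequency"] * u + phase)
    return img + rng.normal(0.0, noise_sd, size=img.shape)


def _random_field(H, W, params, rng, noise_sd):
    noise = rng.normal(size=(H, W))
    smooth = gaussian_filter(noise, sigma=params["sigma"], mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / (4.0 * sd)
    img = 0.5 + smooth
    return img + rng.normal(0.0, noise_sd, size=img.shape)


def _blobs(H, W, params, rng, noise_sd):
    yy, xx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W), indexing="ij")
    img = np.full((H, W), 0.2)
    for _ in range(int(params["n_blobs"])):
        cx, cy = rng.uniform(-0.7, 0.7, size=2)
        w = params["width"] * rng.uniform(0.8, 1.2)
        img += 0.6 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * w**2))
    return img + rng.normal(0.0, noise_sd, size=img.shape)


_GENERATORS = {
    "oriented_grating": _grating,
    "gaussian_random_field": _random_field,
    "blob_mixture": _blobs,
}


def generate_dataset(config: SyntheticDatasetConfig):
    """Generate a labeled image collection.

    Returns ``(images, labels)`` where ``images`` is a list of ``(H, W)``
    float arrays in ``[0, 1]`` and ``labels`` an integer array.  Byte-identical
    across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.size
    gen = _GENERATORS[config.texture_family]
    images: List[np.ndarray] = []
    labels: List[int] = []
    for c in range(config.n_classes):
        params = (
            dict(config.class_params[c])
            if config.class_params is not None
            else _default_params(config.texture_family, c, config.n_classes)
        )
        for _ in range(config.n_per_class):
            img = gen(H, W, params, rng, config.noise_sd)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(c)
    return images, np.asarray(labels)


@dataclass
class BasisImage:
    """Rendered basis function with the affine rescale needed to undo it."""

    pixels: np.ndarray
    scale: float
    offset: float

    def undo_rescale(self) -> np.ndarray:
        return (self.pixels - self.offset) / self.scale


def basis_image(family: str, n: int, m: int, H: int, W: int, spec: MomentSpec | None = None) -> BasisImage:
    """Render the real part of a circular basis function on the disk,
    affinely rescaled into ``[0, 1]``."""
    spec = spec or MomentSpec(family=family)
    if (n, m) not in circular_index_set(spec):
        raise ValueError(f"({n}, {m}) is not in the {family} index set at this order")
    disk = map_to_unit_disk(H, W)
    mask = disk.inside_mask
    vals = np.zeros((H, W))
    kern = radial_kernel(family, n, disk.radius[mask], spec, m=m)
    vals[mask] = np.real(kern * np.exp(1j * m * disk.angle[mask]))
    lo, hi = vals.min(), vals.max()
    scale = 1.0 / (hi - lo) if hi > lo else 1.0
    offset = -lo * scale
    return BasisImage(pixels=vals * scale + offset, scale=scale, offset=offset)


def radial_fixture(H: int = 129, frequency: float = 14.0) -> np.ndarray:
    """Smooth radial test image used by reconstruction-convergence checks.

    The profile ``0.5 + 0.35 exp(-1.5 r) cos(freq * r)`` mixes radial parities
    and carries enough high-order content that truncation error dominates the
    discretization noise floor through order 10.
    """
    yy, xx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, H), indexing="ij")
    r = np.hypot(xx, yy)
    return np.clip(0.5 + 0.35 * np.exp(-1.5 * r) * np.cos(frequency * r), 0.0, 1.0)


def rotated_pair(image: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Exact 90-degree pixel-permutation rotation (no interpolation)."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("rotated_pair requires a square image")
    return np.rot90(image, k=quarter_turns % 4).copy()
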