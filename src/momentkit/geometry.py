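"""Coordinate conventions mapping the pixel grid onto moment domains.

Three domains are supported: the symmetric unit square ``[-1, 1]^2`` used by
continuous Cartesian moments, the integer lattice used by discrete Cartesian
moments, and the unit disk used by circular moments.  Pixel-center (midpoint)
sampling is used everywhere; no sub-pixel quadrature.

Conventions
-----------
* Origin at the image center.  Column index ``j`` maps to
  ``x_j = (2j - W + 1) / W``; row index ``i`` (increasing downward in storage)
  maps to ``y_i = -(2i - H + 1) / H`` for disk coordinates, so that the angle
  ``theta = atan2(y, x)`` follows the mathematical counter-clockwise
  convention.  Rotation-invariance tests depend on this choice.
* The unit disk is inscribed in the image square; pixels with ``r > 1`` are
  excluded from all circular-moment sums (configurable to a circumscribed
  variant via ``scale``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CartesianSupport",
    "DiskCoordinates",
    "cartesian_support",
    "map_to_unit_disk",
    "fractional_substitution",
]


@dataclass
class CartesianSupport:
    """1-D coordinate arrays for a separable Cartesian domain."""

    x: np.ndarray  # per-column coordinate, length W
    y: np.ndarray  # per-row coordinate, length H
    domain_tag: str  # "symmetric_unit_square" | "discrete_lattice"
    cell_area: float


@dataclass
class DiskCoordinates:
    """Per-pixel polar coordinates and the inscribed-disk mask."""

    radius: np.ndarray  # (H, W), values in [0, sqrt(2)]
    angle: np.ndarray  # (H, W), values in [-pi, pi)
    inside_mask: np.ndarray  # (H, W) bool, r <= 1
    cell_area: float


def cartesian_support(H: int, W: int, domain_tag: str = "symmetric_unit_square") -> CartesianSupport:
    """Build the separable coordinate support for an ``H x W`` pixel grid.

    For ``symmetric_unit_square`` pixel centers are
    ``x_j = (2j - W + 1)/W``, ``y_i = (2i - H + 1)/H`` and the cell area is
    ``4/(H*W)``; for ``discrete_lattice`` coordinates are the integer indices
    and the cell area is 1.
    """
    if H < 1 or W < 1:
        raise ValueError("image dimensions must be positive")
    if domain_tag == "symmetric_unit_square":
        x = (2 * np.arange(W) - W + 1) / W
        y = (2 * np.arange(H) - H + 1) / H
        delta = 4.0 / (H * W)
    elif domain_tag == "discrete_lattice":
        x = np.arange(W, dtype=float)
        y = np.arange(H, dtype=float)
        delta = 1.0
    else:
        raise ValueError(f"unknown domain tag {domain_tag!r}")
    return CartesianSupport(x=x, y=y, domain_tag=domain_tag, cell_area=delta)


def map_to_unit_disk(H: int, W: int, scale: float = 1.0) -> DiskCoordinates:
    """Map pixel centers onto the unit disk inscribed in the image square.

    ``scale`` rescales the mask radius (``sqrt(2)`` gives the circumscribed
    variant in which every pixel is kept).
    """
    if H < 3 or W < 3:
        raise ValueError("image dimensions must be at least 3")
    if scale <= 0:
        raise ValueError("scale must be positive")
    sup = cartesian_support(H, W, "symmetric_unit_square")
    xx = sup.x[np.newaxis, :]
    # y flipped so theta increases counter-clockwise despite row-major storage
    yy = -sup.y[:, np.newaxis]
    r = np.hypot(xx, yy) / scale
    theta = np.arctan2(np.broadcast_to(yy, (H, W)), np.broadcast_to(xx, (H, W)))
    inside = r <= 1.0
    return DiskCoordinates(
        radius=r,
        angle=theta,
        inside_mask=inside,
        cell_area=sup.cell_area / scale**2,
    )


def fractional_substitution(r, alpha: float):
    """Fractional-order radial substitution ``r -> r**alpha``.

    Returns ``(r_sub, weight)`` where ``weight = alpha * r**(2*alpha - 2)`` is
    the change-of-variable Jacobian to be folded into the radial inner product
    so that the substituted basis stays orthogonal on the disk.  ``alpha = 1``
    is the exact identity.  At ``r = 0`` with ``alpha < 1`` the (measure-zero)
    divergent weight is replaced by 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("radius must lie in [0, 1]")
    if alpha == 1.0:
        return r, np.ones_like(r)
    r_sub = np.power(r, alpha)
    with np.errstate(divide="ignore", over="ignore"):
        weight = alpha * np.power(r, 2.0 * alpha - 2.0)
    weight = np.where(r == 0.0, 0.0 if alpha < 1.0 else weight, weight)
    weight = np.where(np.isfinite(weight), weight, 0.0)
    return r_sub, weight
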