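"""Cartesian orthogonal moments: Legendre (LM) and discrete Chebyshev
moments of the first (CHM) and second (CH2M) kind.

LM is computed on the symmetric unit square with midpoint sampling of the
continuous inner product; CHM/CH2M are exactly orthonormal on the integer
lattice, so their forward/inverse transforms round-trip polynomial images
to machine precision.

Index-set convention: the triangular set ``p + q <= bound`` with ``bound =
n_max`` for CHM/CH2M (21 features at order 5) and ``bound = n_max + 1`` for
LM (28 features at order 5).  The LM bound is configurable via
``lm_order_bonus``.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy.special import eval_chebyu, eval_legendre

from .base import FeatureVector, MomentSpec, validate_image
from .geometry import cartesian_support

__all__ = [
    "legendre_polynomial",
    "tchebichef_polynomial",
    "tchebichef_basis",
    "chebyshev2_polynomial",
    "chebyshev2_basis",
    "cartesian_index_set",
    "compute_cartesian_moments",
    "reconstruct_cartesian",
]

#: extra total-degree bound granted to LM so order 5 yields 28 features
LM_ORDER_BONUS = 1


def legendre_polynomial(n: int, x) -> np.ndarray:
    """Legendre polynomial ``P_n(x)`` on ``[-1, 1]``."""
    if n < 0:
        raise ValueError("order must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("argument must lie in [-1, 1]")
    return eval_legendre(n, x)


def tchebichef_basis(n_max: int, N: int) -> np.ndarray:
    """Orthonormal discrete Chebyshev (Tchebichef) polynomials on ``0..N-1``.

    Returns an array of shape ``(n_max + 1, N)`` whose rows satisfy
    ``sum_x t_m(x) t_n(x) = delta_mn`` exactly (to rounding).  Uses the
    squared-norm-normalized three-term recurrence, stable up to N = 512.
    """
    if not 0 <= n_max < N:
        raise ValueError("need 0 <= n_max < N")
    x = np.arange(N, dtype=float)
    T = np.empty((n_max + 1, N))
    T[0] = 1.0 / np.sqrt(N)
    if n_max >= 1:
        T[1] = (2.0 * x + 1.0 - N) * np.sqrt(3.0 / (N * (N**2 - 1.0)))
    for n in range(2, n_max + 1):
        b1 = (2.0 / n) * np.sqrt((4.0 * n**2 - 1.0) / (N**2 - n**2))
        b2 = ((1.0 - N) / n) * np.sqrt((4.0 * n**2 - 1.0) / (N**2 - n**2))
        b3 = ((n - 1.0) / n) * np.sqrt((2.0 * n + 1.0) / (2.0 * n - 3.0))
        b3 *= np.sqrt((N**2 - (n - 1.0) ** 2) / (N**2 - n**2))
        T[n] = (b1 * x + b2) * T[n - 1] - b3 * T[n - 2]
    return T


def tchebichef_polynomial(n: int, x, N: int) -> np.ndarray:
    """Orthonormal Tchebichef polynomial value ``t_n(x; N)``."""
    if not 0 <= n < N:
        raise ValueError("need 0 <= n < N")
    x = np.asarray(x)
    vals = tchebichef_basis(n, N)[n]
    return vals[x.astype(int)] if x.ndim else vals[int(x)]


def chebyshev2_basis(n_max: int, N: int) -> np.ndarray:
    """Lattice-orthonormalized second-kind Chebyshev functions.

    ``U_n`` is sampled at the lattice mapped into ``(-1, 1)``, multiplied by
    the square root of the second-kind weight ``sqrt(1 - u^2)`` and the set is
    re-orthonormalized over the lattice (QR with positive-diagonal sign fix),
    so discrete orthonormality holds by construction while the n-th function
    keeps polynomial degree n.
    """
    if not 0 <= n_max < N:
        raise ValueError("need 0 <= n_max < N")
    u = (2.0 * np.arange(N) - N + 1.0) / N  # interior points, |u| < 1
    w = np.sqrt(np.sqrt(1.0 - u**2))  # sqrt of the weight
    A = np.stack([eval_chebyu(n, u) * w for n in range(n_max + 1)], axis=1)
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return (Q * signs).T


def chebyshev2_polynomial(n: int, x, N: int) -> np.ndarray:
    """Discretely orthonormal second-kind Chebyshev value at lattice point(s)."""
    if not 0 <= n < N:
        raise ValueError("need 0 <= n < N")
    x = np.asarray(x)
    vals = chebyshev2_basis(n, N)[n]
    return vals[x.astype(int)] if x.ndim else vals[int(x)]


def cartesian_index_set(spec: MomentSpec) -> List[Tuple[int, int]]:
    """Triangular ``(p, q)`` index set in lexicographic order."""
    bound = spec.n_max + (LM_ORDER_BONUS if spec.family == "LM" else 0)
    return [(p, q) for p in range(bound + 1) for q in range(bound + 1 - p)]


def _basis_1d(spec: MomentSpec, N: int, n_max: int):
    """Per-axis kernel matrix ``(n_max + 1, N)`` and the domain tag."""
    if spec.family == "LM":
        sup = cartesian_support(N, N, "symmetric_unit_square")
        B = np.stack([eval_legendre(n, sup.x) for n in range(n_max + 1)])
        return B, "symmetric_unit_square"
    if spec.family == "CHM":
        return tchebichef_basis(n_max, N), "discrete_lattice"
    if spec.family == "CH2M":
        return chebyshev2_basis(n_max, N), "discrete_lattice"
    raise ValueError(f"{spec.family!r} is not a Cartesian moment family")


def compute_cartesian_moments(image: np.ndarray, spec: MomentSpec) -> FeatureVector:
    """Compute ``M_pq = Delta * sum h_p(x) h_q(y) f(x, y)`` over the index set.

    LM includes the continuous normalization ``(2p+1)(2q+1)/4`` so that the
    constant image ``f = 1`` has ``M_00 = 1``.
    """
    f = validate_image(image)
    H, W = f.shape
    pairs = cartesian_index_set(spec)
    bound = max(p for p, _ in pairs)
    Bx, tag = _basis_1d(spec, W, bound)
    By, _ = _basis_1d(spec, H, bound)
    delta = cartesian_support(H, W, tag).cell_area
    # moments of a separable basis: M = By f Bx^T (rows = q over y, cols = p over x)
    M = delta * (By @ f @ Bx.T)
    values = np.array([M[q, p] for p, q in pairs])
    if spec.family == "LM":
        norm = np.array([(2 * p + 1) * (2 * q + 1) / 4.0 for p, q in pairs])
        values = values * norm
    labels = [f"(p={p},q={q})" for p, q in pairs]
    return FeatureVector(descriptor_name=spec.family, labels=labels, values=values)


def reconstruct_cartesian(features: FeatureVector, spec: MomentSpec, H: int, W: int) -> np.ndarray:
    """Inverse transform of :func:`compute_cartesian_moments`.

    Exact for CHM/CH2M when the image lies in the span of the retained basis;
    for LM the midpoint quadrature limits accuracy.
    """
    pairs = cartesian_index_set(spec)
    if len(pairs) != len(features):
        raise ValueError("feature vector length does not match the spec index set")
    bound = max(p for p, _ in pairs)
    Bx, _ = _basis_1d(spec, W, bound)
    By, _ = _basis_1d(spec, H, bound)
    out = np.zeros((H, W))
    for (p, q), v in zip(pairs, features.values):
        out += v * np.outer(By[q], Bx[p])
    return out
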