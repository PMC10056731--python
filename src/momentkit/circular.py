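"""Circular (radial) orthogonal moments on the unit disk.

Implements the Jacobi-polynomial families (ZM, PZM, OFMM, CHFM, PJFM, JFM),
the harmonic families (RHFM, EFM, PCET, PCT, PST), the eigenfunction family
(BFM), and the fractional-order variants (FrJFM, FrRHFM, FrPCET, FrPCT,
FrPST), plus magnitude feature extraction and reconstruction.

Every radial set is normalized so that ``int_0^1 R_n(r) R_k(r) r dr =
delta_nk``; together with the angular factor ``exp(i m theta)/sqrt(2*pi)``
the 2-D basis is orthonormal on the disk, which makes the inverse transform
a plain conjugate-transpose sum.  Per-family normalizers:

* ZM/PZM: classic radial polynomials scaled by ``sqrt(2(n+1))``.
* OFMM/CHFM/PJFM/JFM: shifted-Jacobi radial functions with the square root
  of the Jacobi weight folded in (OFMM = JFM(p=2, q=2), CHFM = JFM(2, 3/2),
  PJFM = JFM(4, 3)).
* BFM: ``sqrt(2) J_nu(lambda_n r) / |J_{nu+1}(lambda_n)|`` with ``lambda_n``
  the n-th positive zero of ``J_nu``.
* RHFM: ``sqrt(1/r)`` constant / ``sqrt(2/r) sin(2k pi r)`` /
  ``sqrt(2/r) cos(2k pi r)``.
* EFM: ``sqrt(1/r) exp(i 2 pi n r)``; PCET: ``sqrt(2) exp(i 2 pi n r^2)``;
  PCT/PST: ``2 cos/sin(pi n r^2)`` (``sqrt(2)`` for PCT at n = 0).

Kernels that diverge like ``r**-1/2`` at the origin are set to 0 at the
exact center pixel (measure zero on the disk).

Fractional-order variants substitute ``r -> r**alpha`` and multiply by the
square root of the Jacobian weight ``alpha * r**(2 alpha - 2)`` so the
substituted radial set stays orthonormal; ``alpha = 1`` reproduces the
integer-order kernels exactly.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial
from typing import Dict, List, Tuple

import numpy as np
from scipy.special import eval_jacobi, gammaln, jn_zeros, jv

from .base import (
    CIRCULAR_FAMILIES,
    FRACTIONAL_BASE,
    ComplexMomentSet,
    FeatureVector,
    MomentSpec,
    is_fractional,
    validate_image,
)
from .geometry import fractional_substitution, map_to_unit_disk

__all__ = [
    "radial_kernel",
    "circular_index_set",
    "compute_circular_moments",
    "magnitudes",
    "reconstruct",
    "basis_matrix",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# radial kernels (orthonormal with weight r on [0, 1])
# ---------------------------------------------------------------------------

def _zernike_radial(n: int, m: int, r: np.ndarray) -> np.ndarray:
    m = abs(m)
    if n < m or (n - m) % 2:
        raise ValueError(f"illegal Zernike index (n={n}, m={m})")
    out = np.zeros_like(r)
    for s in range((n - m) // 2 + 1):
        c = (-1) ** s * factorial(n - s) / (
            factorial(s) * factorial((n + m) // 2 - s) * factorial((n - m) // 2 - s)
        )
        out += c * r ** (n - 2 * s)
    return np.sqrt(2.0 * (n + 1)) * out


def _pseudo_zernike_radial(n: int, m: int, r: np.ndarray) -> np.ndarray:
    m = abs(m)
    if n < m:
        raise ValueError(f"illegal pseudo-Zernike index (n={n}, m={m})")
    out = np.zeros_like(r)
    for s in range(n - m + 1):
        c = (-1) ** s * factorial(2 * n + 1 - s) / (
            factorial(s) * factorial(n - m - s) * factorial(n + m + 1 - s)
        )
        out += c * r ** (n - s)
    return np.sqrt(2.0 * (n + 1)) * out


def _jacobi_radial(n: int, p: float, q: float, r: np.ndarray) -> np.ndarray:
    """Shifted-Jacobi radial function, orthonormal with weight r on [0, 1].

    Built from ``P_n^{(p-q, q-1)}(2r - 1)`` with the square root of the
    weight ``(1-r)^{p-q} r^{q-2}`` folded in.
    """
    if n < 0:
        raise ValueError("radial order must be non-negative")
    a, b = p - q, q - 1.0
    # squared norm of P_n^{(a,b)} on [0,1] after u = 2r - 1
    log_c = (
        gammaln(n + a + 1.0)
        + gammaln(n + b + 1.0)
        - np.log(2.0 * n + a + b + 1.0)
        - gammaln(n + 1.0)
        - gammaln(n + a + b + 1.0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.power(1.0 - r, 0.5 * (p - q)) * np.power(r, 0.5 * (q - 2.0))
    w = np.where(np.isfinite(w), w, 0.0)  # r = 0 singular point for q < 2
    return np.exp(-0.5 * log_c) * w * eval_jacobi(n, a, b, 2.0 * r - 1.0)


@lru_cache(maxsize=None)
def _bessel_zeros(nu: int, count: int) -> tuple:
    return tuple(jn_zeros(nu, count))


def _bessel_radial(n: int, nu: int, r: np.ndarray) -> np.ndarray:
    if n < 0:
        raise ValueError("radial order must be non-negative")
    lam = _bessel_zeros(nu, n + 1)[n]
    return np.sqrt(2.0) * jv(nu, lam * r) / abs(jv(nu + 1, lam))


def _inv_sqrt_r(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        s = 1.0 / np.sqrt(r)
    return np.where(r == 0.0, 0.0, s)


def _rhfm_radial(n: int, r: np.ndarray) -> np.ndarray:
    if n < 0:
        raise ValueError("radial order must be non-negative")
    if n == 0:
        return _inv_sqrt_r(r)
    k = (n + 1) // 2
    s = _inv_sqrt_r(r) * np.sqrt(2.0)
    if n % 2:
        return s * np.sin(_TWO_PI * k * r)
    return s * np.cos(_TWO_PI * k * r)


def _integer_radial(family: str, n: int, r: np.ndarray, spec: MomentSpec, m: int):
    if family == "ZM":
        return _zernike_radial(n, m, r)
    if family == "PZM":
        return _pseudo_zernike_radial(n, m, r)
    if family == "OFMM":
        return _jacobi_radial(n, 2.0, 2.0, r)
    if family == "CHFM":
        return _jacobi_radial(n, 2.0, 1.5, r)
    if family == "PJFM":
        return _jacobi_radial(n, 4.0, 3.0, r)
    if family == "JFM":
        return _jacobi_radial(n, spec.jacobi_p, spec.jacobi_q, r)
    if family == "BFM":
        return _bessel_radial(n, spec.bessel_nu, r)
    if family == "RHFM":
        return _rhfm_radial(n, r)
    if family == "EFM":
        return _inv_sqrt_r(r) * np.exp(1j * _TWO_PI * n * r)
    if family == "PCET":
        return np.sqrt(2.0) * np.exp(1j * _TWO_PI * n * r**2)
    if family == "PCT":
        if n < 0:
            raise ValueError("PCT radial order must be non-negative")
        if n == 0:
            return np.full_like(r, np.sqrt(2.0))
        return 2.0 * np.cos(np.pi * n * r**2)
    if family == "PST":
        if n < 1:
            raise ValueError("PST radial order must be positive")
        return 2.0 * np.sin(np.pi * n * r**2)
    raise ValueError(f"{family!r} is not a circular moment family")


def radial_kernel(family: str, n: int, r, spec: MomentSpec | None = None, m: int = 0):
    """Evaluate a family's radial kernel at radii ``r`` in ``[0, 1]``.

    For ZM/PZM the kernel depends on the angular repetition ``m`` as well.
    ``Fr*`` families apply the fractional substitution from
    :func:`momentkit.geometry.fractional_substitution`.
    """
    if spec is None:
        spec = MomentSpec(family=family if family in CIRCULAR_FAMILIES else "ZM")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("radius must lie in [0, 1]")
    base = FRACTIONAL_BASE.get(family)
    if base is None:
        return _integer_radial(family, n, r, spec, m)
    if spec.alpha == 1.0:
        return _integer_radial(base, n, r, spec, m)
    r_sub, weight = fractional_substitution(r, spec.alpha)
    return np.sqrt(weight) * _integer_radial(base, n, r_sub, spec, m)


# ---------------------------------------------------------------------------
# index sets and moment computation
# ---------------------------------------------------------------------------

def circular_index_set(spec: MomentSpec) -> List[Tuple[int, int]]:
    """``(n, m)`` pairs in the fixed enumeration order (n asc, then m asc).

    ZM: ``0 <= n <= n_max``, ``|m| <= n``, ``n - |m|`` even; PZM: ``|m| <= n``;
    EFM/PCET: ``n, m in [-n_max, n_max]``; PST: ``1 <= n``; all others:
    ``0 <= n <= n_max``, ``|m| <= m_max``.  Both signs of ``m`` are kept.
    """
    fam = FRACTIONAL_BASE.get(spec.family, spec.family)
    N, M = spec.n_max, spec.m_max
    if fam == "ZM":
        pairs = [(n, m) for n in range(N + 1) for m in range(-n, n + 1)
                 if (n - abs(m)) % 2 == 0]
    elif fam == "PZM":
        pairs = [(n, m) for n in range(N + 1) for m in range(-n, n + 1)]
    elif fam in ("EFM", "PCET"):
        pairs = [(n, m) for n in range(-N, N + 1) for m in range(-N, N + 1)]
    elif fam == "PST":
        pairs = [(n, m) for n in range(1, N + 1) for m in range(-M, M + 1)]
    else:
        pairs = [(n, m) for n in range(N + 1) for m in range(-M, M + 1)]
    return sorted(pairs)


def _kernel_table(spec: MomentSpec, r: np.ndarray, theta: np.ndarray):
    """Conjugated basis samples for every index pair; shape (n_pairs, n_pixels)."""
    pairs = circular_index_set(spec)
    fam = FRACTIONAL_BASE.get(spec.family, spec.family)
    ang_cache: Dict[int, np.ndarray] = {}
    rad_cache: Dict[Tuple[int, int], np.ndarray] = {}
    rows = np.empty((len(pairs), r.size), dtype=complex)
    for i, (n, m) in enumerate(pairs):
        rkey = (n, abs(m)) if fam in ("ZM", "PZM") else (n, 0)
        if rkey not in rad_cache:
            rad_cache[rkey] = radial_kernel(spec.family, n, r, spec, m=m)
        if m not in ang_cache:
            ang_cache[m] = np.exp(1j * m * theta)
        rows[i] = rad_cache[rkey] * ang_cache[m]
    return pairs, rows / np.sqrt(_TWO_PI)


def compute_circular_moments(image: np.ndarray, spec: MomentSpec) -> ComplexMomentSet:
    """Project an image onto a circular family's basis over the inscribed disk.

    ``M(n, m) = Delta * sum_disk conj(R_n(r) exp(i m theta)) f / sqrt(2 pi)``.
    """
    if spec.family not in CIRCULAR_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a circular moment family")
    f = validate_image(image)
    H, W = f.shape
    disk = map_to_unit_disk(H, W)
    mask = disk.inside_mask
    r = disk.radius[mask]
    theta = disk.angle[mask]
    pairs, basis = _kernel_table(spec, r, theta)
    vals = disk.cell_area * (np.conj(basis) @ f[mask])
    entries = {pair: complex(v) for pair, v in zip(pairs, vals)}
    return ComplexMomentSet(family=spec.family, entries=entries, spec=spec)


def magnitudes(moments: ComplexMomentSet) -> FeatureVector:
    """Rotation-invariant magnitude features ``|M(n, m)|`` in index order."""
    pairs = moments.index_pairs()
    values = np.array([abs(moments.entries[p]) for p in pairs])
    labels = [f"(n={n},m={m})" for n, m in pairs]
    return FeatureVector(descriptor_name=moments.family, labels=labels, values=values)


def reconstruct(moments: ComplexMomentSet, H: int, W: int) -> np.ndarray:
    """Inverse transform: ``f_hat = sum M(n,m) R_n(r) exp(i m theta)/sqrt(2 pi)``.

    Evaluated inside the disk; pixels outside are 0.  Output is the real part
    (clipped to finite values, not to ``[0, 1]``).
    """
    spec = moments.spec
    disk = map_to_unit_disk(H, W)
    mask = disk.inside_mask
    r = disk.radius[mask]
    theta = disk.angle[mask]
    pairs, basis = _kernel_table(spec, r, theta)
    coeffs = np.array([moments.entries[p] for p in pairs])
    vals = coeffs @ basis
    out = np.zeros((H, W))
    out[mask] = np.real(vals)
    return np.nan_to_num(out, posinf=0.0, neginf=0.0)


def basis_matrix(spec: MomentSpec, H: int, W: int):
    """Discretized (conjugate) basis over disk pixels, with the cell area.

    Returns ``(pairs, rows, delta)`` where ``rows`` has one basis sample
    vector per index pair; used by orthogonality diagnostics and tests.
    """
    disk = map_to_unit_disk(H, W)
    mask = disk.inside_mask
    pairs, rows = _kernel_table(spec, disk.radius[mask], disk.angle[mask])
    return pairs, rows, disk.cell_area
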