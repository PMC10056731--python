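import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import jv

from momentkit.base import CIRCULAR_FAMILIES, FRACTIONAL_BASE, MomentSpec
from momentkit.circular import (
    basis_matrix,
    circular_index_set,
    compute_circular_moments,
    magnitudes,
    radial_kernel,
    reconstruct,
)
from momentkit.synthetic import basis_image, radial_fixture, rotated_pair

ORDER5_SIZES = {
    "ZM": 21, "PZM": 36, "OFMM": 66, "CHFM": 66, "PJFM": 66, "JFM": 66,
    "FrJFM": 66, "BFM": 66, "RHFM": 66, "EFM": 121, "PCET": 121, "PCT": 66,
    "PST": 55, "FrRHFM": 66, "FrPCET": 121, "FrPCT": 66, "FrPST": 55,
}


class TestRadialKernel:
    def test_zernike_constant(self):
        r = np.linspace(0, 1, 11)
        vals = radial_kernel("ZM", 0, r, m=0)
        # R_00 = 1 up to the sqrt(2(n+1)) orthonormalization
        np.testing.assert_allclose(vals, np.sqrt(2.0))

    def test_zernike_r20_at_1(self):
        # R_{2,0}(1) = 2*1 - 1 = 1 before normalization
        val = radial_kernel("ZM", 2, np.array([1.0]), m=0)
        assert val[0] == pytest.approx(np.sqrt(6.0))

    def test_bessel_first_zero(self):
        # root-finding oracle on J_1
        lam_oracle = brentq(lambda x: jv(1, x), 3.0, 4.5)
        assert lam_oracle == pytest.approx(3.8317, abs=1e-4)
        from momentkit.circular import _bessel_zeros

        assert _bessel_zeros(1, 1)[0] == pytest.approx(lam_oracle, abs=1e-10)

    def test_illegal_zernike_index(self):
        with pytest.raises(ValueError):
            radial_kernel("ZM", 1, np.array([0.5]), m=0)  # n - |m| odd

    def test_illegal_pst_index(self):
        with pytest.raises(ValueError):
            radial_kernel("PST", 0, np.array([0.5]))

    def test_singular_kernels_zero_at_origin(self):
        for fam in ("RHFM", "EFM", "CHFM"):
            v = radial_kernel(fam, 0, np.array([0.0]))
            assert v[0] == 0.0

    @pytest.mark.parametrize("fam", ["ZM", "PZM", "OFMM", "CHFM", "PJFM", "JFM",
                                     "BFM", "RHFM", "PCT", "PST"])
    def test_radial_orthonormality_by_quadrature(self, fam):
        # fine midpoint quadrature oracle, weight r on [0, 1]
        spec = MomentSpec(family=fam)
        M = 100000
        r = (np.arange(M) + 0.5) / M
        ns = range(1, 6) if fam == "PST" else range(6)
        if fam in ("ZM", "PZM"):
            K = np.stack([radial_kernel(fam, n, r, spec, m=0) for n in range(0, 6, 1 if fam == "PZM" else 2)])
        else:
            K = np.stack([radial_kernel(fam, n, r, spec) for n in ns])
        G = (K * r / M) @ K.T
        np.testing.assert_allclose(G, np.eye(K.shape[0]), atol=2e-3)

    def test_complex_radial_orthonormality(self):
        M = 100000
        r = (np.arange(M) + 0.5) / M
        for fam in ("EFM", "PCET"):
            K = np.stack([radial_kernel(fam, n, r) for n in range(-3, 4)])
            G = (K * r / M) @ K.conj().T
            np.testing.assert_allclose(G, np.eye(7), atol=2e-3)


class TestIndexSets:
    @pytest.mark.parametrize("fam,size", sorted(ORDER5_SIZES.items()))
    def test_order5_sizes(self, fam, size):
        assert len(circular_index_set(MomentSpec(family=fam))) == size

    def test_zm_parity(self):
        pairs = circular_index_set(MomentSpec(family="ZM"))
        assert all((n - abs(m)) % 2 == 0 for n, m in pairs)

    def test_enumeration_sorted(self):
        pairs = circular_index_set(MomentSpec(family="PZM"))
        assert pairs == sorted(pairs)


class TestComputeMoments:
    def test_constant_image_angular_vanishing(self):
        # discretely the angular sums vanish only to grid tolerance (pixels
        # near the disk boundary break exact polar symmetry for even m)
        ms = compute_circular_moments(np.ones((65, 65)), MomentSpec(family="PZM"))
        for (n, m), v in ms.entries.items():
            if m % 2:  # odd m cancels exactly by the grid's point symmetry
                assert abs(v) < 1e-12
            elif m != 0:
                assert abs(v) < 0.02

    def test_conjugate_symmetry_real_radial(self, random_image):
        for fam in ("ZM", "OFMM", "RHFM", "PCT"):
            ms = compute_circular_moments(random_image, MomentSpec(family=fam))
            for (n, m), v in ms.entries.items():
                if m > 0:
                    assert abs(np.conj(v) - ms.entries[(n, -m)]) <= 1e-10 * max(abs(v), 1e-15)

    def test_conjugate_symmetry_complex_radial(self, random_image):
        for fam in ("EFM", "PCET"):
            ms = compute_circular_moments(random_image, MomentSpec(family=fam))
            for (n, m), v in ms.entries.items():
                assert np.conj(v) == pytest.approx(ms.entries[(-n, -m)], abs=1e-12)

    def test_non_circular_family_rejected(self, random_image):
        with pytest.raises(ValueError):
            compute_circular_moments(random_image, MomentSpec(family="CHM"))

    def test_magnitude_vector(self, random_image):
        fv = magnitudes(compute_circular_moments(random_image, MomentSpec(family="ZM")))
        assert len(fv) == 21
        assert fv.labels[0] == "(n=0,m=0)"
        # conjugate pairs give equal magnitudes
        ms = compute_circular_moments(random_image, MomentSpec(family="PZM"))
        fvp = magnitudes(ms)
        vals = dict(zip([tuple(map(int, lab.strip("()").replace("n=", "").replace("m=", "").split(","))) for lab in fvp.labels], fvp.values))
        for (n, m), v in vals.items():
            if m > 0:
                assert v == pytest.approx(vals[(n, -m)], abs=1e-10)


class TestRotationInvariance:
    @pytest.mark.parametrize("fam", sorted(CIRCULAR_FAMILIES))
    def test_90_degree_exact(self, fam, random_image):
        f1 = magnitudes(compute_circular_moments(random_image, MomentSpec(family=fam))).values
        rot = rotated_pair(random_image, 1)
        f2 = magnitudes(compute_circular_moments(rot, MomentSpec(family=fam))).values
        assert np.abs(f1 - f2).max() <= 1e-10 * max(np.abs(f1).max(), 1e-15)

    def test_30_degree_bilinear(self, smooth_image):
        from scipy.ndimage import rotate

        rot = np.clip(rotate(smooth_image, 30, reshape=False, order=1,
                             mode="constant", cval=0.5), 0, 1)
        for fam in ("ZM", "RHFM", "PCT"):
            f1 = magnitudes(compute_circular_moments(smooth_image, MomentSpec(family=fam))).values
            f2 = magnitudes(compute_circular_moments(rot, MomentSpec(family=fam))).values
            rel = np.mean(np.abs(f1 - f2)) / np.mean(np.abs(f1))
            assert rel < 0.05


class TestFractionalReduction:
    @pytest.mark.parametrize("fam", sorted(FRACTIONAL_BASE))
    def test_alpha_1_matches_integer_family(self, fam, random_image):
        base = FRACTIONAL_BASE[fam]
        a = compute_circular_moments(random_image, MomentSpec(family=fam, alpha=1.0))
        b = compute_circular_moments(random_image, MomentSpec(family=base))
        for key, v in b.entries.items():
            assert a.entries[key] == pytest.approx(v, abs=1e-10)

    def test_alpha_not_1_differs(self, random_image):
        a = magnitudes(compute_circular_moments(random_image, MomentSpec(family="FrRHFM", alpha=1.5))).values
        b = magnitudes(compute_circular_moments(random_image, MomentSpec(family="RHFM"))).values
        assert np.abs(a - b).max() > 1e-6


class TestReconstruction:
    def test_zero_moments_zero_image(self):
        spec = MomentSpec(family="ZM")
        ms = compute_circular_moments(np.zeros((33, 33)), spec)
        rec = reconstruct(ms, 33, 33)
        np.testing.assert_array_equal(rec, np.zeros((33, 33)))

    def test_projection_concentrates(self):
        # projection oracle: basis image of (2, 0) projects mainly onto (2, 0)
        bi = basis_image("ZM", 2, 0, 64, 64)
        ms = compute_circular_moments(bi.pixels, MomentSpec(family="ZM"))
        mags = {k: abs(v) for k, v in ms.entries.items()}
        # remove the DC offset introduced by the [0,1] rescale
        mags.pop((0, 0))
        assert max(mags, key=mags.get) == (2, 0)

    @pytest.mark.parametrize("fam", ["ZM", "PZM", "RHFM"])
    def test_error_non_increasing(self, fam):
        img = radial_fixture(129)
        mask = np.hypot(*np.meshgrid(np.linspace(-1, 1, 129), np.linspace(-1, 1, 129))) <= 1
        errs = []
        for n_max in range(2, 11, 2):
            spec = MomentSpec(family=fam, n_max=n_max, m_max=5)
            rec = reconstruct(compute_circular_moments(img, spec), 129, 129)
            errs.append(np.sqrt(np.mean((rec[mask] - img[mask]) ** 2)))
        assert all(errs[i + 1] <= errs[i] * (1 + 1e-9) for i in range(len(errs) - 1))


class TestDiscreteOrthogonality:
    @pytest.mark.parametrize("fam", sorted(CIRCULAR_FAMILIES))
    def test_gram_256(self, fam):
        pairs, rows, delta = basis_matrix(MomentSpec(family=fam), 256, 256)
        G = delta * (rows @ rows.conj().T)
        d = np.sqrt(np.real(np.diag(G)))
        Gn = G / np.outer(d, d)
        off = np.abs(Gn - np.eye(len(pairs))).max()
        assert off < 5e-2
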