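"""Forward-model unit tests: elementary pieces, the probing-depth closed
form against its quadrature oracle, the equivalent-medium fixed point, and
the full MTF forward pass."""
import numpy as np
import pytest
import scipy.integrate as si

from sfdiskin import _kernels
from sfdiskin.optics import (AcquisitionGeometry, ChromophoreTable,
                             HomogeneousOptics, InvalidInputError, R_EFF,
                             SkinParameterSet, _equivalent_mua_arrays,
                             dermis_mua, epidermis_absorbance, equivalent_mua,
                             extrapolation_length, forward_mtf,
                             homogeneous_mtf, param_bounds_arrays,
                             probing_depth, reduced_scattering)


@pytest.mark.parametrize("musp540, b, lam, expected", [
    (1.0, 1.2, 540, 1.0),     # reference wavelength
    (1.0, 0.0, 460, 1.0),     # b=0 removes wavelength dependence
    (1.0, 1.0, 270, 2.0),     # (270/540)^-1 = 2
    (2.5, -1.0, 270, 1.25),   # negative scattering power flips the slope
])
def test_reduced_scattering_power_law(musp540, b, lam, expected):
    assert reduced_scattering(musp540, b, lam) == pytest.approx(expected)


def test_reduced_scattering_rejects_nonpositive():
    with pytest.raises(InvalidInputError):
        reduced_scattering(0.0, 1.0, 540)
    with pytest.raises(InvalidInputError):
        reduced_scattering(1.0, 1.0, -540)


class TestChromophores:
    def test_dermis_mua_limits(self, table):
        assert dermis_mua(0.0, 0.5, 540, table) == 0.0
        c = 0.013
        assert dermis_mua(c, 1.0, 623, table) == pytest.approx(
            table.eps_hbo2(623) * c)

    def test_dermis_mua_hand_expansion(self, table):
        expected = 0.004 * table.eps_hb(540) + 0.006 * table.eps_hbo2(540)
        assert dermis_mua(0.01, 0.6, 540, table) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_epidermis_absorbance_linear(self, table):
        assert epidermis_absorbance(0.0, 460, table) == 0.0
        assert epidermis_absorbance(1.0, 460, table) == pytest.approx(
            table.eps_melanin(460))
        assert epidermis_absorbance(0.76, 540, table) == pytest.approx(
            0.76 * table.eps_melanin(540))

    def test_unknown_wavelength_rejected(self, table):
        with pytest.raises(KeyError):
            dermis_mua(0.01, 0.5, 555, table)

    def test_physical_sanity(self, table):
        # hemoglobin absorbs far more in the green than in the red, and
        # melanin absorption decreases monotonically with wavelength
        assert table.eps_hb(540) > table.eps_hb(623)
        eps = [table.eps_melanin(w) for w in (460, 540, 623)]
        assert eps[0] > eps[1] > eps[2]


class TestExtrapolationLength:
    def test_smooth_reference_and_linearity(self):
        mut = 1.3
        l0 = extrapolation_length(1.0, mut)
        assert extrapolation_length(0.8, mut) == pytest.approx(0.8 * l0)
        assert extrapolation_length(1.5, mut) == pytest.approx(1.5 * l0)

    def test_hand_value(self):
        # (2/3) * (1 + 0.493)/(1 - 0.493) / 2.0
        assert extrapolation_length(1.0, 2.0) == pytest.approx(
            (1.0 / 3.0) * (1.0 + R_EFF) / (1.0 - R_EFF))

    def test_monotone(self):
        assert extrapolation_length(1.0, 2.0) < extrapolation_length(1.0, 1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            extrapolation_length(-1.0, 1.0)


def _quadrature_depth(q, mua, musp, l):
    m = mua + musp
    Q = np.sqrt(q * q + 3 * mua * m)
    a, c = 1 + Q * l, 1 + m * l

    def I(z):
        return (a * np.exp(-m * z) - c * np.exp(-Q * z)) ** 2

    top = si.quad(lambda z: z * I(z), 0, np.inf, limit=200)[0]
    bot = si.quad(I, 0, np.inf, limit=200)[0]
    return top / bot


class TestProbingDepth:
    def test_matches_quadrature_oracle_spot_checks(self, rng):
        for _ in range(20):
            mua = rng.uniform(0.005, 0.5)
            musp = rng.uniform(0.3, 2.5)
            alpha = rng.uniform(0.1, 1.5)
            q = rng.choice([0.0, 0.63, 1.26])
            l = float(extrapolation_length(alpha, mua + musp))
            opt = HomogeneousOptics(mua, musp, l)
            L = probing_depth(q, opt)
            assert L == pytest.approx(_quadrature_depth(q, mua, musp, l),
                                      rel=1e-6)

    def test_no_singularity_at_Q_equals_mut(self):
        # q chosen so that Q = mut exactly: q^2 = mut^2 - 3 mua mut.  The
        # two-exponential profile vanishes identically there, so the oracle
        # is the analytic limit of the moment ratio instead of quadrature.
        mua, musp = 0.05, 1.0
        m = mua + musp
        q = np.sqrt(m * m - 3 * mua * m)
        l = float(extrapolation_length(1.0, m))
        opt = HomogeneousOptics(mua, musp, l)
        L = probing_depth(q, opt)
        c = 1 + m * l
        L_limit = (3 * c * c + 4 * c * l * m + 2 * l * l * m * m) / (
            2 * m * (c * c + 2 * c * l * m + 2 * l * l * m * m))
        assert L == pytest.approx(L_limit, rel=1e-12)
        # and the closed form is continuous across the crossing
        assert L == pytest.approx(
            _quadrature_depth(q * (1 + 1e-4), mua, musp, l), rel=1e-3)

    def test_monotone_in_q_and_mua(self):
        musp, alpha = 1.0, 1.0
        qs = np.linspace(0.0, 2.0, 9)
        for mua in (0.01, 0.1, 0.4):
            l = float(extrapolation_length(alpha, mua + musp))
            opt = HomogeneousOptics(mua, musp, l)
            Ls = np.array([probing_depth(q, opt) for q in qs])
            assert np.all(np.diff(Ls) < 0)
        for q in (0.0, 0.63, 1.26):
            Ls = []
            for mua in np.linspace(0.01, 0.5, 8):
                l = float(extrapolation_length(alpha, mua + musp))
                Ls.append(probing_depth(q, HomogeneousOptics(mua, musp, l)))
            assert np.all(np.diff(Ls) < 0)


class TestHomogeneousMtf:
    def test_dc_above_ac_and_monotone_mua(self):
        for mua in (0.02, 0.1, 0.3):
            l = float(extrapolation_length(1.0, mua + 1.0))
            opt = HomogeneousOptics(mua, 1.0, l)
            assert homogeneous_mtf(0.0, opt) > homogeneous_mtf(
                2 * np.pi * 0.2, opt)
        vals = []
        for mua in np.linspace(0.01, 0.5, 8):
            l = float(extrapolation_length(1.0, mua + 1.0))
            vals.append(homogeneous_mtf(1.2566, HomogeneousOptics(mua, 1.0, l)))
        assert np.all(np.diff(vals) < 0)

    def test_dual_implementation_oracle(self):
        """The closed form agrees with the independently coded compiled
        kernel at a fixed operating point."""
        mua, musp, alpha, q = 0.05, 1.0, 1.0, 1.2566
        l = float(extrapolation_length(alpha, mua + musp))
        ours = homogeneous_mtf(q, HomogeneousOptics(mua, musp, l))
        other = _kernels._mtf_scalar(q, mua, musp, l)
        assert ours == pytest.approx(other, rel=1e-14)
        assert 0 < ours < 1


class TestEquivalentMua:
    def test_h_zero_melanin_zero_collapses_to_dermis(self, table):
        mua_d = float(dermis_mua(0.007, 0.6, 540, table))
        mua = _equivalent_mua_arrays(mua_d, 0.0, 1.0, 0.5, 0.0, 0.0)
        assert abs(float(mua) - mua_d) <= 1e-10

    def test_matched_layers_give_dermal_mua(self, table):
        # epidermal per-mm absorption equal to dermal absorption
        mua_d = float(dermis_mua(0.01, 0.7, 540, table))
        for h in (0.05, 0.12, 0.19):
            mua = _equivalent_mua_arrays(mua_d, mua_d * h, 1.2, 0.8, h, 1.2566)
            assert abs(float(mua) - mua_d) <= 1e-10

    def test_generic_fixed_point_residual(self, geom, table, rng):
        lo, hi = param_bounds_arrays()
        for _ in range(20):
            p = SkinParameterSet.from_array(rng.uniform(lo, hi))
            for q in (0.0, geom.q):
                for lam in geom.wavelengths:
                    _, info = equivalent_mua(p, q, lam, table,
                                             full_output=True)
                    assert info["residual"] <= 1e-10
                    assert info["mapping_valid"]


class TestForwardMtf:
    def test_bounds_and_ac_below_dc(self, geom, table, rng):
        lo, hi = param_bounds_arrays()
        P = rng.uniform(lo, hi, size=(50, 7))
        M = forward_mtf(P, geom, table)
        assert np.all(M > 0) and np.all(M < 1)
        assert np.all(M[:, 3:] < M[:, :3])

    def test_hemoglobin_darkens_green(self, geom, table, rng):
        lo, hi = param_bounds_arrays()
        for _ in range(10):
            p = rng.uniform(lo, hi)
            p[0] = rng.uniform(lo[0], hi[0] / 2)
            p2 = p.copy()
            p2[0] = 2 * p[0]
            m1, m2 = forward_mtf(p, geom, table), forward_mtf(p2, geom, table)
            assert m2[1] < m1[1]  # 540 nm DC
            assert m2[4] < m1[4]  # 540 nm AC

    def test_deterministic_bitwise(self, geom, table):
        p = SkinParameterSet(0.007, 0.6, 0.76, 0.84, -0.2, 0.45, 0.13)
        a = forward_mtf(p, geom, table)
        b = forward_mtf(p, geom, table)
        assert np.array_equal(a, b)

    def test_continuity_under_small_perturbations(self, geom, table, rng):
        lo, hi = param_bounds_arrays()
        span = hi - lo
        for _ in range(5):
            p = rng.uniform(lo + 0.1 * span, hi - 0.1 * span)
            m0 = forward_mtf(p, geom, table)
            for j in range(7):
                pj = p.copy()
                pj[j] += 1e-6 * span[j]
                assert np.max(np.abs(forward_mtf(pj, geom, table) - m0)) < 1e-3

    def test_compiled_kernel_parity(self, geom, table, rng):
        """The numba fitting kernel reproduces the vectorized numpy forward
        model to near machine precision."""
        lo, hi = param_bounds_arrays()
        lams = np.asarray(geom.wavelengths)
        hb, hbo2, mel = table.as_arrays(geom.wavelengths)
        buf = np.empty(6)
        for _ in range(25):
            p = rng.uniform(lo, hi)
            ref = forward_mtf(p, geom, table)
            fast = _kernels.forward_mtf6(p, geom.q, lams, hb, hbo2, mel,
                                         buf).copy()
            np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-14)
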