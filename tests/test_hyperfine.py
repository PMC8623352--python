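"""Quadrupole tensors and two-nucleus hyperfine patterns."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amwspec import (HyperfineFitParams, InvalidInputError, QuadrupoleTensor,
                     RotationalLevel, chi_eff, diagonalize_tensor,
                     fit_params_from_tensor, hyperfine_pattern,
                     quadrupole_sublevels, rotate_tensor, scale_tensor,
                     tensor_from_fit_params, theta_str_correction)
from amwspec.datasets import hyperfine_params, quad_tensor


def casimir_energy(chi, J, I, F):
    """Textbook first-order single-nucleus quadrupole energy (oracle)."""
    C = F * (F + 1) - I * (I + 1) - J * (J + 1)
    Y = (0.75 * C * (C + 1) - I * (I + 1) * J * (J + 1)) \
        / (2 * I * (2 * I - 1) * (2 * J - 1) * (2 * J + 3))
    return chi * Y


def uncoupled_eigenvalues(J, chis, I1=1, I2=1):
    """Brute-force H_Q eigenvalues in the |J m><I1 m1><I2 m2| product
    basis (oracle for the coupled-basis recoupling machinery)."""
    from sympy.physics.wigner import wigner_3j

    w3 = {}

    def threej(*a):
        if a not in w3:
            w3[a] = float(wigner_3j(*a))
        return w3[a]

    def reduced_product(chi, I):
        # anchored on the stretched product state = Casimir at F = J + I
        y_stretch = J / (4.0 * (2 * J + 3))
        return chi * y_stretch / (threej(J, 2, J, -J, 0, J)
                                  * threej(I, 2, I, -I, 0, I))

    basis = list(itertools.product(range(-J, J + 1), range(-I1, I1 + 1),
                                   range(-I2, I2 + 1)))
    P = [reduced_product(chis[0], I1), reduced_product(chis[1], I2)]
    H = np.zeros((len(basis), len(basis)))
    for a, (ma, m1a, m2a) in enumerate(basis):
        for b, (mb, m1b, m2b) in enumerate(basis):
            val = 0.0
            specs = [(I1, m1a, m1b, m2a, m2b), (I2, m2a, m2b, m1a, m1b)]
            for n, (In, mna, mnb, msa, msb) in enumerate(specs):
                if msa != msb:
                    continue
                q = ma - mb
                if abs(q) > 2:
                    continue
                rot_el = (-1.0) ** (J - ma) * threej(J, 2, J, -ma, q, mb)
                spin_el = (-1.0) ** (In - mna) * threej(In, 2, In, -mna, -q, mnb)
                val += P[n] * (-1.0) ** q * rot_el * spin_el
            H[a, b] = val
    return np.sort(np.linalg.eigvalsh(H))


class TestFitParams:
    def test_zero_params_zero_tensor(self):
        t = tensor_from_fit_params(HyperfineFitParams(0.0, 0.0))
        assert t.is_zero

    @pytest.mark.parametrize("species,nucleus,expected", [
        ("amp", "Na", -4.203), ("amp", "Nr", 2.343),
        ("amw", "Na", -4.114), ("amw", "Nr", 1.882),
    ])
    def test_chi_cc_from_laplace_relation(self, species, nucleus, expected):
        """chi_cc derived from the two fitted combinations matches the
        published derived values to 1 mMHz."""
        params = {p.nucleus_label: p
                  for p in hyperfine_params(species, "parent")}
        t = tensor_from_fit_params(params[nucleus])
        assert t.chi_cc == pytest.approx(expected, abs=1e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(p1=st.floats(-10, 10), p2=st.floats(-10, 10), ab=st.floats(-5, 5))
    def test_round_trip(self, p1, p2, ab):
        p = HyperfineFitParams(p1, p2, ab)
        back = fit_params_from_tensor(tensor_from_fit_params(p))
        assert back.three_halves_chi_aa == pytest.approx(p1, abs=1e-9)
        assert back.quarter_chi_bb_minus_cc == pytest.approx(p2, abs=1e-9)


class TestRotation:
    def test_identity(self):
        t = quad_tensor("amp", "Nr", "exp")
        r = rotate_tensor(t, 0.0)
        assert r.chi_aa == t.chi_aa and r.chi_ab == t.chi_ab

    def test_ninety_degrees_swaps_axes(self):
        t = QuadrupoleTensor(1.0, -3.0, 2.0, chi_ab=0.7)
        r = rotate_tensor(t, 90.0)
        assert r.chi_aa == pytest.approx(-3.0, abs=1e-12)
        assert r.chi_bb == pytest.approx(1.0, abs=1e-12)
        assert r.chi_ab == pytest.approx(-0.7, abs=1e-12)

    def test_two_degree_rotation_reproduces_d6_parameters(self):
        """Rotating the monomer ring-N tensor by the 2-degree isotopic
        axis rotation reproduces the 6-d fitted combinations."""
        t = quad_tensor("amp", "Nr", "exp")
        r = rotate_tensor(t, 2.0)
        assert 1.5 * r.chi_aa == pytest.approx(0.222, abs=2e-3)
        assert 0.25 * (r.chi_bb - r.chi_cc) == pytest.approx(-1.208, abs=2e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(aa=st.floats(-5, 5), bb=st.floats(-5, 5), ab=st.floats(-5, 5),
           theta=st.floats(-180, 180))
    def test_trace_and_eigenvalues_preserved(self, aa, bb, ab, theta):
        t = QuadrupoleTensor(aa, bb, -aa - bb, chi_ab=ab)
        r = rotate_tensor(t, theta)
        assert r.chi_aa + r.chi_bb + r.chi_cc == pytest.approx(0.0, abs=1e-9)
        eig0 = np.sort(np.linalg.eigvalsh(np.array([[aa, ab], [ab, bb]])))
        eig1 = np.sort(np.linalg.eigvalsh(
            np.array([[r.chi_aa, r.chi_ab], [r.chi_ab, r.chi_bb]])))
        assert np.allclose(eig0, eig1, atol=1e-9)


class TestDiagonalization:
    def test_already_diagonal(self):
        t = QuadrupoleTensor(1.0, 2.5, -3.5, chi_ab=0.0)
        pr = diagonalize_tensor(t)
        assert pr.theta_za == pytest.approx(90.0)  # z is the c axis here
        assert pr.chi_zz == pytest.approx(-3.5)

    def test_cluster_ring_nitrogen(self):
        pr = diagonalize_tensor(quad_tensor("amw", "Nr", "exp"))
        assert pr.chi_zz == pytest.approx(-3.66, abs=0.01)
        assert pr.theta_za == pytest.approx(15.9, abs=0.1)

    def test_monomer_ring_nitrogen(self):
        pr = diagonalize_tensor(quad_tensor("amp", "Nr", "exp"))
        assert pr.chi_zz == pytest.approx(-4.30, abs=0.01)
        assert pr.theta_za == pytest.approx(55.5, abs=0.1)

    def test_degenerate_block_flagged(self):
        pr = diagonalize_tensor(QuadrupoleTensor(1.0, 1.0, -2.0, chi_ab=0.0))
        assert pr.degenerate

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(theta=st.floats(-60, 60))
    def test_rotation_shifts_theta_za(self, theta):
        t = quad_tensor("amw", "Nr", "exp")
        base = diagonalize_tensor(t)
        rot = diagonalize_tensor(rotate_tensor(t, theta))
        assert rot.chi_zz == pytest.approx(base.chi_zz, abs=1e-9)
        # eigenvector angle shifts by -theta modulo axis labelling
        expected = base.theta_za_signed - theta
        folded = (expected + 90.0) % 180.0 - 90.0
        assert rot.theta_za_signed == pytest.approx(folded, abs=1e-6)


class TestThetaStrAndScaling:
    def test_equal_calc_pair_is_identity(self):
        assert theta_str_correction(12.0, 5.0, 5.0) == pytest.approx(12.0)

    def test_cluster_structural_angle(self):
        pr = diagonalize_tensor(quad_tensor("amw", "Nr", "exp"))
        assert theta_str_correction(pr.theta_za, 18.3, 19.9) == \
            pytest.approx(17.5, abs=0.1)

    def test_additivity(self):
        assert theta_str_correction(0.0, 1.0, 2.5) == pytest.approx(1.5)

    def test_scaling_reproduces_monomer_chi_cc(self):
        t = QuadrupoleTensor(2.2335, 2.2335, -4.4670)
        assert scale_tensor(t, 0.941).chi_cc == pytest.approx(-4.2034,
                                                              abs=1e-4)

    def test_scaling_preserves_tracelessness(self):
        t = quad_tensor("amw", "Nr", "exp")
        s = scale_tensor(t, 0.73)
        assert s.chi_aa + s.chi_bb + s.chi_cc == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InvalidInputError):
            scale_tensor(quad_tensor("amp", "Na", "exp"), 0.0)


class TestHyperfinePattern:
    def test_zero_tensors_single_component(self, amp_rotor):
        up = RotationalLevel(1, 0, 1, 0.0, "0plus")
        lo = RotationalLevel(0, 0, 0, 0.0, "0plus")
        zero = QuadrupoleTensor(0, 0, 0)
        comps = hyperfine_pattern(up, lo, [zero, zero], amp_rotor)
        offsets = sorted(set(round(c.offset, 9) for c in comps))
        assert offsets == [0.0]
        assert sum(c.intensity for c in comps) == pytest.approx(1.0)

    def test_single_nucleus_matches_casimir(self, amp_rotor):
        """F-resolved shifts of a single I=1 nucleus equal the closed-form
        first-order quadrupole energies."""
        t = quad_tensor("amp", "Na", "exp")
        for (J, Ka, Kc) in [(1, 0, 1), (2, 1, 2), (3, 0, 3)]:
            ce = chi_eff(t, amp_rotor.jg_squared(J, Ka, Kc), J)
            subs = quadrupole_sublevels(J, [ce], [1.0])
            for F, shifts, _, _ in subs:
                assert shifts[0] == pytest.approx(
                    casimir_energy(ce, J, 1.0, F), abs=1e-9)

    def test_two_nuclei_match_uncoupled_oracle(self, amp_rotor):
        """Coupled-basis eigenvalues (weighted by 2F+1) equal brute-force
        diagonalization in the uncoupled product basis, J <= 3."""
        t1 = quad_tensor("amp", "Na", "exp")
        t2 = quad_tensor("amp", "Nr", "exp")
        for J in (1, 2, 3):
            for Ka, Kc in [(0, J), (1, J - 1)]:
                jg2 = amp_rotor.jg_squared(J, Ka, Kc)
                chis = [chi_eff(t1, jg2, J), chi_eff(t2, jg2, J)]
                subs = quadrupole_sublevels(J, chis, [1.0, 1.0])
                impl = np.sort(np.concatenate(
                    [np.repeat(w, int(2 * F + 1)) for F, w, _, _ in subs]))
                oracle = uncoupled_eigenvalues(J, chis)
                assert np.max(np.abs(impl - oracle)) < 1e-9

    def test_nine_sublevels_for_j_ge_2(self):
        subs = quadrupole_sublevels(3, [1.0, -0.5], [1.0, 1.0])
        assert sum(len(w) for _, w, _, _ in subs) == 9

    def test_center_of_gravity_sum_rule(self, amp_rotor):
        """Intensity-weighted mean hyperfine offset vanishes."""
        tensors = [quad_tensor("amp", "Na", "exp"),
                   quad_tensor("amp", "Nr", "exp")]
        cases = [((2, 1, 2), (1, 0, 1)), ((3, 1, 3), (2, 0, 2)),
                 ((2, 0, 2), (1, 1, 1))]
        for (upq, loq) in cases:
            up = RotationalLevel(*upq, 0.0, "0plus")
            lo = RotationalLevel(*loq, 0.0, "0plus")
            comps = hyperfine_pattern(up, lo, tensors, amp_rotor)
            total = sum(c.intensity for c in comps)
            assert total == pytest.approx(1.0, abs=1e-9)
            cog = sum(c.intensity * c.offset for c in comps)
            assert abs(cog) < 1e-6

    def test_r_branch_from_ground_intensities(self, amp_rotor):
        """1_01 <- 0_00 with one I=1 nucleus: intensities follow the
        2F'+1 degeneracy ratio 1:3:5."""
        up = RotationalLevel(1, 0, 1, 0.0, "0plus")
        lo = RotationalLevel(0, 0, 0, 0.0, "0plus")
        comps = hyperfine_pattern(up, lo, [quad_tensor("amp", "Na", "exp")],
                                  amp_rotor)
        by_f = {c.upper[4]: c.intensity for c in comps}
        assert by_f[0.0] == pytest.approx(1 / 9, abs=1e-9)
        assert by_f[1.0] == pytest.approx(3 / 9, abs=1e-9)
        assert by_f[2.0] == pytest.approx(5 / 9, abs=1e-9)
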