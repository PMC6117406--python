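"""Material-point laws: invariants, passive hyperelastic stress, active
tension, and total-stress superposition."""

import numpy as np
import pytest

from lvmech.materials import (
    ActiveParams,
    MaterialParams,
    active_tension,
    compute_invariants,
    paper_table1,
    passive_pk2_stress,
    strain_energy,
    total_stress,
)

F0 = np.array([1.0, 0.0, 0.0])
S0 = np.array([0.0, 1.0, 0.0])


def random_states(rng, n=100, scale=0.15):
    """Random deformation gradients with positive determinant."""
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            out.append(F)
    return np.array(out)


class TestInvariants:
    def test_reference_configuration(self):
        inv = compute_invariants(np.eye(3), F0, S0)
        assert inv.I1 == pytest.approx(3.0)
        assert inv.I4f == pytest.approx(1.0)
        assert inv.I4s == pytest.approx(1.0)
        assert inv.I8fs == pytest.approx(0.0)
        assert inv.J == pytest.approx(1.0)
        assert inv.Eff == pytest.approx(0.0)

    def test_isochoric_uniaxial_fiber_stretch(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        inv = compute_invariants(F, F0, S0)
        assert inv.I4f == pytest.approx(1.44)
        assert inv.Eff == pytest.approx(0.22)
        assert inv.J == pytest.approx(1.0)

    def test_against_dense_matrix_oracle(self, rng):
        for F in random_states(rng, n=20):
            C = F.T @ F
            inv = compute_invariants(F, F0, S0)
            assert inv.I1 == pytest.approx(np.trace(C), rel=1e-12)
            assert inv.I4f == pytest.approx(F0 @ C @ F0, rel=1e-12)
            assert inv.I4s == pytest.approx(S0 @ C @ S0, rel=1e-12)
            assert inv.I8fs == pytest.approx(F0 @ C @ S0, abs=1e-12)
            assert inv.J == pytest.approx(np.linalg.det(F), rel=1e-12)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            compute_invariants(-np.eye(3), F0, S0)


class TestPassiveStress:
    def test_stress_free_reference(self):
        S = passive_pk2_stress(np.eye(3), F0, S0, paper_table1())
        assert np.abs(S).max() < 1e-12

    def test_fiber_term_vanishes_at_unit_i4(self):
        """With I4f = 1 the fiber exponential has zero slope, so a_f does
        not contribute: stress is independent of a_f there."""
        lam = 1.1  # stretch the sheet direction only
        F = np.diag([1.0, lam, 1.0 / lam])
        mp1 = paper_table1()
        mp2 = MaterialParams(**{**mp1.__dict__, "a_f": 10 * mp1.a_f})
        S1 = passive_pk2_stress(F, F0, S0, mp1)
        S2 = passive_pk2_stress(F, F0, S0, mp2)
        assert np.allclose(S1, S2, atol=1e-14)

    def test_stress_is_energy_gradient(self, rng):
        """P = dPsi/dF == F S to relative 1e-6 (central differences),
        over 100 random states with the default parameter set."""
        mp = paper_table1()
        h = 1e-6
        for F in random_states(rng, n=100):
            P = F @ passive_pk2_stress(F, F0, S0, mp)
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P_fd[i, j] = (
                        strain_energy(Fp, F0, S0, mp) - strain_energy(Fm, F0, S0, mp)
                    ) / (2 * h)
            assert np.abs(P - P_fd).max() <= 1e-6 * max(np.abs(P_fd).max(), 1e-8)

    def test_objectivity_under_rotations(self, rng):
        mp = paper_table1()
        for F in random_states(rng, n=10):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            assert strain_energy(q @ F, F0, S0, mp) == pytest.approx(
                strain_energy(F, F0, S0, mp), abs=1e-10, rel=1e-10
            )

    def test_uniaxial_fiber_stress_monotone(self):
        """Fiber stress strictly increasing in stretch on [1, 1.3]."""
        mp = paper_table1()
        lams = np.linspace(1.0, 1.3, 16)
        s_ff = []
        for lam in lams:
            F = np.diag([lam, lam**-0.5, lam**-0.5])
            S = passive_pk2_stress(F, F0, S0, mp)
            s_ff.append(F0 @ S @ F0)
        assert np.all(np.diff(s_ff) > 0)

    def test_symmetry(self, rng):
        mp = paper_table1()
        for F in random_states(rng, n=10):
            S = passive_pk2_stress(F, F0, S0, mp)
            assert np.allclose(S, S.T, atol=1e-14)


class TestActiveTension:
    ap = ActiveParams(t_max=0.1)

    def test_zero_contractility_gives_zero(self):
        ap0 = ActiveParams(t_max=0.0)
        for t in (0.0, 0.1, 0.3):
            assert active_tension(t, np.array([0.1, -0.1]), ap0) == pytest.approx(0.0)

    def test_zero_before_activation_and_after_relaxation(self):
        assert active_tension(0.0, 0.0, self.ap) == 0.0
        l = self.ap.lR  # sarcomere length at zero strain
        tr = self.ap.m_relax * l + self.ap.b_relax
        assert active_tension(self.ap.t0 + tr + 1e-6, 0.0, self.ap) == pytest.approx(0.0)

    def test_peak_activation_at_t0(self):
        """At t = t0 the activation shape Ct = (1 - cos(pi))/2 = 1, so the
        tension equals the length-dependent plateau value."""
        T_peak = active_tension(self.ap.t0, 0.0, self.ap)
        l = self.ap.lR
        eca50_sq = self.ap.ca0_max**2 / (np.exp(self.ap.b_len * (l - self.ap.l0)) - 1)
        expected = self.ap.t_max * self.ap.ca0**2 / (self.ap.ca0**2 + eca50_sq)
        assert T_peak == pytest.approx(expected, rel=1e-12)
        # and it is the maximum over the cycle
        ts = np.linspace(0, 0.6, 200)
        vals = [active_tension(t, 0.0, self.ap) for t in ts]
        assert max(vals) == pytest.approx(T_peak, rel=1e-3)

    def test_short_sarcomeres_produce_no_tension(self):
        # l <= l0 (strong fiber compression) -> no active stress, no error
        eff_short = 0.5 * ((self.ap.l0 / self.ap.lR) ** 2 - 1) - 0.01
        assert active_tension(self.ap.t0, eff_short, self.ap) == 0.0
        # approaching l0 from above the tension falls monotonically to zero
        ratios = np.array([1.05, 1.01, 1.001, 1.0001])
        effs = 0.5 * ((ratios * self.ap.l0 / self.ap.lR) ** 2 - 1)
        vals = active_tension(self.ap.t0, effs, self.ap)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-2 * self.ap.t_max


class TestTotalStress:
    def test_reduces_to_passive_before_activation(self, rng):
        mp, ap = paper_table1(), ActiveParams(t_max=0.1)
        F = random_states(rng, n=1)[0]
        assert np.allclose(
            total_stress(F, F0, S0, mp, ap, t=0.0),
            passive_pk2_stress(F, F0, S0, mp),
        )

    def test_pure_active_closed_form(self):
        """Zero passive moduli, Eff = 0, t = t0: S = T0 f0 (x) f0 with the
        plateau tension at the stress-free sarcomere length."""
        mp = MaterialParams(a=0, b=1, a_f=0, b_f=1, a_s=0, b_s=1, a_fs=0, b_fs=1)
        ap = ActiveParams(t_max=0.1)
        S = total_stress(np.eye(3), F0, S0, mp, ap, t=ap.t0)
        eca50_sq = ap.ca0_max**2 / (np.exp(ap.b_len * (ap.lR - ap.l0)) - 1)
        t0_expected = ap.t_max * ap.ca0**2 / (ap.ca0**2 + eca50_sq)
        expected = t0_expected * np.outer(F0, F0)
        assert np.allclose(S, expected, atol=1e-12)

    def test_symmetric_for_random_states(self, rng):
        mp, ap = paper_table1(), ActiveParams(t_max=0.1)
        for F in random_states(rng, n=5):
            S = total_stress(F, F0, S0, mp, ap, t=0.15)
            assert np.allclose(S, S.T, atol=1e-13)


def test_compressibility_parameter_definition():
    mp = paper_table1(bulk_modulus=2.5)
    assert mp.D == pytest.approx(2.0 / 2.5)
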