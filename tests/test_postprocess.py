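"""Outcome measures: EF arithmetic, torsion conventions, strain operator,
sphericity."""

import dataclasses

import numpy as np
import pytest

from lvmech.fe import SimState
from lvmech.postprocess import (
    ejection_fraction,
    global_strains,
    sphericity_index,
    torsion,
    torsion_from_rings,
)


class TestEjectionFraction:
    @pytest.mark.parametrize(
        "edv, esv, expected",
        [(53.0, 24.8, 53.2075), (53.0, 31.4, 40.7547), (53.0, 53.0, 0.0)],
    )
    def test_values(self, edv, esv, expected):
        assert ejection_fraction(edv, esv) == pytest.approx(expected, abs=1e-3)

    def test_rejects_nonpositive_edv(self):
        with pytest.raises(ValueError):
            ejection_fraction(0.0, 10.0)


class TestTorsion:
    def test_worked_example(self):
        assert torsion_from_rings(10.0, -5.0, 2.0, 3.0, 8.0) == pytest.approx(4.69, abs=0.005)

    def test_rigid_rotation_gives_zero(self, small_mesh):
        ang = np.deg2rad(13.0)
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        u = small_mesh.nodes @ R.T - small_mesh.nodes
        tau = torsion(SimState(u=u), small_mesh)
        assert tau == pytest.approx(0.0, abs=1e-9)

    def test_positive_for_apex_counterclockwise_seen_from_apex(self, small_mesh):
        """A twist that rotates the apex clockwise in standard x-y
        orientation (so counterclockwise for an observer at the apex
        looking up the +z axis) must be positive."""
        z = small_mesh.nodes[:, 2]
        z_base, z_apex = z.max(), z.min()
        ang = np.deg2rad(-8.0) * (z_base - z) / (z_base - z_apex)  # 0 at base
        c, s = np.cos(ang), np.sin(ang)
        x, y = small_mesh.nodes[:, 0], small_mesh.nodes[:, 1]
        u = np.stack([c * x - s * y - x, s * x + c * y - y, np.zeros_like(x)], axis=1)
        assert torsion(SimState(u=u), small_mesh) > 0

    def test_invariant_under_uniform_scaling(self, small_mesh):
        z = small_mesh.nodes[:, 2]
        ang = np.deg2rad(6.0) * (z.max() - z) / (z.max() - z.min())
        c, s = np.cos(ang), np.sin(ang)
        x, y = small_mesh.nodes[:, 0], small_mesh.nodes[:, 1]
        u = np.stack([c * x - s * y - x, s * x + c * y - y, np.zeros_like(x)], axis=1)
        tau1 = torsion(SimState(u=u), small_mesh)
        scale = 1.7
        big = dataclasses.replace(small_mesh, nodes=scale * small_mesh.nodes)
        tau2 = torsion(SimState(u=scale * u), big)
        assert tau2 == pytest.approx(tau1, rel=1e-12)


class TestGlobalStrains:
    def test_identity_deformation_gives_zero(self, small_model, small_fibers):
        ed = SimState(u=np.zeros((small_model.n_nodes, 3)))
        assert global_strains(ed, ed, small_model, small_fibers) == pytest.approx((0, 0, 0))

    def test_uniform_dilation_matches_analytic_green_strain(self, small_model, small_fibers):
        """For pure dilation x -> s x, every direction carries the same
        Green-Lagrange strain (s^2 - 1)/2, whatever the local basis."""
        s = 1.06
        ed = SimState(u=np.zeros((small_model.n_nodes, 3)))
        es = SimState(u=(s - 1.0) * small_model.nodes)
        e_l, e_c, e_r = global_strains(ed, es, small_model, small_fibers)
        expected = 100.0 * 0.5 * (s**2 - 1.0)
        assert e_l == pytest.approx(expected, abs=1e-8)
        assert e_c == pytest.approx(expected, abs=1e-8)
        assert e_r == pytest.approx(expected, abs=1e-8)

    def test_es_referenced_to_ed_not_reference(self, small_model, small_fibers):
        """Strains compare ES against ED: if ES == ED != reference, the
        result is exactly zero."""
        st = SimState(u=0.05 * small_model.nodes)
        out = global_strains(st, st, small_model, small_fibers)
        assert out == pytest.approx((0.0, 0.0, 0.0), abs=1e-10)


class TestSphericity:
    def test_undeformed_prolate_geometry_echo(self, small_mesh):
        state = SimState(u=np.zeros((small_mesh.n_nodes, 3)))
        g = small_mesh.geometry
        expected = (g.endo_semi_axis_long + g.truncation_height) / (
            2 * g.endo_semi_axis_short
        )
        assert sphericity_index(state, small_mesh) == pytest.approx(expected, rel=0.05)

    def test_decreases_under_short_axis_dilation(self, small_mesh):
        """Widening the short axis makes the chamber more spherical, so
        the index drops."""
        state0 = SimState(u=np.zeros((small_mesh.n_nodes, 3)))
        u = np.zeros_like(small_mesh.nodes)
        u[:, 0] = 0.15 * small_mesh.nodes[:, 0]
        u[:, 1] = 0.15 * small_mesh.nodes[:, 1]
        wide = SimState(u=u)
        assert sphericity_index(wide, small_mesh) < sphericity_index(state0, small_mesh)
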