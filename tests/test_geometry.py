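"""Truncated-ellipsoid construction, Klotz unloading, and meshing."""

import numpy as np
import pytest

from lvmech.geometry import (
    GeometryError,
    REGION_NAMES,
    build_ed_surfaces,
    klotz_unloaded_volume,
    mesh_lv,
    scale_to_unloaded,
    truncated_ellipsoid_volume,
)
from lvmech.patients import paper_patient
from lvmech.fe import FEModel
from lvmech.fibers import assign_fibers
from lvmech.materials import paper_table1


def midpoint_volume(a, c, h, n=20000):
    """Independent oracle: midpoint-rule integration of the disc areas."""
    z = np.linspace(-c, h, n + 1)
    zm = 0.5 * (z[1:] + z[:-1])
    return float(np.sum(np.pi * a * a * (1 - zm**2 / c**2) * np.diff(z)))


@pytest.mark.parametrize("a,c,h", [(2.0, 3.0, 1.2), (1.5, 4.0, 0.0), (2.3, 2.3, 2.0)])
def test_analytic_volume_matches_midpoint_integration(a, c, h):
    assert truncated_ellipsoid_volume(a, c, h) == pytest.approx(
        midpoint_volume(a, c, h), rel=1e-6
    )


class TestKlotzUnloadedVolume:
    def test_reference_subject(self):
        assert klotz_unloaded_volume(53.0, 14.3) == pytest.approx(27.25, abs=0.01)

    def test_zero_pressure_intercept(self):
        assert klotz_unloaded_volume(80.0, 0.0) == pytest.approx(0.6 * 80.0)

    def test_direct_evaluation(self):
        assert klotz_unloaded_volume(100.0, 10.0) == pytest.approx(54.0)

    def test_nonphysiologic_pressure_rejected(self):
        with pytest.raises(ValueError):
            klotz_unloaded_volume(53.0, 100.0)
        with pytest.raises(ValueError):
            klotz_unloaded_volume(53.0, -1.0)


class TestEDSurfaces:
    def test_cavity_volume_matches_edv(self, patient):
        geom = build_ed_surfaces(patient)
        assert geom.cavity_volume == pytest.approx(patient.edv, rel=5e-3)

    def test_diameter_and_thickness_respected(self, patient):
        geom = build_ed_surfaces(patient)
        assert 2 * geom.endo_semi_axis_short == pytest.approx(
            patient.lv_internal_diameter_ed
        )
        thick = geom.epi_semi_axis_short - geom.endo_semi_axis_short
        assert thick == pytest.approx(patient.mean_wall_thickness_ed)

    def test_cubic_scaling_of_all_linear_measurements(self, patient):
        import dataclasses

        doubled = dataclasses.replace(
            patient,
            edv=8 * patient.edv,
            esv=8 * patient.esv,
            lv_internal_diameter_ed=2 * patient.lv_internal_diameter_ed,
            posterior_wall_thickness_ed=2 * patient.posterior_wall_thickness_ed,
            septal_wall_thickness_ed=2 * patient.septal_wall_thickness_ed,
        )
        g1, g2 = build_ed_surfaces(patient), build_ed_surfaces(doubled)
        assert g2.cavity_volume == pytest.approx(8 * g1.cavity_volume, rel=1e-9)
        assert g2.wall_volume == pytest.approx(8 * g1.wall_volume, rel=1e-9)

    def test_infeasible_thickness_rejected(self, patient):
        import dataclasses

        bad = dataclasses.replace(
            patient, posterior_wall_thickness_ed=3.0, septal_wall_thickness_ed=3.0
        )
        with pytest.raises(GeometryError):
            build_ed_surfaces(bad)


class TestUnloading:
    def test_identity_when_target_equals_cavity(self, patient):
        geom = build_ed_surfaces(patient)
        same = scale_to_unloaded(geom, geom.cavity_volume)
        assert same.endo_semi_axis_long == pytest.approx(geom.endo_semi_axis_long)
        assert same.epi_semi_axis_short == pytest.approx(geom.epi_semi_axis_short)

    def test_reference_chain_reaches_klotz_volume(self, patient):
        geom = build_ed_surfaces(patient)
        v0 = klotz_unloaded_volume(patient.edv, patient.edp)
        g0 = scale_to_unloaded(geom, v0)
        assert g0.cavity_volume == pytest.approx(27.25, rel=1e-3)

    def test_wall_mass_preserved(self, patient):
        geom = build_ed_surfaces(patient)
        for frac in (0.5, 0.7, 0.9):
            g0 = scale_to_unloaded(geom, frac * geom.cavity_volume)
            numeric_wall = midpoint_volume(
                g0.epi_semi_axis_short, g0.epi_semi_axis_long, g0.truncation_height
            ) - midpoint_volume(
                g0.endo_semi_axis_short, g0.endo_semi_axis_long, g0.truncation_height
            )
            assert numeric_wall == pytest.approx(geom.wall_volume, rel=1e-3)
            assert g0.wall_volume == pytest.approx(geom.wall_volume, rel=1e-3)

    def test_invalid_targets_rejected(self, patient):
        geom = build_ed_surfaces(patient)
        with pytest.raises(ValueError):
            scale_to_unloaded(geom, 1.5 * geom.cavity_volume)
        with pytest.raises(ValueError):
            scale_to_unloaded(geom, 0.0)


class TestMesh:
    def test_structured_counts_and_layers(self, unloaded_geometry):
        mesh = mesh_lv(unloaded_geometry, 16, 10)
        assert mesh.n_elems == 8 * 16 * 10 == 1280
        assert sorted(np.unique(mesh.layer_index)) == list(range(1, 9))

    def test_region_fractions_three_two_three(self, small_mesh):
        counts = np.bincount(small_mesh.region, minlength=3) / small_mesh.n_elems
        assert counts == pytest.approx([3 / 8, 2 / 8, 3 / 8])
        assert REGION_NAMES == ("subendocardium", "midmyocardium", "subepicardium")

    def test_node_sets(self, small_mesh):
        assert len(small_mesh.annulus_nodes) == small_mesh.n_circ
        assert len(small_mesh.basal_nodes) == 9 * small_mesh.n_circ
        assert len(small_mesh.endo_faces) == small_mesh.n_circ * small_mesh.n_long
        # the basal plane is flat at the truncation height
        z = small_mesh.nodes[small_mesh.basal_nodes, 2]
        assert np.allclose(z, small_mesh.geometry.truncation_height)

    def test_resolution_bounds_enforced(self, unloaded_geometry):
        with pytest.raises(GeometryError):
            mesh_lv(unloaded_geometry, 4, 10)
        with pytest.raises(GeometryError):
            mesh_lv(unloaded_geometry, 8, 3)

    def test_cavity_volume_converges_under_refinement(self, unloaded_geometry):
        """Discrete cavity volume -> analytic volume, error at least halved
        when both resolutions double."""
        errs = []
        for nc, nl in [(8, 6), (16, 12)]:
            mesh = mesh_lv(unloaded_geometry, nc, nl)
            model = FEModel.from_mesh(mesh, assign_fibers(mesh), paper_table1())
            v = model.cavity_volume(np.zeros((mesh.n_nodes, 3)))
            errs.append(abs(v - unloaded_geometry.cavity_volume))
        assert errs[1] < 0.5 * errs[0]
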