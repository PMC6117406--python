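"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lvmech import (
    FEModel,
    assign_fibers,
    build_ed_surfaces,
    klotz_unloaded_volume,
    mesh_lv,
    paper_patient,
    paper_table1,
    scale_to_unloaded,
)
from lvmech.materials import ActiveParams


@pytest.fixture(scope="session")
def patient():
    return paper_patient()


@pytest.fixture(scope="session")
def unloaded_geometry(patient):
    geom_ed = build_ed_surfaces(patient)
    return scale_to_unloaded(geom_ed, klotz_unloaded_volume(patient.edv, patient.edp))


@pytest.fixture(scope="session")
def small_mesh(unloaded_geometry):
    """Coarsest admissible LV mesh (8 x 8 x 6 = 384 hexahedra)."""
    return mesh_lv(unloaded_geometry, 8, 6)


@pytest.fixture(scope="session")
def small_fibers(small_mesh):
    return assign_fibers(small_mesh)


@pytest.fixture()
def small_model(small_mesh, small_fibers):
    return FEModel.from_mesh(
        small_mesh, small_fibers, paper_table1(), active=ActiveParams(t_max=0.0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180824)


def single_element_model(
    mp=None, f0=(1.0, 0.0, 0.0), s0=(0.0, 1.0, 0.0), t_max=0.0
) -> FEModel:
    """Unit-cube single-hexahedron model without boundary conditions."""
    from lvmech.elements import HEX_CORNERS

    nodes = 0.5 * (HEX_CORNERS + 1.0)
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    return FEModel(
        nodes,
        elems,
        np.array([f0], dtype=float),
        np.array([s0], dtype=float),
        mp or paper_table1(),
        active=ActiveParams(t_max=1.0),
        t_max_elem=np.array([t_max]),
    )
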