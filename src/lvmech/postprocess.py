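"""Outcome measures: ejection fraction, normalized torsion, global
strains, sphericity index, and transmural fiber strain/stress profiles.

Conventions
-----------
Torsion follows the size-normalized twist

    tau = (phi_apex - phi_base) * (rho_apex + rho_base) / (2 D),

with ring rotations phi in degrees (positive = counterclockwise seen from
the apex), rho the deformed mean ring radii and D the deformed axial
apex-base ring distance.  Rotations are evaluated on the basal endocardial
annulus and the most apical complete endocardial node ring (the pole
itself is singular).

Global strains are ED-referenced (clinical convention): the per-element
Green-Lagrange strain of end systole relative to end diastole, expressed
in the ED-pushed-forward local (circumferential, longitudinal, radial)
directions and volume-averaged with end-diastolic element volumes.
Transmural profiles are layer-wise volume-weighted means of the
ED-referenced fiber strain and the total Cauchy fiber stress at ES.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import materials as mat
from .elements import det3, inv3
from .fe import FEModel, SimState
from .fibers import FiberField
from .geometry import LVMesh

__all__ = [
    "ScenarioMetrics",
    "ejection_fraction",
    "torsion_from_rings",
    "torsion",
    "global_strains",
    "sphericity_index",
    "transmural_profile",
    "compute_metrics",
]


def ejection_fraction(edv: float, esv: float) -> float:
    """EF in percent: 100 (EDV - ESV) / EDV."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def torsion_from_rings(
    phi_apex_deg: float, phi_base_deg: float, rho_apex: float, rho_base: float, dist: float
) -> float:
    """Normalized torsion (degrees) from ring rotations/radii and the
    apex-base distance; invariant under uniform scaling of the heart."""
    return (phi_apex_deg - phi_base_deg) * (rho_apex + rho_base) / (2.0 * dist)


def _ring_rotation_radius(mesh: LVMesh, u: np.ndarray, ring: np.ndarray) -> tuple[float, float, float]:
    """Mean rotation (deg, + = CCW seen from apex), deformed mean radius,
    and deformed mean z of a node ring."""
    X = mesh.nodes[ring]
    x = X + u.reshape(-1, 3)[ring]
    phi0 = np.arctan2(X[:, 1], X[:, 0])
    phi1 = np.arctan2(x[:, 1], x[:, 0])
    dphi = np.angle(np.exp(1j * (phi1 - phi0)))  # wrapped to (-pi, pi]
    # +z is base; an observer at the apex (-z) sees standard math-positive
    # rotation about +z as clockwise, so flip the sign
    rot = -np.degrees(dphi.mean())
    rho = float(np.hypot(x[:, 0], x[:, 1]).mean())
    return rot, rho, float(x[:, 2].mean())


def torsion(es_state: SimState, mesh: LVMesh) -> float:
    """Normalized LV torsion (degrees) of a deformed state."""
    u = es_state.u
    rot_a, rho_a, z_a = _ring_rotation_radius(mesh, u, mesh.apex_ring_nodes)
    rot_b, rho_b, z_b = _ring_rotation_radius(mesh, u, mesh.annulus_nodes)
    dist = abs(z_b - z_a)
    return torsion_from_rings(rot_a, rot_b, rho_a, rho_b, dist)


def _deformation_gradients(model: FEModel, u: np.ndarray) -> np.ndarray:
    """F at every Gauss point, (ne, 8, 3, 3)."""
    u_e = u.reshape(model.n_nodes, 3)[model.elems]
    return np.einsum("eai,egaj->egij", u_e, model.gradN0, optimize=True) + np.eye(3)


def global_strains(
    ed_state: SimState, es_state: SimState, model: FEModel, fibers: FiberField
) -> tuple[float, float, float]:
    """Volume-weighted mean ED-referenced Green-Lagrange strain components
    (e_l, e_c, e_r) at end systole, in percent."""
    F_ed = _deformation_gradients(model, ed_state.u)
    F_es = _deformation_gradients(model, es_state.u)
    F_rel = np.einsum("egij,egjk->egik", F_es, inv3(F_ed))
    C_rel = np.einsum("egki,egkj->egij", F_rel, F_rel)
    E = 0.5 * (C_rel - np.eye(3))
    w = model.wJ0 * det3(F_ed)  # end-diastolic volume weights

    def comp(direction: np.ndarray) -> float:
        # push the reference local direction to the ED configuration
        d = np.einsum("egij,ej->egi", F_ed, direction)
        d /= np.linalg.norm(d, axis=-1, keepdims=True)
        e = np.einsum("egi,egij,egj->eg", d, E, d)
        return float((w * e).sum() / w.sum())

    e_c = comp(fibers.e_c)
    e_l = comp(fibers.e_l)
    e_r = comp(fibers.e_r)
    return 100.0 * e_l, 100.0 * e_c, 100.0 * e_r


def sphericity_index(es_state: SimState, mesh: LVMesh) -> float:
    """Deformed cavity long-axis length over short-axis diameter."""
    u = es_state.u.reshape(-1, 3)
    endo_mask = (np.arange(mesh.n_nodes) % 9) == 0  # radial node layer 0
    x_endo = (mesh.nodes + u)[endo_mask]
    ring_z = x_endo[:, 2].reshape(mesh.n_long + 1, mesh.n_circ)
    ring_r = np.hypot(x_endo[:, 0], x_endo[:, 1]).reshape(mesh.n_long + 1, mesh.n_circ)
    base_z = ring_z[0].mean()
    apex_z = ring_z[-1].mean()
    long_axis = abs(base_z - apex_z)
    short_axis = 2.0 * ring_r.mean(axis=1).max()
    return float(long_axis / short_axis)


def transmural_profile(
    es_state: SimState,
    ed_state: SimState,
    model: FEModel,
    fibers: FiberField,
    t_es: float | None = None,
) -> np.ndarray:
    """Layer-wise (8 rows) volume-weighted mean fiber strain and stress.

    Columns: transmural depth d (layer midpoint, 0 = endo), ED-referenced
    fiber Green-Lagrange strain at ES, and total Cauchy fiber stress (MPa)
    at ES.  ``t_es`` defaults to the ES state's time.
    """
    mesh = model.mesh
    F_ed = _deformation_gradients(model, ed_state.u)
    F_es = _deformation_gradients(model, es_state.u)
    F_rel = np.einsum("egij,egjk->egik", F_es, inv3(F_ed))
    # fiber direction in the ED configuration
    f_ed = np.einsum("egij,ej->egi", F_ed, fibers.f0)
    f_ed /= np.linalg.norm(f_ed, axis=-1, keepdims=True)
    lam_rel = np.linalg.norm(np.einsum("egij,egj->egi", F_rel, f_ed), axis=-1)
    eff_rel = 0.5 * (lam_rel**2 - 1.0)

    # total (passive + active) Cauchy fiber stress at ES
    t = es_state.time if t_es is None else t_es
    f0 = fibers.f0[:, None, :]
    s0 = fibers.s0[:, None, :]
    S = mat.passive_pk2_stress(F_es, f0, s0, model.mp)
    inv = mat.compute_invariants(F_es, f0, s0)
    T0 = mat.active_tension(t, inv.Eff, replace(model.active, t_max=1.0))
    T0 = T0 * model.t_max_elem[:, None]
    ff = np.einsum("...i,...j->...ij", f0, f0)
    S = S + (T0 / inv.I4f)[..., None, None] * ff
    sigma = np.einsum("egik,egkl,egjl->egij", F_es, S, F_es) / inv.J[..., None, None]
    f_es = np.einsum("egij,ej->egi", F_es, fibers.f0)
    f_es /= np.linalg.norm(f_es, axis=-1, keepdims=True)
    sig_ff = np.einsum("egi,egij,egj->eg", f_es, sigma, f_es)

    w = model.wJ0 * det3(F_ed)
    rows = []
    for layer in range(1, 9):
        sel = mesh.layer_index == layer
        wl = w[sel]
        rows.append(
            [
                (layer - 0.5) / 8.0,
                float((wl * eff_rel[sel]).sum() / wl.sum()),
                float((wl * sig_ff[sel]).sum() / wl.sum()),
            ]
        )
    return np.array(rows)


@dataclass
class ScenarioMetrics:
    """Per-scenario outcome bundle (the machine twin of a results-table
    row): EF %, ESV ml, ESP mmHg, normalized torsion deg, global strains
    %, ES sphericity, and the 8-layer transmural profile."""

    scenario_id: int
    t_max_subendo: float
    t_max_mid: float
    t_max_subepi: float
    ef: float
    esv: float
    esp: float
    edp: float
    torsion: float
    e_l: float
    e_c: float
    e_r: float
    sphericity_es: float
    transmural: np.ndarray = field(repr=False)

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "t_max_subendo_mpa": self.t_max_subendo,
            "t_max_mid_mpa": self.t_max_mid,
            "t_max_subepi_mpa": self.t_max_subepi,
            "ef_percent": self.ef,
            "esv_ml": self.esv,
            "esp_mmhg": self.esp,
            "torsion_deg": self.torsion,
            "e_l_percent": self.e_l,
            "e_c_percent": self.e_c,
            "e_r_percent": self.e_r,
            "sphericity_es": self.sphericity_es,
        }


def compute_metrics(
    scenario_id: int,
    t_max_triple: tuple[float, float, float],
    beat,
    model: FEModel,
    fibers: FiberField,
) -> ScenarioMetrics:
    """All outcome measures for one simulated beat."""
    e_l, e_c, e_r = global_strains(beat.ed_state, beat.es_state, model, fibers)
    return ScenarioMetrics(
        scenario_id=scenario_id,
        t_max_subendo=t_max_triple[0],
        t_max_mid=t_max_triple[1],
        t_max_subepi=t_max_triple[2],
        ef=ejection_fraction(beat.edv, beat.esv),
        esv=beat.esv,
        esp=beat.esp,
        edp=beat.edp,
        torsion=torsion(beat.es_state, model.mesh),
        e_l=e_l,
        e_c=e_c,
        e_r=e_r,
        sphericity_es=sphericity_index(beat.es_state, model.mesh),
        transmural=transmural_profile(beat.es_state, beat.ed_state, model, fibers),
    )
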