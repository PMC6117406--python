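"""Idealized left-ventricular geometry and structured hexahedral meshing.

The LV is a truncated thick-walled prolate ellipsoid: endocardial and
epicardial ellipsoidal surfaces share a long axis (z; base at z > 0, apex
at the -z pole) and are cut by a flat basal plane a height ``h`` above the
equator.  End-diastolic surfaces are back-calculated from echo
measurements; the unloaded (stress-free) reference is obtained by shrinking
the endocardium to the Klotz-regression unloaded volume and rescaling the
epicardium so the myocardial wall volume is conserved.

The mesh is a structured shell of 8-node hexahedra with exactly eight
transmural layers; layers 1-3, 4-5 and 6-8 form the subendocardial,
midmyocardial and subepicardial regions.  The apical pole is left open by
half of one longitudinal increment (no collapsed elements), so every
hexahedron has a strictly positive Jacobian; cavity-volume evaluation
closes the surface with basal and apical caps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .elements import reference_gradients
from .patients import PatientMeasurements

__all__ = [
    "GeometryError",
    "EllipsoidGeometry",
    "LVMesh",
    "truncated_ellipsoid_volume",
    "build_ed_surfaces",
    "klotz_unloaded_volume",
    "scale_to_unloaded",
    "mesh_lv",
    "REGION_NAMES",
    "REGION_OF_LAYER",
]


class GeometryError(ValueError):
    """Raised for infeasible measurement combinations or degenerate meshes."""


#: region code -> name; codes index this tuple
REGION_NAMES = ("subendocardium", "midmyocardium", "subepicardium")

#: transmural layer (1..8) -> region code (0/1/2)
REGION_OF_LAYER = {1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2}


def truncated_ellipsoid_volume(a: float, c: float, h: float) -> float:
    """Volume (ml) enclosed by an ellipsoid of revolution x^2/a^2 + y^2/a^2
    + z^2/c^2 = 1 cut by the plane z = h (keeping z <= h), h in (-c, c]."""
    if not (-c < h <= c):
        raise GeometryError(f"truncation height {h} outside (-{c}, {c}]")
    return np.pi * a * a * (h - h**3 / (3.0 * c * c) + 2.0 * c / 3.0)


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Truncated thick-walled ellipsoid (lengths cm, volumes ml).

    ``truncation_height`` is the basal-plane height above the equator on
    the long axis; both surfaces are cut by the same plane.
    """

    endo_semi_axis_long: float
    endo_semi_axis_short: float
    epi_semi_axis_long: float
    epi_semi_axis_short: float
    truncation_height: float
    cavity_volume: float
    wall_volume: float

    def __post_init__(self) -> None:
        if not (self.epi_semi_axis_long > self.endo_semi_axis_long > 0):
            raise GeometryError("epicardial long semi-axis must exceed endocardial")
        if not (self.epi_semi_axis_short > self.endo_semi_axis_short > 0):
            raise GeometryError("epicardial short semi-axis must exceed endocardial")
        if not (0 <= self.truncation_height < self.endo_semi_axis_long):
            raise GeometryError("truncation height must lie below the endocardial pole")
        v_analytic = truncated_ellipsoid_volume(
            self.endo_semi_axis_short, self.endo_semi_axis_long, self.truncation_height
        )
        if abs(v_analytic - self.cavity_volume) > 1e-3 * self.cavity_volume:
            raise GeometryError(
                f"cavity_volume {self.cavity_volume} inconsistent with analytic {v_analytic}"
            )


def build_ed_surfaces(
    meas: PatientMeasurements, truncation_fraction: float = 0.5
) -> EllipsoidGeometry:
    """Back-calculate end-diastolic endo/epi surfaces from echo scalars.

    The endocardial short semi-axis is half the measured internal diameter
    and the long semi-axis is solved so the truncated cavity volume equals
    the measured EDV; the basal plane sits at ``truncation_fraction`` of
    the endocardial long semi-axis above the equator.  The epicardium is
    offset by the mean of the posterior and septal wall thicknesses in
    both semi-axes, giving that wall thickness at the equator.
    """
    a = 0.5 * meas.lv_internal_diameter_ed
    t = meas.mean_wall_thickness_ed
    f = truncation_fraction
    if not (0 <= f < 1):
        raise GeometryError(f"truncation fraction must be in [0, 1), got {f}")
    if t >= a:
        raise GeometryError(
            f"wall thickness {t} cm is infeasible for internal radius {a} cm"
        )
    # V = pi a^2 c (f - f^3/3 + 2/3) with h = f c  =>  c linear in EDV
    shape = f - f**3 / 3.0 + 2.0 / 3.0
    c = meas.edv / (np.pi * a * a * shape)
    h = f * c
    if h >= c:
        raise GeometryError("truncation height reached the endocardial pole")
    cavity = truncated_ellipsoid_volume(a, c, h)
    a_epi, c_epi = a + t, c + t
    wall = truncated_ellipsoid_volume(a_epi, c_epi, h) - cavity
    return EllipsoidGeometry(
        endo_semi_axis_long=c,
        endo_semi_axis_short=a,
        epi_semi_axis_long=c_epi,
        epi_semi_axis_short=a_epi,
        truncation_height=h,
        cavity_volume=cavity,
        wall_volume=wall,
    )


def klotz_unloaded_volume(edv: float, edp: float) -> float:
    """Unloaded LV cavity volume V0 (ml) from the single-point EDPVR
    regression ``V0 = EDV * (0.6 - 0.006 * EDP)`` (EDP in mmHg)."""
    if edp < 0:
        raise ValueError(f"EDP must be non-negative, got {edp}")
    if edp >= 100.0:
        raise ValueError(f"EDP {edp} mmHg is non-physiologic for the V0 regression")
    return edv * (0.6 - 0.006 * edp)


def scale_to_unloaded(geom: EllipsoidGeometry, v0: float) -> EllipsoidGeometry:
    """Affinely shrink the endocardium to cavity volume ``v0`` and rescale
    the epicardium to conserve the myocardial wall volume.

    The endocardial semi-axes and the truncation height scale by the same
    factor s = (v0 / V_ED)^(1/3); the epicardial semi-axes are then scaled
    (same truncation plane) so the wall volume matches the end-diastolic
    one to better than 0.1%.
    """
    if not (0 < v0 <= geom.cavity_volume):
        raise ValueError(
            f"unloaded volume {v0} must lie in (0, {geom.cavity_volume}]"
        )
    s = (v0 / geom.cavity_volume) ** (1.0 / 3.0)
    a = geom.endo_semi_axis_short * s
    c = geom.endo_semi_axis_long * s
    h = geom.truncation_height * s
    cavity = truncated_ellipsoid_volume(a, c, h)

    def wall_mismatch(u: float) -> float:
        return (
            truncated_ellipsoid_volume(geom.epi_semi_axis_short * u, geom.epi_semi_axis_long * u, h)
            - cavity
            - geom.wall_volume
        )

    lo, hi = 0.5 * s, 1.5
    if wall_mismatch(hi) < 0:  # pragma: no cover - extreme geometries
        hi = 3.0
    u = brentq(wall_mismatch, lo, hi, xtol=1e-12)
    return EllipsoidGeometry(
        endo_semi_axis_long=c,
        endo_semi_axis_short=a,
        epi_semi_axis_long=geom.epi_semi_axis_long * u,
        epi_semi_axis_short=geom.epi_semi_axis_short * u,
        truncation_height=h,
        cavity_volume=cavity,
        wall_volume=geom.wall_volume,
    )


@dataclass(frozen=True)
class LVMesh:
    """Structured hexahedral shell mesh of the truncated ellipsoid.

    ``nodes`` are reference coordinates in cm; ``elems`` holds VTK-ordered
    hexahedra; ``layer_index`` runs 1 (innermost) to 8 (outermost).
    Node/face index sets support boundary conditions and cavity closure:
    the basal node set lies in the basal plane, the annulus set is the
    basal endocardial ring (ordered circumferentially), and the apical
    ring is the most apical endocardial node ring.
    """

    nodes: np.ndarray          # (nn, 3)
    elems: np.ndarray          # (ne, 8) int
    layer_index: np.ndarray    # (ne,) int, 1..8
    region: np.ndarray         # (ne,) int code into REGION_NAMES
    n_circ: int
    n_long: int
    basal_nodes: np.ndarray    # (9 * n_circ,) int
    annulus_nodes: np.ndarray  # (n_circ,) int, ordered ring
    apex_ring_nodes: np.ndarray  # (n_circ,) int, ordered ring (endo, apical)
    endo_faces: np.ndarray     # (n_circ * n_long, 4) int, quads on endocardium
    geometry: EllipsoidGeometry

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_coords(self) -> np.ndarray:
        """Nodal coordinates per element, (ne, 8, 3)."""
        return self.nodes[self.elems]

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def transmural_depth(self) -> np.ndarray:
        """Element-centroid transmural depth d in [0, 1] (0 = endo)."""
        return (self.layer_index - 0.5) / 8.0


def _surface_points(a: float, c: float, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Points on the ellipsoid for polar angles theta measured from the +z
    pole (apex at theta = pi, z = -c) and azimuths phi; returns (...,3)."""
    st, ct = np.sin(theta), np.cos(theta)
    x = a * st[:, None] * np.cos(phi)[None, :]
    y = a * st[:, None] * np.sin(phi)[None, :]
    z = (c * ct)[:, None] * np.ones_like(phi)[None, :]
    return np.stack([x, y, np.broadcast_to(z, x.shape)], axis=-1)


def mesh_lv(geom: EllipsoidGeometry, n_circ: int, n_long: int) -> LVMesh:
    """Mesh the truncated thick-walled ellipsoid with 8 transmural layers.

    Produces exactly ``8 * n_circ * n_long`` hexahedra.  Longitudinal node
    rings are equally spaced in the polar angle from the basal plane to
    half an increment short of the apical pole (open apex, positive
    Jacobians everywhere); radial node layers interpolate linearly between
    the endocardial and epicardial surfaces (equal thickness per layer).
    """
    if n_circ < 8:
        raise GeometryError(f"n_circ must be >= 8, got {n_circ}")
    if n_long < 6:
        raise GeometryError(f"n_long must be >= 6, got {n_long}")
    a_en, c_en = geom.endo_semi_axis_short, geom.endo_semi_axis_long
    a_ep, c_ep = geom.epi_semi_axis_short, geom.epi_semi_axis_long
    h = geom.truncation_height
    if a_ep <= a_en or c_ep <= c_en:
        raise GeometryError("non-positive wall thickness")

    phi = 2.0 * np.pi * np.arange(n_circ) / n_circ

    def theta_ladder(c_axis: float) -> np.ndarray:
        # z = c cos(theta) = h at the base
        theta_base = np.arccos(np.clip(h / c_axis, -1.0, 1.0))
        step = (np.pi - theta_base) / (n_long + 0.5)
        return theta_base + step * np.arange(n_long + 1)

    endo = _surface_points(a_en, c_en, theta_ladder(c_en), phi)  # (n_long+1, n_circ, 3)
    epi = _surface_points(a_ep, c_ep, theta_ladder(c_ep), phi)

    n_rad = 9  # 8 layers of elements
    frac = np.arange(n_rad) / 8.0
    # nodes[i_long, j_circ, k_rad]
    pts = endo[:, :, None, :] + frac[None, None, :, None] * (epi - endo)[:, :, None, :]
    nodes = pts.reshape(-1, 3)

    def nid(i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        return (i * n_circ + (j % n_circ)) * n_rad + k

    i, j, k = np.meshgrid(
        np.arange(n_long), np.arange(n_circ), np.arange(8), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # VTK ordering with local axes (xi1 = longitudinal toward apex,
    # xi2 = circumferential, xi3 = radial outward) -> positive Jacobian
    elems = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    ).astype(np.int64)

    layer_index = (k + 1).astype(np.int64)
    region = np.array([REGION_OF_LAYER[li] for li in layer_index], dtype=np.int64)

    # index sets
    jj = np.arange(n_circ)
    basal = np.concatenate([nid(np.zeros_like(jj), jj, np.full_like(jj, kk)) for kk in range(n_rad)])
    annulus = nid(np.zeros_like(jj), jj, np.zeros_like(jj))
    apex_ring = nid(np.full_like(jj, n_long), jj, np.zeros_like(jj))

    ii, jj2 = np.meshgrid(np.arange(n_long), np.arange(n_circ), indexing="ij")
    ii, jj2 = ii.ravel(), jj2.ravel()
    z0 = np.zeros_like(ii)
    endo_faces = np.stack(
        [nid(ii, jj2, z0), nid(ii, jj2 + 1, z0), nid(ii + 1, jj2 + 1, z0), nid(ii + 1, jj2, z0)],
        axis=1,
    ).astype(np.int64)

    mesh = LVMesh(
        nodes=nodes,
        elems=elems,
        layer_index=layer_index,
        region=region,
        n_circ=n_circ,
        n_long=n_long,
        basal_nodes=basal,
        annulus_nodes=annulus,
        apex_ring_nodes=apex_ring,
        endo_faces=endo_faces,
        geometry=geom,
    )
    # positivity check of all Gauss-point Jacobians
    try:
        reference_gradients(mesh.element_coords())
    except ValueError as exc:  # pragma: no cover - degenerate inputs only
        raise GeometryError(str(exc)) from exc
    return mesh


def refine(mesh: LVMesh, factor: int = 2) -> LVMesh:
    """Re-mesh the same geometry with ``factor``-times finer circumferential
    and longitudinal resolution (transmural layer count is fixed at 8)."""
    return mesh_lv(mesh.geometry, mesh.n_circ * factor, mesh.n_long * factor)
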