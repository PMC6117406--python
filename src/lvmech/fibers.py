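"""Rule-based myofiber architecture.

Each element carries a local orthonormal triad (circumferential,
longitudinal, radial) evaluated at its centroid and a fiber/sheet pair
(f0, s0).  The fiber helix angle, measured from the local circumferential
direction toward the apex-to-base direction, varies linearly through the
wall from +60 deg on the endocardium to -60 deg on the epicardium — the
standard rule-based transmural law from histology and DT-MRI.  The sheet
direction is the radial direction orthogonalized against the fiber (and
equals it exactly, since f0 lies in the circumferential-longitudinal
plane), so the sheet-type energy terms act transmurally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LVMesh

__all__ = ["FiberField", "local_basis", "assign_fibers"]


@dataclass(frozen=True)
class FiberField:
    """Per-element fiber architecture (unit vectors, angles in degrees)."""

    f0: np.ndarray               # (ne, 3) fiber direction
    s0: np.ndarray               # (ne, 3) sheet direction
    transmural_depth: np.ndarray  # (ne,) d in [0, 1], 0 = endocardium
    helix_angle: np.ndarray      # (ne,) degrees
    e_c: np.ndarray              # (ne, 3) circumferential
    e_l: np.ndarray              # (ne, 3) longitudinal (apex to base)
    e_r: np.ndarray              # (ne, 3) radial (outward)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def local_basis(mesh: LVMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-element right-handed orthonormal triad (e_c, e_l, e_r).

    Constructed from the element's own edges (structured mesh): the radial
    direction is the mean outward transmural edge, the longitudinal
    direction the mean apex-to-base edge orthogonalized against it, and
    e_c = e_l x e_r.  Being built purely from nodal coordinates, the triad
    co-rotates with any rigid rotation of the mesh.
    """
    X = mesh.element_coords()  # (ne, 8, 3)
    # local xi3 (radial): nodes 4..7 minus 0..3; xi1 (toward apex): 1,2,5,6 minus 0,3,4,7
    e_r = _normalize(X[:, 4:8].mean(axis=1) - X[:, 0:4].mean(axis=1))
    toward_apex = X[:, [1, 2, 5, 6]].mean(axis=1) - X[:, [0, 3, 4, 7]].mean(axis=1)
    e_l = -toward_apex  # apex-to-base
    e_l = e_l - np.einsum("ei,ei->e", e_l, e_r)[:, None] * e_r
    e_l = _normalize(e_l)
    e_c = np.cross(e_l, e_r)
    return e_c, e_l, e_r


def assign_fibers(
    mesh: LVMesh, endo_angle: float = 60.0, epi_angle: float = -60.0
) -> FiberField:
    """Assign fiber/sheet unit vectors at element centroids.

    The helix angle interpolates linearly in transmural depth d (layer
    midpoint, d = (layer - 0.5)/8) from ``endo_angle`` at d = 0 to
    ``epi_angle`` at d = 1; f0 = cos(angle) e_c + sin(angle) e_l, s0 = e_r.
    """
    e_c, e_l, e_r = local_basis(mesh)
    d = mesh.transmural_depth()
    helix = endo_angle + (epi_angle - endo_angle) * d
    ang = np.deg2rad(helix)
    f0 = np.cos(ang)[:, None] * e_c + np.sin(ang)[:, None] * e_l
    # sheet: radial orthogonalized against the fiber (identical to e_r here,
    # as f0 has no radial component; kept explicit for safety)
    s0 = e_r - np.einsum("ei,ei->e", e_r, f0)[:, None] * f0
    s0 = _normalize(s0)
    return FiberField(
        f0=f0, s0=s0, transmural_depth=d, helix_angle=helix, e_c=e_c, e_l=e_l, e_r=e_r
    )
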