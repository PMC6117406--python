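"""Trilinear 8-node hexahedron reference-element utilities.

Local node ordering follows the VTK_HEXAHEDRON convention with local
coordinates (xi1, xi2, xi3) in [-1, 1]^3.  Quadrature is 2x2x2 Gauss.
"""

from __future__ import annotations

import numpy as np

#: local corner coordinates, shape (8, 3), VTK hexahedron ordering
HEX_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
#: 2x2x2 Gauss points, shape (8, 3); weights are all 1
GAUSS_POINTS = HEX_CORNERS * _G
GAUSS_WEIGHTS = np.ones(8)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """N_a(xi) for points xi of shape (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * HEX_CORNERS, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi of shape (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    terms = 1.0 + xi[..., None, :] * HEX_CORNERS  # (..., 8, 3)
    out = np.empty(terms.shape)
    for i in range(3):
        prod = np.ones(terms.shape[:-1])
        for j in range(3):
            if j == i:
                prod = prod * HEX_CORNERS[:, j]
            else:
                prod = prod * terms[..., j]
        out[..., i] = prod
    return 0.125 * out


#: dN/dxi at the 8 Gauss points, shape (8 gp, 8 nodes, 3)
GAUSS_SHAPE_GRADIENTS = shape_gradients(GAUSS_POINTS)
#: N at the 8 Gauss points, shape (8 gp, 8 nodes)
GAUSS_SHAPE_FUNCTIONS = shape_functions(GAUSS_POINTS)


def det3(A: np.ndarray) -> np.ndarray:
    """Determinant of batched 3x3 matrices (explicit cofactor expansion;
    much faster than LAPACK for large batches of tiny matrices)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def inv3(A: np.ndarray, det: np.ndarray | None = None) -> np.ndarray:
    """Inverse of batched 3x3 matrices via the adjugate."""
    if det is None:
        det = det3(A)
    adj = np.empty_like(A)
    adj[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    adj[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    adj[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    adj[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    adj[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    adj[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    adj[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    adj[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    adj[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return adj / det[..., None, None]


def jacobians(node_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-point Jacobians for elements.

    Parameters
    ----------
    node_coords : (n_elem, 8, 3) nodal coordinates.

    Returns
    -------
    J : (n_elem, 8 gp, 3, 3) with J_ij = d x_i / d xi_j.
    detJ : (n_elem, 8 gp) determinants.
    """
    # J_ij = sum_a x_a,i dN_a/dxi_j
    J = np.einsum("eai,gaj->egij", node_coords, GAUSS_SHAPE_GRADIENTS, optimize=True)
    detJ = np.linalg.det(J)
    return J, detJ


def reference_gradients(node_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients w.r.t. physical reference coordinates.

    Returns (gradN, w_detJ): gradN has shape (n_elem, 8 gp, 8 nodes, 3)
    with dN_a/dX_i, and w_detJ (n_elem, 8 gp) are quadrature weights times
    Jacobian determinants (all Gauss weights are 1).
    """
    J, detJ = jacobians(node_coords)
    if np.any(detJ <= 0):
        raise ValueError("non-positive Jacobian in reference configuration")
    Jinv = np.linalg.inv(J)
    gradN = np.einsum("gaj,egji->egai", GAUSS_SHAPE_GRADIENTS, Jinv, optimize=True)
    return gradN, detJ * GAUSS_WEIGHTS
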