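"""Quasi-static total-Lagrangian finite-element machinery.

8-node hexahedra with 2x2x2 Gauss quadrature; the volumetric penalty is
treated by mean dilatation (B-bar): the volumetric pressure at every Gauss
point of an element is evaluated from the element-average Jacobian, which
removes volumetric locking at the near-incompressible default bulk
modulus.  The element residual is the exact gradient of the mean-dilatation
energy plus the (non-potential) active fiber stress; consistent element
tangents are obtained by forward differencing the exact residual, which
inherits the B-bar and active couplings by construction.

The cavity volume is a divergence-theorem sum over the deformed
endocardial surface closed by basal and apical caps.  Cavity pressure is
applied as the fluid-cavity virtual work p*dV: the follower load is
p times the analytic volume gradient and the load stiffness is the
analytic volume Hessian, so pressure loading and volume bookkeeping are
exactly energy-consistent; in volume-constrained (isovolumic) and
Windkessel-coupled solves the cavity pressure is a bordered unknown.

Boundary conditions follow the study setup: all basal-plane nodes are
fixed longitudinally, and the mean in-plane translation and the mean
long-axis rotation of the endocardial annulus are tied to the (fixed)
base center through linear multipoint constraints — exactly removing the
remaining rigid-body modes while leaving annular inflation free.

External units at this module's API: pressures mmHg, volumes ml, lengths
cm, time s.  Stresses are MPa internally; the single pressure conversion
happens in the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import materials as mat
from . import _kernels
from .elements import det3, inv3, reference_gradients
from .fibers import FiberField
from .geometry import LVMesh
from .units import MMHG_TO_MPA

__all__ = ["FEError", "SolverError", "SimState", "BoundarySpec", "FEModel", "newton_solve", "advance"]


class FEError(RuntimeError):
    pass


class SolverError(FEError):
    """Newton iteration failed to converge (after load cutbacks)."""


class StepRejected(FEError):
    """Trial state invalid (inverted element); signals a load cutback."""


@dataclass
class SimState:
    """Converged solver state.  ``cavity_pressure`` in mmHg, time in s."""

    u: np.ndarray
    cavity_pressure: float = 0.0
    time: float = 0.0
    converged: bool = True
    newton_iterations: int = 0

    def copy(self) -> "SimState":
        return replace(self, u=self.u.copy())


@dataclass(frozen=True)
class BoundarySpec:
    """Node/face sets realizing the basal boundary conditions."""

    basal_longitudinal_fixed: np.ndarray   # node ids with u_z = 0
    annulus_nodes: np.ndarray              # ring coupled to the base center
    base_center: np.ndarray                # fixed point on the long axis
    endocardial_faces: np.ndarray          # (nf, 4) pressure-loaded quads

    @classmethod
    def from_mesh(cls, mesh: LVMesh) -> "BoundarySpec":
        center = np.array([0.0, 0.0, mesh.geometry.truncation_height])
        return cls(
            basal_longitudinal_fixed=mesh.basal_nodes,
            annulus_nodes=mesh.annulus_nodes,
            base_center=center,
            endocardial_faces=mesh.endo_faces,
        )


class FEModel:
    """Assembled model: mesh + fibers + materials + boundary conditions.

    ``t_max_by_region`` maps region codes (0 subendo, 1 mid, 2 subepi) to
    contractility in MPa; pass a scalar for uniform contractility.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        elems: np.ndarray,
        f0: np.ndarray,
        s0: np.ndarray,
        mp: mat.MaterialParams,
        active: mat.ActiveParams | None = None,
        t_max_elem: np.ndarray | None = None,
        boundary: BoundarySpec | None = None,
        cavity_rings: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.nodes = np.asarray(nodes, dtype=float)
        self.elems = np.asarray(elems, dtype=np.int64)
        self.f0 = np.asarray(f0, dtype=float)
        self.s0 = np.asarray(s0, dtype=float)
        self.mp = mp
        self.active = active or mat.ActiveParams()
        ne = self.elems.shape[0]
        self.t_max_elem = (
            np.zeros(ne) if t_max_elem is None else np.broadcast_to(np.asarray(t_max_elem, float), (ne,)).copy()
        )
        self.boundary = boundary
        self.n_nodes = self.nodes.shape[0]
        self.ndof = 3 * self.n_nodes

        X_e = self.nodes[self.elems]
        self.gradN0, self.wJ0 = reference_gradients(X_e)  # (ne,8,8,3), (ne,8)
        self.elem_vol0 = self.wJ0.sum(axis=1)
        self.edof = (3 * self.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
        self._krows = np.repeat(self.edof, 24, axis=1).ravel()
        self._kcols = np.tile(self.edof, (1, 24)).ravel()

        # Dirichlet: longitudinal fixation of the basal plane
        fixed = np.zeros(self.ndof, dtype=bool)
        if boundary is not None:
            fixed[3 * boundary.basal_longitudinal_fixed + 2] = True
        self.fixed_dofs = fixed
        self.free_mask = ~fixed

        # multipoint constraints: mean annulus translation/rotation = 0
        self.G = self._build_mpc() if boundary is not None else None

        # cavity surface triangulation (endo quads + basal/apical caps)
        if boundary is not None and cavity_rings is not None:
            self._build_cavity(boundary.endocardial_faces, *cavity_rings)

        #: use the compiled element kernels when numba is importable; the
        #: numpy implementation is the reference path (tested equivalent)
        self.use_numba = _kernels.HAVE_NUMBA

    @property
    def _mpar(self) -> tuple:
        m = self.mp
        return (m.a, m.b, m.a_f, m.b_f, m.a_s, m.b_s, m.a_fs, m.b_fs, m.D)

    @property
    def _apar(self) -> tuple:
        a = self.active
        return (a.ca0, a.ca0_max, a.b_len, a.l0, a.lR, a.m_relax, a.b_relax, a.t0)

    # ----- construction helpers -------------------------------------------------

    @classmethod
    def from_mesh(
        cls,
        mesh: LVMesh,
        fibers: FiberField,
        mp: mat.MaterialParams,
        active: mat.ActiveParams | None = None,
        t_max_by_region: dict[int, float] | float | None = None,
    ) -> "FEModel":
        if t_max_by_region is None:
            t_max_elem = None
        elif np.isscalar(t_max_by_region):
            t_max_elem = np.full(mesh.n_elems, float(t_max_by_region))
        else:
            t_max_elem = np.array([t_max_by_region[r] for r in mesh.region])
        model = cls(
            mesh.nodes,
            mesh.elems,
            fibers.f0,
            fibers.s0,
            mp,
            active=active,
            t_max_elem=t_max_elem,
            boundary=BoundarySpec.from_mesh(mesh),
            cavity_rings=(mesh.annulus_nodes, mesh.apex_ring_nodes),
        )
        model.mesh = mesh
        model.fibers = fibers
        return model

    def set_material(self, mp: mat.MaterialParams) -> None:
        self.mp = mp

    def set_t_max(self, t_max_by_region: dict[int, float] | float) -> None:
        if np.isscalar(t_max_by_region):
            self.t_max_elem[:] = float(t_max_by_region)
        else:
            mesh = getattr(self, "mesh", None)
            if mesh is None:
                raise FEError("per-region contractility requires a mesh-built model")
            self.t_max_elem[:] = [t_max_by_region[r] for r in mesh.region]

    def _build_mpc(self) -> sp.csr_matrix:
        ann = self.boundary.annulus_nodes
        n = len(ann)
        X = self.nodes[ann] - self.boundary.base_center[None, :]
        rows, cols, data = [], [], []
        for j, node in enumerate(ann):
            rows += [0, 1]
            cols += [3 * node, 3 * node + 1]
            data += [1.0 / n, 1.0 / n]
            # mean rotation about the long axis: sum(x dy - y dx)/n
            rows += [2, 2]
            cols += [3 * node + 1, 3 * node]
            data += [X[j, 0] / n, -X[j, 1] / n]
        return sp.csr_matrix((data, (rows, cols)), shape=(3, self.ndof))

    def _build_cavity(self, faces: np.ndarray, base_ring: np.ndarray, apex_ring: np.ndarray) -> None:
        tris = []
        for q in faces:
            tris.append([q[0], q[1], q[2]])
            tris.append([q[0], q[2], q[3]])
        self._cav_tris = np.array(tris, dtype=np.int64)
        self._cav_base_ring = np.asarray(base_ring, dtype=np.int64)
        self._cav_apex_ring = np.asarray(apex_ring, dtype=np.int64)
        self._cav_sign = 1.0
        v = self.cavity_volume(np.zeros((self.n_nodes, 3)))
        if v < 0:
            self._cav_sign = -1.0

    # ----- cavity volume ----------------------------------------------------------

    def _cavity_triangles(self, x: np.ndarray):
        """Deformed coordinates of all cavity triangles incl. cap fans."""
        t_surf = x[self._cav_tris]  # (nt,3,3)
        caps = []
        for ring, flip in ((self._cav_base_ring, True), (self._cav_apex_ring, False)):
            r = x[ring]
            c = r.mean(axis=0)
            nxt = np.roll(np.arange(len(ring)), -1)
            a, b = (r[nxt], r) if flip else (r, r[nxt])
            cap = np.stack([np.broadcast_to(c, a.shape), a, b], axis=1)
            caps.append(cap)
        return t_surf, caps

    def cavity_volume(self, u: np.ndarray) -> float:
        """Cavity volume (ml) of the deformed, capped endocardial surface."""
        if not hasattr(self, "_cav_tris"):
            raise FEError("model has no cavity surface")
        x = self.nodes + u.reshape(self.n_nodes, 3)
        t_surf, caps = self._cavity_triangles(x)
        vol = np.einsum("ti,ti->t", t_surf[:, 0], np.cross(t_surf[:, 1], t_surf[:, 2])).sum()
        for cap in caps:
            vol += np.einsum("ti,ti->t", cap[:, 0], np.cross(cap[:, 1], cap[:, 2])).sum()
        return self._cav_sign * vol / 6.0

    def cavity_volume_grad(self, u: np.ndarray) -> np.ndarray:
        """Analytic dV/du, shape (ndof,)."""
        x = self.nodes + u.reshape(self.n_nodes, 3)
        grad = np.zeros((self.n_nodes, 3))
        tris = self._cav_tris
        a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
        np.add.at(grad, tris[:, 0], np.cross(b, c))
        np.add.at(grad, tris[:, 1], np.cross(c, a))
        np.add.at(grad, tris[:, 2], np.cross(a, b))
        for ring, flip in ((self._cav_base_ring, True), (self._cav_apex_ring, False)):
            r = x[ring]
            cc = r.mean(axis=0)
            n = len(ring)
            nxt = np.roll(np.arange(n), -1)
            p1, p2 = (r[nxt], r) if flip else (r, r[nxt])
            g_c = np.cross(p1, p2).sum(axis=0)
            grad[ring] += g_c[None, :] / n
            g1 = np.cross(p2, np.broadcast_to(cc, p2.shape))
            g2 = np.cross(np.broadcast_to(cc, p1.shape), p1)
            if flip:
                idx1, idx2 = ring[nxt], ring
            else:
                idx1, idx2 = ring, ring[nxt]
            np.add.at(grad, idx1, g1)
            np.add.at(grad, idx2, g2)
        return self._cav_sign * grad.ravel() / 6.0

    # ----- element internal forces -------------------------------------------------

    def _element_internal(self, u_elem: np.ndarray, t: float) -> np.ndarray:
        """Internal nodal forces for batched element displacement states.

        u_elem: (ne, P, 8, 3) -> forces (ne, P, 8, 3).  P is a trial-state
        batch (used for finite-difference tangents).
        """
        F = np.einsum("epai,egaj->epgij", u_elem, self.gradN0, optimize=True)
        F = F + np.eye(3)
        J = det3(F)
        if np.any(J <= 0):
            raise StepRejected("inverted element at a Gauss point")
        C = np.einsum("...ki,...kj->...ij", F, F)
        Cinv = inv3(C)
        f0 = self.f0[:, None, None, :]
        s0 = self.s0[:, None, None, :]
        S = mat.dev_pk2_from_C(C, Cinv, J, f0, s0, self.mp)
        # mean dilatation: element-average J drives the volumetric pressure
        Jbar = np.einsum("eg,epg->ep", self.wJ0, J) / self.elem_vol0[:, None]
        pbar = mat.volumetric_pressure(Jbar, self.mp.D)
        S = S + (pbar[..., None] * J)[..., None, None] * Cinv
        # active fiber stress
        if t > 0.0 and np.any(self.t_max_elem > 0):
            I4f = np.einsum("...i,...ij,...j->...", f0, C, f0)
            T0 = mat.active_tension(t, 0.5 * (I4f - 1.0), replace(self.active, t_max=1.0))
            T0 = T0 * self.t_max_elem[:, None, None]
            ff = np.einsum("...i,...j->...ij", f0, f0)
            S = S + (T0 / I4f)[..., None, None] * ff
        P = np.einsum("...ik,...kj->...ij", F, S)
        f_int = np.einsum("eg,epgij,egaj->epai", self.wJ0, P, self.gradN0, optimize=True)
        return f_int

    def internal_force(self, u: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Global internal force vector (ndof,)."""
        if self.use_numba:
            u_e = np.ascontiguousarray(u.reshape(self.n_nodes, 3)[self.elems])
            fe, ok = _kernels.forces(
                u_e, self.gradN0, self.wJ0, self.elem_vol0, self.f0, self.s0,
                self._mpar, self.t_max_elem, float(t), self._apar,
            )
            if not ok:
                raise StepRejected("inverted element at a Gauss point")
        else:
            u_e = u.reshape(self.n_nodes, 3)[self.elems][:, None]  # (ne,1,8,3)
            fe = self._element_internal(u_e, t)[:, 0]
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof, fe.reshape(-1, 24))
        return f

    def strain_energy(self, u: np.ndarray) -> float:
        """Passive strain energy of the mean-dilatation formulation (mJ =
        MPa*cm^3)."""
        u_e = u.reshape(self.n_nodes, 3)[self.elems]
        F = np.einsum("eai,egaj->egij", u_e, self.gradN0, optimize=True) + np.eye(3)
        J = det3(F)
        psi_dev = mat.strain_energy(F, self.f0[:, None, :], self.s0[:, None, :], self.mp)
        # subtract the pointwise volumetric part, replace by mean dilatation
        psi_dev = psi_dev - ((J * J - 1.0) / 2.0 - np.log(J)) / self.mp.D
        Jbar = np.einsum("eg,eg->e", self.wJ0, J) / self.elem_vol0
        e = np.einsum("eg,eg->", self.wJ0, psi_dev)
        e += (self.elem_vol0 * ((Jbar**2 - 1.0) / 2.0 - np.log(Jbar)) / self.mp.D).sum()
        return float(e)

    def element_internal_force(
        self, elem_id: int, u: np.ndarray, t: float = 0.0, fd_step: float = 1e-7
    ) -> tuple[np.ndarray, np.ndarray]:
        """Residual vector (24,) and consistent tangent (24, 24) of one
        element (forward-difference tangent of the exact residual)."""
        u_e = u.reshape(self.n_nodes, 3)[self.elems[elem_id : elem_id + 1]]
        batch = self._fd_batch(u_e, fd_step)
        f = self._element_internal(batch, t)[0]
        r = f[0].ravel()
        K = (f[1:].reshape(24, 24) - r[None, :]) / fd_step
        return r, K.T

    @staticmethod
    def _fd_batch(u_e: np.ndarray, h: float) -> np.ndarray:
        """(ne,8,3) -> (ne,25,8,3): base state plus 24 perturbed states."""
        ne = u_e.shape[0]
        batch = np.repeat(u_e[:, None], 25, axis=1)
        pert = np.arange(24)
        a, i = divmod(pert, 3)
        batch[:, 1 + pert, a, i] += h
        return batch

    def tangent_internal(self, u: np.ndarray, t: float, fd_step: float = 1e-7) -> sp.csr_matrix:
        """Global tangent of the internal force (FD of element residuals)."""
        u_e = np.ascontiguousarray(u.reshape(self.n_nodes, 3)[self.elems])
        if self.use_numba:
            _, Ke, ok = _kernels.forces_and_tangents(
                u_e, self.gradN0, self.wJ0, self.elem_vol0, self.f0, self.s0,
                self._mpar, self.t_max_elem, float(t), self._apar, fd_step,
            )
            if not ok:
                raise StepRejected("inverted element at a Gauss point")
        else:
            batch = self._fd_batch(u_e, fd_step)
            f = self._element_internal(batch, t)  # (ne,25,8,3)
            base = f[:, 0].reshape(-1, 1, 24)
            Ke = (f[:, 1:].reshape(-1, 24, 24) - base) / fd_step  # [e, col, row]
            Ke = np.swapaxes(Ke, 1, 2)
        K = sp.coo_matrix((Ke.ravel(), (self._krows, self._kcols)), shape=(self.ndof, self.ndof))
        return K.tocsr()

    # ----- cavity pressure load (fluid-cavity virtual work) ------------------------

    def cavity_load(self, u: np.ndarray) -> np.ndarray:
        """Nodal load per unit cavity pressure (MPa): p delta-V gives the
        follower force p dV/du over the closed cavity surface (lateral
        endocardium plus basal/apical caps), exactly energy-consistent
        with :meth:`cavity_volume`."""
        return self.cavity_volume_grad(u)

    def tangent_load(self, u: np.ndarray) -> sp.csr_matrix:
        """Load stiffness per unit pressure: the analytic cavity-volume
        Hessian d^2 V / du^2 (symmetric)."""
        x = self.nodes + u.reshape(self.n_nodes, 3)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        data: list[np.ndarray] = []

        def skew(v: np.ndarray) -> np.ndarray:
            out = np.zeros(v.shape[:-1] + (3, 3))
            out[..., 0, 1] = -v[..., 2]
            out[..., 0, 2] = v[..., 1]
            out[..., 1, 0] = v[..., 2]
            out[..., 1, 2] = -v[..., 0]
            out[..., 2, 0] = -v[..., 1]
            out[..., 2, 1] = v[..., 0]
            return out

        def add_blocks(ni, nj, wi, wj, M):
            """Accumulate wi*wj*M at 3x3 blocks (ni, nj); ni/nj arrays."""
            r = (3 * ni[:, None, None] + np.arange(3)[None, :, None]).repeat(3, axis=2)
            c = (3 * nj[:, None, None] + np.arange(3)[None, None, :]).repeat(3, axis=1)
            rows.append(r.ravel())
            cols.append(c.ravel())
            data.append(((wi * wj)[:, None, None] * M).ravel())

        def add_triangle_blocks(v0, v1, v2, w0, w1, w2):
            """Hessian of sum (1/6) x0 . (x1 x x2) for triangles given by
            vertex node-index arrays and per-triangle weights (for cap
            centroids the weight spreads over ring nodes)."""
            a, b, c = x[v0], x[v1], x[v2]
            s = self._cav_sign / 6.0
            pairs = [
                (v0, v1, w0, w1, -skew(c)),  # d2V/da db
                (v0, v2, w0, w2, skew(b)),
                (v1, v2, w1, w2, -skew(a)),
            ]
            for ni, nj, wi, wj, M in pairs:
                add_blocks(ni, nj, wi, wj, s * M)
                add_blocks(nj, ni, wj, wi, s * np.swapaxes(M, -1, -2))

        tris = self._cav_tris
        ones = np.ones(len(tris))
        add_triangle_blocks(tris[:, 0], tris[:, 1], tris[:, 2], ones, ones, ones)

        for ring, flip in ((self._cav_base_ring, True), (self._cav_apex_ring, False)):
            n = len(ring)
            nxt = np.roll(np.arange(n), -1)
            p1, p2 = (ring[nxt], ring) if flip else (ring, ring[nxt])
            cc = x[ring].mean(axis=0)
            b, c = x[p1], x[p2]
            s = self._cav_sign / 6.0
            w = np.ones(n)
            # (p1, p2) pair: centroid is the third vertex
            Mbc = -skew(np.broadcast_to(cc, b.shape))
            add_blocks(p1, p2, w, w, s * Mbc)
            add_blocks(p2, p1, w, w, s * np.swapaxes(Mbc, -1, -2))
            # pairs involving the centroid: spread with weight 1/n over ring
            for rj in range(n):
                wj = np.full(n, 1.0 / n)
                ring_arr = ring
                Mab = s * -skew(np.broadcast_to(c[rj], (n, 3)))  # (c, p1) pair
                add_blocks(ring_arr, np.full(n, p1[rj]), wj, np.ones(n), Mab)
                add_blocks(np.full(n, p1[rj]), ring_arr, np.ones(n), wj,
                           np.swapaxes(Mab, -1, -2))
                Mac = s * skew(np.broadcast_to(b[rj], (n, 3)))  # (c, p2) pair
                add_blocks(ring_arr, np.full(n, p2[rj]), wj, np.ones(n), Mac)
                add_blocks(np.full(n, p2[rj]), ring_arr, np.ones(n), wj,
                           np.swapaxes(Mac, -1, -2))

        H = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        )
        return H.tocsr()

    # ----- residual / BC helpers ---------------------------------------------------

    def residual(self, u: np.ndarray, t: float, p_mmhg: float) -> np.ndarray:
        """Out-of-balance force with BC rows zeroed (constraint forces not
        included; they are appended by the solver)."""
        r = self.internal_force(u, t)
        if p_mmhg != 0.0:
            r = r - (p_mmhg * MMHG_TO_MPA) * self.cavity_load(u)
        r[self.fixed_dofs] = 0.0
        return r

    def _apply_bc_matrix(self, K: sp.csr_matrix) -> sp.csr_matrix:
        mask = sp.diags(self.free_mask.astype(float))
        K = mask @ K @ mask + sp.diags(self.fixed_dofs.astype(float))
        return K.tocsr()


def _interp_control(control: dict, state_from: SimState, frac: float, model: FEModel) -> dict:
    """Control for a partial increment (load-cutback bisection)."""
    c = dict(control)
    kind = c["kind"]
    if kind == "pressure":
        p0 = state_from.cavity_pressure
        c["pressure"] = p0 + frac * (control["pressure"] - p0)
    elif kind == "volume":
        v0 = model.cavity_volume(state_from.u)
        c["volume"] = v0 + frac * (control["volume"] - v0)
    elif kind == "windkessel":
        c["dt"] = frac * control["dt"]
    return c


def newton_solve(
    model: FEModel,
    state: SimState,
    control: dict,
    *,
    time: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    max_iter: int = 25,
    tangent: str = "step",
    fd_step: float = 1e-7,
    cache: dict | None = None,
) -> SimState:
    """Solve one equilibrium problem by Newton iteration.

    ``control`` selects the loading mode:

    - ``{"kind": "pressure", "pressure": p_mmhg}`` — prescribed cavity
      pressure;
    - ``{"kind": "volume", "volume": v_ml}`` — prescribed cavity volume,
      cavity pressure is an unknown;
    - ``{"kind": "windkessel", "dt": s, "p_prev": mmHg, "v_prev": ml,
      "resistance": mmHg*s/ml, "compliance": ml/mmHg}`` — ejection against
      a two-element Windkessel (backward Euler), pressure unknown.

    ``tangent='step'`` freezes the tangent factorization at the step start
    (refreshed if convergence stalls); ``'full'`` reassembles every
    iteration (quadratic convergence, used by verification tests).
    """
    t = state.time if time is None else time
    kind = control["kind"]
    u = state.u.copy().ravel()
    p = control["pressure"] if kind == "pressure" else state.cavity_pressure
    lam = np.zeros(3) if model.G is not None else None

    v_ref = abs(model.cavity_volume(u)) if kind != "pressure" else 1.0
    # a factorization from a previous, nearby step may be reused; the
    # monotonicity test below rejects it automatically when it stalls
    lu = cache.get(("lu", kind)) if (cache is not None and tangent == "step") else None

    def build_residual(u, p, lam):
        """Augmented residual and the force scale for relative tolerances."""
        f_int = model.internal_force(u, t)
        f_int[model.fixed_dofs] = 0.0
        scale = np.linalg.norm(f_int)
        r = f_int
        if p != 0.0:
            fl = (p * MMHG_TO_MPA) * model.cavity_load(u)
            fl[model.fixed_dofs] = 0.0
            scale = max(scale, np.linalg.norm(fl))
            r = r - fl
        parts = [r]
        if lam is not None:
            parts = [r + model.G.T @ lam, model.G @ u]
        if kind == "volume":
            parts.append(np.array([model.cavity_volume(u) - control["volume"]]))
        elif kind == "windkessel":
            v = model.cavity_volume(u)
            dt = control["dt"]
            g = (
                control["compliance"] * (p - control["p_prev"]) / dt
                + p / control["resistance"]
                - (control["v_prev"] - v) / dt
            )
            parts.append(np.array([g]))
        r_aug = np.concatenate(parts) if len(parts) > 1 else parts[0]
        return r_aug, scale

    def assemble(u, p):
        K = model.tangent_internal(u, t, fd_step)
        if p != 0.0:
            K = K - (p * MMHG_TO_MPA) * model.tangent_load(u)
        K = model._apply_bc_matrix(K)
        blocks = [[K]]
        if lam is not None:
            blocks[0].append(model.G.T)
            blocks.append([model.G, None])
        if kind != "pressure":
            col = -MMHG_TO_MPA * model.cavity_load(u)
            col[model.fixed_dofs] = 0.0
            for b in blocks[1:]:
                b.append(None)
            blocks[0].append(sp.csc_matrix(col[:, None]))
            dv = model.cavity_volume_grad(u)
            dv[model.fixed_dofs] = 0.0
            row = [sp.csc_matrix(dv[None, :])]
            if lam is not None:
                row.append(None)
            if kind == "volume":
                dgdp = 0.0
            else:
                dv /= control["dt"]
                row = [sp.csc_matrix(dv[None, :])]
                if lam is not None:
                    row.append(None)
                dgdp = control["compliance"] / control["dt"] + 1.0 / control["resistance"]
            row.append(sp.csc_matrix(np.array([[dgdp]])))
            blocks.append(row)
        return splu(sp.bmat(blocks, format="csc"))

    r_aug, scale = build_residual(u, p, lam)
    it = 0
    fresh_tangent = False
    dx = None  # Newton direction -J^{-1} r at (u, p, lam) for the current lu
    while True:
        r_u = r_aug[: model.ndof]
        ok = np.linalg.norm(r_u) <= max(rtol * max(scale, atol), atol)
        if lam is not None:
            ok &= np.linalg.norm(r_aug[model.ndof : model.ndof + 3]) <= 1e-9 * max(
                1.0, np.linalg.norm(u)
            )
        if kind != "pressure":
            g = r_aug[-1] * (control["dt"] if kind == "windkessel" else 1.0)
            ok &= abs(g) <= 1e-6 * max(v_ref, 1.0)
        if ok:
            if cache is not None and lu is not None:
                cache[("lu", kind)] = lu
            return SimState(
                u=u.reshape(model.n_nodes, 3),
                cavity_pressure=float(p),
                time=t,
                converged=True,
                newton_iterations=it,
            )
        if it >= max_iter:
            raise SolverError(
                f"Newton failed: |r|={np.linalg.norm(r_u):.3e}, scale={scale:.3e}, it={it}"
            )
        if lu is None or tangent == "full":
            try:
                lu = assemble(u, p)
                fresh_tangent, dx = True, None
            except StepRejected as exc:
                raise SolverError(str(exc)) from exc
        if dx is None:
            dx = lu.solve(-r_aug)
        if not np.all(np.isfinite(dx)):
            raise SolverError("singular tangent system")
        # Damped Newton with the affine-invariant (natural) monotonicity
        # test: accept when |J^{-1} r_trial| < |J^{-1} r_current| = |dx|.
        # Scale-invariant, so the mixed force/volume residual rows need no
        # ad hoc weighting.
        ndx = np.linalg.norm(dx)
        step, accepted = 1.0, False
        for _ in range(10):
            u_try = u + step * dx[: model.ndof]
            lam_try = lam + step * dx[model.ndof : model.ndof + 3] if lam is not None else None
            p_try = p + step * dx[-1] if kind != "pressure" else p
            try:
                r_try, scale_try = build_residual(u_try, p_try, lam_try)
            except (StepRejected, FloatingPointError):
                step *= 0.5
                continue
            if not np.all(np.isfinite(r_try)):
                step *= 0.5
                continue
            dx_bar = lu.solve(-r_try)
            if np.linalg.norm(dx_bar) < ndx:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            if tangent == "step" and not fresh_tangent:
                lu = None  # stalled on a frozen tangent: refresh and retry
                continue
            raise SolverError(f"line search failed at it={it}")
        u, lam, p, r_aug, scale = u_try, lam_try, p_try, r_try, scale_try
        dx = dx_bar  # valid Newton direction at the new point for this lu
        # poor contraction on a frozen tangent: refresh it for the next pass
        if tangent == "step" and not fresh_tangent and np.linalg.norm(dx_bar) > 0.2 * ndx:
            lu, dx = None, None
        fresh_tangent = False
        it += 1


def advance(
    model: FEModel,
    state: SimState,
    control: dict,
    *,
    time: float | None = None,
    max_cutbacks: int = 10,
    _depth: int = 0,
    **kw,
) -> SimState:
    """Advance to a load/time target with automatic increment bisection."""
    t_new = state.time if time is None else time
    try:
        return newton_solve(model, state, control, time=t_new, **kw)
    except SolverError:
        if _depth >= max_cutbacks:
            raise
        c_half = _interp_control(control, state, 0.5, model)
        t_mid = 0.5 * (state.time + t_new)
        s_mid = advance(
            model, state, c_half, time=t_mid, max_cutbacks=max_cutbacks, _depth=_depth + 1, **kw
        )
        c_rest = dict(control)
        if control["kind"] == "windkessel":
            c_rest["dt"] = control["dt"] - c_half["dt"]
            c_rest["p_prev"] = s_mid.cavity_pressure
            c_rest["v_prev"] = model.cavity_volume(s_mid.u)
        return advance(
            model, s_mid, c_rest, time=t_new, max_cutbacks=max_cutbacks, _depth=_depth + 1, **kw
        )
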