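"""Material-point constitutive laws for passive and active myocardium.

Passive tissue is the orthotropic Holzapfel-Ogden hyperelastic model with
a deviatoric part expressed in isochoric invariants and a volumetric
penalty ``Psi_vol = (1/D)((J^2 - 1)/2 - ln J)`` with ``D = 2/K``:

    Psi_dev = a/(2b) exp(b (I1_bar - 3))
            + sum_{i=f,s} a_i/(2 b_i) {exp(b_i (I4i_bar - 1)^2) - 1}
            + a_fs/(2 b_fs) {exp(b_fs I8fs_bar^2) - 1}

where the fiber/sheet exponential terms contribute only in tension
(I4_bar > 1; fibers do not bear compression).  Default constants are the
named parameter set :func:`paper_table1`.

Active contraction is a time-varying elastance law with length-dependent
calcium sensitivity: the fiber tension is

    T0 = T_max * Ca0^2 / (Ca0^2 + ECa50^2) * Ct,
    Ct = (1 - cos omega)/2,
    ECa50 = Ca0_max / sqrt(exp(B (l - l0)) - 1),
    l = lR sqrt(2 Eff + 1),

with omega ramping over [0, t0] (peak at t = t0) and relaxing over the
length-dependent duration ``tr = m l + b``.  The active second
Piola-Kirchhoff stress is ``T0 f0 (x) f0 / I4f`` so the Cauchy fiber
stress magnitude is ``T0 lambda_f / J``.

All functions are vectorized over arbitrary leading batch dimensions.
Stresses in MPa, sarcomere lengths in micrometres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "MaterialParams",
    "ActiveParams",
    "Invariants",
    "paper_table1",
    "compute_invariants",
    "strain_energy",
    "passive_dev_pk2",
    "volumetric_pressure",
    "passive_pk2_stress",
    "active_tension",
    "total_stress",
]

_EXP_CAP = 60.0  # cap on exponent arguments; keeps trial Newton states finite


def _exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.minimum(x, _EXP_CAP))


@dataclass(frozen=True)
class MaterialParams:
    """Passive Holzapfel-Ogden constants (a-type in MPa) plus bulk modulus
    K (MPa); the compressibility parameter is D = 2/K."""

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    bulk_modulus: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bulk_modulus <= 0:
            raise ValueError("bulk modulus must be positive")

    @property
    def D(self) -> float:
        return 2.0 / self.bulk_modulus

    def as_array(self) -> np.ndarray:
        """The eight fit parameters in canonical order (a, b, a_f, b_f,
        a_s, b_s, a_fs, b_fs)."""
        return np.array(
            [self.a, self.b, self.a_f, self.b_f, self.a_s, self.b_s, self.a_fs, self.b_fs]
        )

    def with_array(self, x: np.ndarray) -> "MaterialParams":
        return replace(
            self, a=x[0], b=x[1], a_f=x[2], b_f=x[3], a_s=x[4], b_s=x[5], a_fs=x[6], b_fs=x[7]
        )


def paper_table1(bulk_modulus: float = 1.0) -> MaterialParams:
    """Named default passive parameter set fitted to the normal-subject
    end-diastolic pressure-volume curve."""
    return MaterialParams(
        a=6.832e-4,
        b=7.541,
        a_f=2.252e-3,
        b_f=14.471,
        a_s=3.127e-4,
        b_s=12.548,
        a_fs=1.837e-4,
        b_fs=3.088,
        bulk_modulus=bulk_modulus,
    )


@dataclass(frozen=True)
class ActiveParams:
    """Active-law constants (Guccione/Walker lineage defaults).

    t_max: peak isometric tension at largest sarcomere length and highest
    calcium (MPa) — the contractility dial varied per region.  ca0 and
    ca0_max in micromolar, b_len in 1/um, sarcomere lengths in um, m_relax
    in s/um, b_relax and t0 in s.
    """

    t_max: float = 0.086
    ca0: float = 4.35
    ca0_max: float = 4.35
    b_len: float = 4.75
    l0: float = 1.58
    lR: float = 1.95
    m_relax: float = 1.0489
    b_relax: float = -1.429
    t0: float = 0.2

    def __post_init__(self) -> None:
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")
        if not (self.lR >= self.l0 > 0):
            raise ValueError("require lR >= l0 > 0")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")


class Invariants(NamedTuple):
    I1: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    J: np.ndarray
    Eff: np.ndarray


def compute_invariants(F: np.ndarray, f0: np.ndarray, s0: np.ndarray) -> Invariants:
    """Kinematic invariants of C = F^T F for fiber/sheet directions.

    I1 = tr C, I4f = f0.C.f0, I4s = s0.C.s0, I8fs = f0.C.s0, J = det F,
    and the fiber Green-Lagrange strain Eff = (I4f - 1)/2.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("inverted deformation state: det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    Cf = np.einsum("...ij,...j->...i", C, f0)
    I4f = np.einsum("...i,...i->...", f0, Cf)
    I4s = np.einsum("...i,...ij,...j->...", s0, C, s0)
    I8fs = np.einsum("...i,...i->...", s0, Cf)
    return Invariants(I1=I1, I4f=I4f, I4s=I4s, I8fs=I8fs, J=J, Eff=0.5 * (I4f - 1.0))


def _isochoric(inv: Invariants) -> tuple[np.ndarray, ...]:
    scale = inv.J ** (-2.0 / 3.0)
    return scale * inv.I1, scale * inv.I4f, scale * inv.I4s, scale * inv.I8fs, scale


def strain_energy(F: np.ndarray, f0: np.ndarray, s0: np.ndarray, mp: MaterialParams) -> np.ndarray:
    """Total strain energy density Psi_dev + Psi_vol (MPa)."""
    inv = compute_invariants(F, f0, s0)
    I1b, I4fb, I4sb, I8b, _ = _isochoric(inv)
    # the "- 1" normalizes the energy to zero in the reference state
    psi = mp.a / (2.0 * mp.b) * (_exp(mp.b * (I1b - 3.0)) - 1.0)
    e4f = np.maximum(I4fb - 1.0, 0.0)
    e4s = np.maximum(I4sb - 1.0, 0.0)
    psi = psi + mp.a_f / (2.0 * mp.b_f) * (_exp(mp.b_f * e4f**2) - 1.0)
    psi = psi + mp.a_s / (2.0 * mp.b_s) * (_exp(mp.b_s * e4s**2) - 1.0)
    psi = psi + mp.a_fs / (2.0 * mp.b_fs) * (_exp(mp.b_fs * I8b**2) - 1.0)
    J = inv.J
    psi_vol = (1.0 / mp.D) * ((J * J - 1.0) / 2.0 - np.log(J))
    return psi + psi_vol


def dev_pk2_from_C(
    C: np.ndarray,
    Cinv: np.ndarray,
    J: np.ndarray,
    f0: np.ndarray,
    s0: np.ndarray,
    mp: MaterialParams,
) -> np.ndarray:
    """Deviatoric passive PK2 stress given precomputed C, C^-1 and J
    (assembler fast path; see :func:`passive_dev_pk2`)."""
    scale = J ** (-2.0 / 3.0)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    Cf = np.einsum("...ij,...j->...i", C, f0)
    I4f = np.einsum("...i,...i->...", f0, Cf)
    I4s = np.einsum("...i,...ij,...j->...", s0, C, s0)
    I8 = np.einsum("...i,...i->...", s0, Cf)
    I1b, I4fb, I4sb, I8b = scale * I1, scale * I4f, scale * I4s, scale * I8

    psi1 = 0.5 * mp.a * _exp(mp.b * (I1b - 3.0))
    e4f = I4fb - 1.0
    e4s = I4sb - 1.0
    psi4f = np.where(e4f > 0, mp.a_f * e4f * _exp(mp.b_f * e4f**2), 0.0)
    psi4s = np.where(e4s > 0, mp.a_s * e4s * _exp(mp.b_s * e4s**2), 0.0)
    psi8 = mp.a_fs * I8b * _exp(mp.b_fs * I8b**2)

    eye = np.broadcast_to(np.eye(3), C.shape)
    ff = np.einsum("...i,...j->...ij", f0, f0)
    ss = np.einsum("...i,...j->...ij", s0, s0)
    fs = np.einsum("...i,...j->...ij", f0, s0)
    fs = 0.5 * (fs + np.swapaxes(fs, -1, -2))

    # d(Ibar)/dC = scale * A - (Ibar/3) C^{-1}; note the unscaled Cinv term
    def dev_term(psi, A, I_unbarred):
        return psi[..., None, None] * (A - (I_unbarred / 3.0)[..., None, None] * Cinv)

    S = dev_term(psi1, eye, I1) + dev_term(psi4f, ff, I4f)
    S = S + dev_term(psi4s, ss, I4s) + dev_term(psi8, fs, I8)
    return 2.0 * scale[..., None, None] * S


def passive_dev_pk2(
    F: np.ndarray, f0: np.ndarray, s0: np.ndarray, mp: MaterialParams
) -> np.ndarray:
    """Deviatoric passive second Piola-Kirchhoff stress S = 2 dPsi_dev/dC
    (isochoric invariants; anisotropic fiber/sheet terms tension-only)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("inverted deformation state: det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    return dev_pk2_from_C(C, np.linalg.inv(C), J, f0, s0, mp)


def volumetric_pressure(J: np.ndarray, D: float) -> np.ndarray:
    """dPsi_vol/dJ = (1/D)(J - 1/J) (MPa)."""
    J = np.asarray(J, dtype=float)
    return (J - 1.0 / J) / D


def passive_pk2_stress(
    F: np.ndarray, f0: np.ndarray, s0: np.ndarray, mp: MaterialParams
) -> np.ndarray:
    """Full passive PK2 stress: deviatoric part plus pointwise volumetric
    part ``p J C^{-1}`` with p = dPsi_vol/dJ."""
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    J = np.linalg.det(F)
    p = volumetric_pressure(J, mp.D)
    return passive_dev_pk2(F, f0, s0, mp) + (p * J)[..., None, None] * Cinv


def active_tension(t: float, Eff: np.ndarray, ap: ActiveParams) -> np.ndarray:
    """Scalar active fiber tension T0(t, Eff) in MPa.

    Zero before activation (t <= 0), after the length-dependent relaxation
    completes (t >= t0 + tr), and at or below the zero-tension sarcomere
    length l0.
    """
    Eff = np.asarray(Eff, dtype=float)
    stretch_sq = 2.0 * Eff + 1.0
    if np.any(stretch_sq <= 0):
        raise ValueError("fiber stretch^2 must be positive")
    if ap.t_max == 0.0 or t <= 0.0:
        return np.zeros_like(Eff)
    l = ap.lR * np.sqrt(stretch_sq)
    tr = np.maximum(ap.m_relax * l + ap.b_relax, 1e-9)
    omega = np.where(
        t <= ap.t0,
        np.pi * t / ap.t0,
        np.where(t <= ap.t0 + tr, np.pi * (t - ap.t0 + tr) / tr, 2.0 * np.pi),
    )
    ct = 0.5 * (1.0 - np.cos(omega))
    dl = l - ap.l0
    denom_arg = _exp(ap.b_len * dl) - 1.0
    active = dl > 0
    eca50_sq = np.where(active, ap.ca0_max**2 / np.maximum(denom_arg, 1e-30), np.inf)
    t0_tension = ap.t_max * ap.ca0**2 / (ap.ca0**2 + eca50_sq) * ct
    return np.where(active, t0_tension, 0.0)


def total_stress(
    F: np.ndarray,
    f0: np.ndarray,
    s0: np.ndarray,
    mp: MaterialParams,
    ap: ActiveParams,
    t: float,
) -> np.ndarray:
    """Total PK2 stress: passive plus active ``T0 f0 (x) f0 / I4f``."""
    inv = compute_invariants(F, f0, s0)
    T0 = active_tension(t, inv.Eff, ap)
    ff = np.einsum("...i,...j->...ij", f0, f0)
    return passive_pk2_stress(F, f0, s0, mp) + (T0 / inv.I4f)[..., None, None] * ff
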