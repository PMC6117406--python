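"""Calibration: passive parameters against the Klotz EDPVR, contractility
against a measured end-systolic volume.

The Klotz single-point method reconstructs a whole end-diastolic
pressure-volume relation from one measured (V, P) pair:

    P(V) = An * Vn^Bn,   Vn = (V - V0) / (V30 - V0),

with species-independent constants An = 28.2 mmHg and Bn = 2.79, the
regression V0 = EDV (0.6 - 0.006 EDP) for the unloaded volume, and V30
(volume at 30 mmHg) fixed by requiring the curve to pass through the
measured point.  The eight passive constants are then fitted with SLSQP so
the model's passive inflation matches this curve at matched pressures; the
fit is judged by curve mismatch (RMS volume error), never by parameter
values — an eight-parameter exponential fit to one curve is not unique.

Contractility calibration is a bracketed scalar root-find on T_max so the
simulated ESV hits the echo target; end-diastole does not depend on
contractility, so all trial beats share one ED state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .fe import FEModel, SimState, SolverError, advance, newton_solve
from .geometry import klotz_unloaded_volume
from .hemodynamics import AfterloadParams, BeatResult, inflate_to_volume, run_beat
from .materials import MaterialParams

__all__ = [
    "KlotzCurve",
    "klotz_pressure",
    "FitReport",
    "fit_passive_params",
    "CalibrationError",
    "calibrate_tmax_uniform",
    "calibrate_tmax_subepi",
]

#: region codes (see geometry.REGION_NAMES)
SUBENDO, MID, SUBEPI = 0, 1, 2


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class KlotzCurve:
    """Single-point analytic EDPVR (volumes ml, pressures mmHg)."""

    v0: float
    v30: float
    vm: float
    pm: float
    an: float = 28.2
    bn: float = 2.79

    @classmethod
    def from_measurement(cls, edv: float, edp: float, an: float = 28.2, bn: float = 2.79) -> "KlotzCurve":
        v0 = klotz_unloaded_volume(edv, edp)
        v30 = v0 + (edv - v0) / (edp / an) ** (1.0 / bn)
        return cls(v0=v0, v30=v30, vm=edv, pm=edp, an=an, bn=bn)

    def pressure(self, v: np.ndarray) -> np.ndarray:
        """P(V); zero below the unloaded volume."""
        v = np.asarray(v, dtype=float)
        vn = np.clip((v - self.v0) / (self.v30 - self.v0), 0.0, None)
        return self.an * vn**self.bn

    def volume(self, p: np.ndarray) -> np.ndarray:
        """Inverse curve V(P) for P >= 0."""
        p = np.asarray(p, dtype=float)
        return self.v0 + (self.v30 - self.v0) * (p / self.an) ** (1.0 / self.bn)


def klotz_pressure(curve: KlotzCurve, v: float) -> float:
    return float(curve.pressure(v))


@dataclass
class FitReport:
    params: MaterialParams
    rms_volume_error: float  # ml, over the sampled pressures
    volume_at_edp: float     # ml, fitted model volume at the measured EDP
    n_evaluations: int
    n_iterations: int
    success: bool
    message: str


def fit_passive_params(
    model: FEModel,
    curve: KlotzCurve,
    init: MaterialParams,
    *,
    n_samples: int = 8,
    maxiter: int = 20,
    a_bounds: tuple[float, float] = (1e-6, 1e-1),
    b_bounds: tuple[float, float] = (0.1, 30.0),
    rtol: float = 1e-7,
) -> tuple[MaterialParams, FitReport]:
    """Fit the eight passive constants to the Klotz curve with SLSQP.

    The objective compares model and Klotz volumes at ``n_samples`` evenly
    spaced pressures in (0, EDP] (robust where the curves are steep in V).
    Parameters are optimized as multiples of ``init`` within the given
    absolute bounds; a failed forward solve is penalized, so the optimizer
    backs away from pathological parameter sets.  A one-dimensional
    stiffness prescale (secant on the common factor of the four a-type
    moduli so the model matches the measured ED point) supplies the SLSQP
    starting point — the geometry generally needs an overall softening or
    stiffening that a finite-difference SQP is slow to find on its own.
    """
    pressures = np.linspace(curve.pm / n_samples, curve.pm, n_samples)
    v_target = curve.volume(pressures)
    x0_abs = init.as_array()
    bounds = [
        (lo / x0_abs[i], hi / x0_abs[i])
        for i, (lo, hi) in enumerate([a_bounds, b_bounds] * 4)
    ]
    n_eval = 0
    a_idx = [0, 2, 4, 6]
    # warm starts: converged state per sampled pressure from the previous
    # evaluation (parameters move little between SQP evaluations, so a
    # direct re-solve from the old equilibrium converges in a few steps)
    warm: list[SimState | None] = [None] * n_samples
    cache: dict = {}

    def volumes_of(x_rel: np.ndarray) -> np.ndarray | None:
        nonlocal n_eval
        n_eval += 1
        model.set_material(init.with_array(x_rel * x0_abs))
        vs = np.empty(n_samples)
        state = SimState(u=np.zeros((model.n_nodes, 3)))
        for k, p in enumerate(pressures):
            control = {"kind": "pressure", "pressure": float(p)}
            solved = None
            if warm[k] is not None:
                try:
                    solved = newton_solve(
                        model, warm[k], control, rtol=rtol, cache=cache, max_iter=12
                    )
                except SolverError:
                    solved = None
            if solved is None:
                try:
                    solved = advance(model, state, control, rtol=rtol, cache=cache)
                except SolverError:
                    return None
            warm[k] = solved
            state = solved
            vs[k] = model.cavity_volume(solved.u)
        return vs

    def x_of_scale(s: float) -> np.ndarray:
        x = np.ones(8)
        x[a_idx] = s
        return x

    # --- stage 1: common a-type scale matching V(EDP) = measured EDV ----
    s0, s1 = 1.0, None
    f_prev, s_prev = None, None
    s_best, err_best = 1.0, np.inf
    for _ in range(8):
        vs = volumes_of(x_of_scale(s0))
        if vs is None:
            s0 = np.sqrt(s0)  # soften/stiffen less aggressively
            continue
        err = vs[-1] - curve.vm
        if abs(err) < abs(err_best):
            s_best, err_best = s0, abs(err)
        if abs(err) < 0.005 * curve.vm:
            break
        if f_prev is None or err == f_prev:
            s1 = s0 * (2.0 if err > 0 else 0.5)  # stiffer model -> soften
        else:
            ln_s = np.log(s0) - err * (np.log(s0) - np.log(s_prev)) / (err - f_prev)
            s1 = float(np.exp(np.clip(ln_s, np.log(s0) - 1.5, np.log(s0) + 1.5)))
        f_prev, s_prev = err, s0
        lo_rel = max(a_bounds[0] / x0_abs[a_idx].max(), 1e-3)
        hi_rel = a_bounds[1] / x0_abs[a_idx].min()
        s0 = float(np.clip(s1, lo_rel, hi_rel))
    x_start = x_of_scale(s_best)

    # --- stage 2: SLSQP on all eight parameters ------------------------
    def objective(x_rel: np.ndarray) -> float:
        vs = volumes_of(x_rel)
        if vs is None:
            return 1e6
        return float(np.sum((vs - v_target) ** 2))

    obj_start = objective(x_start)
    res = minimize(
        objective,
        x_start,
        method="SLSQP",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-4, "eps": 1e-3},
    )
    x_best = res.x if res.fun <= obj_start else x_start
    fitted = init.with_array(x_best * x0_abs)
    vs = volumes_of(x_best)
    if vs is None:  # pragma: no cover - best iterate should be solvable
        raise CalibrationError("passive fit: best iterate does not converge")
    rms = float(np.sqrt(np.mean((vs - v_target) ** 2)))
    model.set_material(fitted)
    report = FitReport(
        params=fitted,
        rms_volume_error=rms,
        volume_at_edp=float(vs[-1]),
        n_evaluations=n_eval,
        n_iterations=int(res.nit),
        success=bool(res.success),
        message=str(res.message),
    )
    return fitted, report


def _esv_root_find(
    esv_of,  # Callable[[float], BeatResult]
    target_esv: float,
    x0: float,
    x1: float,
    *,
    tol_ml: float = 0.2,
    bounds: tuple[float, float] = (0.0, 0.5),
    max_evals: int = 12,
    strict: bool = True,
) -> tuple[float, BeatResult]:
    """Secant iteration with bracketing safeguard on ESV(t_max) - target.

    ESV decreases monotonically with contractility, so a sign change
    brackets the root; secant steps outside the bracket fall back to
    bisection.
    """
    lo, hi = bounds
    evals: list[tuple[float, float, BeatResult]] = []

    def f(x: float) -> tuple[float, BeatResult]:
        beat = esv_of(x)
        err = beat.esv - target_esv
        evals.append((x, err, beat))
        return err, beat

    f0, b0 = f(x0)
    if abs(f0) <= tol_ml:
        return x0, b0
    f1, b1 = f(x1)
    while len(evals) < max_evals:
        if abs(f1) <= tol_ml:
            return x1, b1
        # bracket from all evaluations so far (f decreasing in x)
        above = [x for x, e, _ in evals if e > 0]
        below = [x for x, e, _ in evals if e < 0]
        blo = max(above) if above else lo
        bhi = min(below) if below else hi
        if f1 != f0:
            x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        else:
            x2 = 0.5 * (blo + bhi)
        if not (blo < x2 < bhi) or not np.isfinite(x2):
            x2 = 0.5 * (blo + bhi)
        x2 = float(np.clip(x2, lo + 1e-6, hi))
        x0, f0 = x1, f1
        f1, b1 = f(x2)
        x1 = x2
    best = min(evals, key=lambda e: abs(e[1]))
    if abs(best[1]) > tol_ml:
        if strict:
            raise CalibrationError(
                f"ESV target {target_esv} ml not reached within {tol_ml} ml "
                f"(best |error| {abs(best[1]):.2f} ml at t_max={best[0]:.4f} MPa)"
            )
        import warnings

        warnings.warn(
            f"ESV target {target_esv} ml unreachable (best |error| "
            f"{abs(best[1]):.2f} ml at t_max={best[0]:.4f} MPa); returning the "
            "best iterate",
            RuntimeWarning,
            stacklevel=3,
        )
    return best[0], best[2]


def calibrate_tmax_uniform(
    model: FEModel,
    afterload: AfterloadParams,
    target_esv: float,
    edv: float,
    *,
    dt: float = 0.005,
    ed_state: SimState | None = None,
    guesses: tuple[float, float] = (0.06, 0.10),
    tol_ml: float = 0.2,
) -> tuple[float, BeatResult]:
    """Uniform T_max (MPa) such that the beat's ESV hits ``target_esv``."""
    if not target_esv < edv:
        raise CalibrationError("target ESV must be below EDV")
    if ed_state is None:
        ed_state = inflate_to_volume(model, edv)

    def esv_of(t_max: float) -> BeatResult:
        model.set_t_max(t_max)
        return run_beat(model, afterload, edv, dt=dt, ed_state=ed_state)

    t_max, beat = _esv_root_find(esv_of, target_esv, *guesses, tol_ml=tol_ml)
    model.set_t_max(t_max)
    return t_max, beat


def calibrate_tmax_subepi(
    model: FEModel,
    afterload: AfterloadParams,
    baseline_tmax: float,
    target_esv: float,
    edv: float,
    *,
    dt: float = 0.005,
    ed_state: SimState | None = None,
    tol_ml: float = 0.2,
    strict: bool = True,
) -> tuple[float, BeatResult]:
    """Subepicardial T_max restoring ``target_esv`` with a silenced
    subendocardium (T_max = 0 in layers 1-3, baseline in layers 4-5).

    With ``strict=False`` an unreachable target returns the best iterate
    (with a warning) instead of raising, so a study can still report the
    best-achievable compensation.
    """
    if ed_state is None:
        ed_state = inflate_to_volume(model, edv)

    def esv_of(t_sub: float) -> BeatResult:
        model.set_t_max({SUBENDO: 0.0, MID: baseline_tmax, SUBEPI: t_sub})
        return run_beat(model, afterload, edv, dt=dt, ed_state=ed_state)

    t_sub, beat = _esv_root_find(
        esv_of, target_esv, baseline_tmax, 1.5 * baseline_tmax, tol_ml=tol_ml,
        strict=strict, max_evals=8,
    )
    model.set_t_max({SUBENDO: 0.0, MID: baseline_tmax, SUBEPI: t_sub})
    return t_sub, beat
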