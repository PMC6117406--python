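"""One-beat hemodynamics: diastolic loading, isovolumic contraction,
ejection against a lumped afterload, and end-systole detection.

Diastole is simulated quasi-statically.  :func:`inflate_to_edp` ramps the
endocardial pressure to a target EDP and records the passive PV curve (the
Klotz-fit comparison); :func:`run_beat` instead loads the cavity under
volume control to the measured EDV (so the beat's EDV is exactly the echo
value) and reads off the model EDP as a fit check.

Systole: activation starts at ED (t = 0 of the active law).  While the
mitral and aortic valves are closed the cavity volume is held at EDV
(isovolumic contraction; cavity pressure is the constraint unknown).  When
cavity pressure reaches the aortic opening pressure, ejection begins
against a two-element Windkessel (peripheral resistance R, arterial
compliance C, backward-Euler coupling; the open valve is lossless, so
arterial and cavity pressure coincide).  End systole is the instant
outflow returns to zero (valve closure); ESV and ESP are recorded there.
If peak cavity pressure never reaches the opening pressure the beat is
flagged "no ejection" and EF = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fe import FEModel, SimState, advance

__all__ = ["AfterloadParams", "BeatResult", "inflate_to_edp", "inflate_to_volume", "run_beat"]


@dataclass(frozen=True)
class AfterloadParams:
    """Two-element Windkessel behind an aortic opening pressure.

    Units: mmHg, ml, s.  Defaults give a normal-range end-systolic
    pressure for the reference subject; the pipeline recalibrates the
    resistance once on the baseline scenario and then freezes it.
    """

    aortic_opening_pressure: float = 80.0
    arterial_resistance: float = 0.55
    arterial_compliance: float = 0.30

    def __post_init__(self) -> None:
        if min(self.aortic_opening_pressure, self.arterial_resistance, self.arterial_compliance) <= 0:
            raise ValueError("afterload parameters must be positive")


@dataclass
class BeatResult:
    """Pressure-volume history of one simulated beat plus ED/ES snapshots.

    ``times`` are active-law times (s, 0 = end diastole); pressures mmHg,
    volumes ml.  ``esp`` is the cavity pressure at valve closure.
    """

    times: np.ndarray
    pressures: np.ndarray
    volumes: np.ndarray
    edv: float
    esv: float
    esp: float
    edp: float
    ed_state: SimState
    es_state: SimState
    ejected: bool = True

    @property
    def ejection_fraction(self) -> float:
        return 100.0 * (self.edv - self.esv) / self.edv


def inflate_to_edp(
    model: FEModel,
    edp: float,
    n_steps: int = 8,
    pressures: np.ndarray | None = None,
    **solver_kw,
) -> tuple[SimState, np.ndarray, np.ndarray]:
    """Pressure-controlled passive inflation to ``edp`` (mmHg).

    Returns the final state and the (P, V) record at every load step,
    starting from (0, V0).
    """
    state = SimState(u=np.zeros((model.n_nodes, 3)))
    cache: dict = {}
    if pressures is None:
        pressures = np.linspace(edp / n_steps, edp, n_steps)
    ps = [0.0]
    vs = [model.cavity_volume(state.u)]
    for p in pressures:
        state = advance(
            model, state, {"kind": "pressure", "pressure": float(p)}, cache=cache, **solver_kw
        )
        ps.append(float(p))
        vs.append(model.cavity_volume(state.u))
    return state, np.array(ps), np.array(vs)


def inflate_to_volume(model: FEModel, v_target: float, n_steps: int = 9) -> SimState:
    """Volume-controlled passive inflation (cavity pressure unknown).

    Increments are log-spaced in volume — denser early, where the
    exponential wall is softest and the response steepest in V.
    """
    state = SimState(u=np.zeros((model.n_nodes, 3)))
    cache: dict = {}
    v0 = model.cavity_volume(state.u)
    if v_target < v0:
        raise ValueError(f"target volume {v_target} below unloaded volume {v0:.2f}")
    # a whisper of pressure moves the state off the floppy stress-free
    # configuration before the volume constraint takes over
    state = advance(model, state, {"kind": "pressure", "pressure": 0.2}, cache=cache)
    v_seed = model.cavity_volume(state.u)
    if v_seed >= v_target:  # pragma: no cover - target inside the toe region
        state.cavity_pressure = 0.2
        return state
    schedule = v_seed * (v_target / v_seed) ** (np.arange(1, n_steps + 1) / n_steps)
    for v in schedule:
        state = advance(model, state, {"kind": "volume", "volume": float(v)}, cache=cache)
    return state


def run_beat(
    model: FEModel,
    afterload: AfterloadParams,
    edv: float,
    *,
    dt: float = 0.005,
    t_end: float = 0.5,
    ed_state: SimState | None = None,
    n_inflation_steps: int = 9,
) -> BeatResult:
    """Simulate one beat; see the module docstring for the phase logic.

    ``ed_state`` may carry a previously computed end-diastolic state for
    the same model/EDV (diastole is contractility-independent, so
    calibration loops reuse it).
    """
    if ed_state is None:
        ed_state = inflate_to_volume(model, edv, n_steps=n_inflation_steps)
    edp = ed_state.cavity_pressure
    state = ed_state.copy()
    state.time = 0.0
    cache: dict = {}

    times = [0.0]
    pressures = [edp]
    volumes = [edv]
    phase = "isovolumic"
    ejected = False
    es_state = None
    esv, esp = edv, edp
    p_peak = edp
    v_prev = edv

    t = 0.0
    while t < t_end - 1e-12:
        t = round(t + dt, 12)
        if phase == "isovolumic":
            state = advance(
                model, state, {"kind": "volume", "volume": edv}, time=t, cache=cache
            )
            p_peak = max(p_peak, state.cavity_pressure)
            if state.cavity_pressure >= afterload.aortic_opening_pressure:
                phase = "ejection"
                v_prev = edv
            elif t > model.active.t0 and state.cavity_pressure < 0.5 * p_peak:
                break  # activation has peaked and relaxed: no ejection
        else:
            control = {
                "kind": "windkessel",
                "dt": dt,
                "p_prev": state.cavity_pressure,
                "v_prev": v_prev,
                "resistance": afterload.arterial_resistance,
                "compliance": afterload.arterial_compliance,
            }
            prev_state = state
            state = advance(model, state, control, time=t, cache=cache)
            v_now = model.cavity_volume(state.u)
            outflow = (v_prev - v_now) / dt
            if outflow <= 0.0:
                # valve closes: end systole is the last ejecting state
                es_state = prev_state
                esv, esp = v_prev, prev_state.cavity_pressure
                ejected = True
                break
            v_prev = v_now
            ejected = True
        times.append(t)
        pressures.append(state.cavity_pressure)
        volumes.append(model.cavity_volume(state.u))

    if es_state is None:
        if ejected:  # ran past t_end while still ejecting: take the last state
            es_state = state
            esv, esp = volumes[-1], pressures[-1]
        else:
            es_state = state
            esv, esp = edv, max(pressures)
    return BeatResult(
        times=np.array(times),
        pressures=np.array(pressures),
        volumes=np.array(volumes),
        edv=edv,
        esv=float(esv),
        esp=float(esp),
        edp=float(edp),
        ed_state=ed_state,
        es_state=es_state,
        ejected=ejected,
    )
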