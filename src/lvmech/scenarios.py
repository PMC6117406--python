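"""The six transmural-contractility scenarios.

All six beats share geometry, passive parameters, activation timing and
afterload; only the per-region T_max assignments differ:

1. uniform baseline (normal);
2. subendocardium silenced (T_max = 0 in layers 1-3) — the HFrEF-like
   insult;
3. as 2, with subepicardial T_max recalibrated to restore the baseline
   ESV — the HFpEF compensation hypothesis;
4. all layers at half baseline;
5. only the subendocardium active;
6. subepicardium silenced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import MID, SUBENDO, SUBEPI
from .fe import FEModel, SimState, SolverError
from .fibers import FiberField
from .hemodynamics import AfterloadParams, BeatResult, run_beat
from .postprocess import ScenarioMetrics, compute_metrics

__all__ = ["ScenarioSpec", "scenario_table", "run_all_scenarios"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario design: per-region T_max in MPa."""

    id: int
    t_max_subendo: float
    t_max_mid: float
    t_max_subepi: float

    @property
    def by_region(self) -> dict[int, float]:
        return {SUBENDO: self.t_max_subendo, MID: self.t_max_mid, SUBEPI: self.t_max_subepi}

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.t_max_subendo, self.t_max_mid, self.t_max_subepi)


def scenario_table(baseline_tmax: float, calibrated_subepi: float) -> list[ScenarioSpec]:
    """Resolve the six scenario T_max assignments to numbers (MPa)."""
    b, c = baseline_tmax, calibrated_subepi
    return [
        ScenarioSpec(1, b, b, b),
        ScenarioSpec(2, 0.0, b, b),
        ScenarioSpec(3, 0.0, b, c),
        ScenarioSpec(4, b / 2, b / 2, b / 2),
        ScenarioSpec(5, b, 0.0, 0.0),
        ScenarioSpec(6, b, b, 0.0),
    ]


def run_all_scenarios(
    model: FEModel,
    fibers: FiberField,
    afterload: AfterloadParams,
    scenarios: list[ScenarioSpec],
    edv: float,
    *,
    dt: float = 0.005,
    ed_state: SimState | None = None,
    precomputed: dict[int, BeatResult] | None = None,
) -> tuple[dict[int, BeatResult], list[ScenarioMetrics], pd.DataFrame]:
    """One beat per scenario with everything but T_max shared.

    ``precomputed`` may supply beats already produced by the calibration
    stage (scenarios 1 and 3) so they are not re-simulated.  A scenario
    whose solve fails is reported as a NaN row; the remaining scenarios
    still run.
    """
    beats: dict[int, BeatResult] = {}
    metrics: list[ScenarioMetrics] = []
    for spec in scenarios:
        beat = (precomputed or {}).get(spec.id)
        if beat is None:
            model.set_t_max(spec.by_region)
            try:
                beat = run_beat(model, afterload, edv, dt=dt, ed_state=ed_state)
            except SolverError as exc:
                metrics.append(
                    ScenarioMetrics(
                        scenario_id=spec.id,
                        t_max_subendo=spec.t_max_subendo,
                        t_max_mid=spec.t_max_mid,
                        t_max_subepi=spec.t_max_subepi,
                        ef=np.nan, esv=np.nan, esp=np.nan, edp=np.nan,
                        torsion=np.nan, e_l=np.nan, e_c=np.nan, e_r=np.nan,
                        sphericity_es=np.nan, transmural=np.full((8, 3), np.nan),
                    )
                )
                continue
        beats[spec.id] = beat
        # metrics evaluation needs the model to carry this scenario's T_max
        model.set_t_max(spec.by_region)
        metrics.append(compute_metrics(spec.id, spec.triple, beat, model, fibers))
    table = pd.DataFrame([m.as_row() for m in metrics]).set_index("scenario")
    return beats, metrics, table
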