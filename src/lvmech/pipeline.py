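"""Deterministic end-to-end orchestration.

Stages: patient -> ED geometry -> Klotz unloading -> mesh/fibers ->
passive fit (coarse mesh) -> uniform T_max calibration (optionally with
one frozen afterload-resistance adjustment toward a target end-systolic
pressure) -> subepicardial T_max recalibration -> six scenario beats ->
metrics table and CSV/VTK outputs.  A config hash is recorded in every
output; identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    FitReport,
    KlotzCurve,
    calibrate_tmax_subepi,
    calibrate_tmax_uniform,
    fit_passive_params,
)
from .fe import FEModel
from .fibers import FiberField, assign_fibers
from .geometry import LVMesh, build_ed_surfaces, klotz_unloaded_volume, mesh_lv, scale_to_unloaded
from .hemodynamics import AfterloadParams, BeatResult, inflate_to_volume
from .materials import ActiveParams, MaterialParams, paper_table1
from .patients import PatientMeasurements, paper_patient, sample_patient
from .postprocess import ScenarioMetrics
from .scenarios import ScenarioSpec, run_all_scenarios, scenario_table
from .vtkio import write_vtk

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run configuration (units: cm, ml, mmHg, MPa, s)."""

    patient_source: str = "paper"        # "paper" or "sample"
    seed: int = 0                        # used when patient_source == "sample"
    truncation_fraction: float = 0.5
    fit_mesh: tuple[int, int] = (8, 6)   # (n_circ, n_long) for the passive fit
    run_mesh: tuple[int, int] = (12, 8)  # (n_circ, n_long) for scenario beats
    endo_helix_deg: float = 60.0
    epi_helix_deg: float = -60.0
    bulk_modulus_mpa: float = 1.0
    klotz_an: float = 28.2
    klotz_bn: float = 2.79
    active: dict = field(
        default_factory=lambda: {
            "ca0": 4.35, "ca0_max": 4.35, "b_len": 4.75, "l0": 1.58,
            "lR": 1.95, "m_relax": 1.0489, "b_relax": -1.429, "t0": 0.2,
        }
    )
    afterload: dict = field(
        default_factory=lambda: {
            "aortic_opening_pressure": 80.0,
            "arterial_resistance": 0.55,
            "arterial_compliance": 0.30,
        }
    )
    calibrate_afterload: bool = False
    target_esp_mmhg: float = 88.9
    dt_s: float = 0.0075
    fit_maxiter: int = 10
    esv_tolerance_ml: float = 0.2
    scenario_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    write_vtk_fields: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        d["version"] = __version__
        return json.dumps(d, sort_keys=True, default=list)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    patient: PatientMeasurements
    klotz: KlotzCurve
    mesh: LVMesh
    fibers: FiberField
    material: MaterialParams
    fit_report: FitReport
    afterload: AfterloadParams
    baseline_tmax: float
    subepi_tmax: float
    scenarios: list[ScenarioSpec]
    beats: dict[int, BeatResult]
    metrics: list[ScenarioMetrics]
    table: pd.DataFrame


def _stage(log, name):
    if log:
        log(name)


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
    log=None,
) -> PipelineResult:
    """Run the whole study workflow; optionally write outputs to ``outdir``."""
    _stage(log, "patient")
    if config.patient_source == "paper":
        patient = paper_patient()
    elif config.patient_source == "sample":
        patient = sample_patient(config.seed)
    else:
        raise ValueError(f"unknown patient source {config.patient_source!r}")

    _stage(log, "geometry")
    geom_ed = build_ed_surfaces(patient, truncation_fraction=config.truncation_fraction)
    v0 = klotz_unloaded_volume(patient.edv, patient.edp)
    geom0 = scale_to_unloaded(geom_ed, v0)
    klotz = KlotzCurve.from_measurement(
        patient.edv, patient.edp, an=config.klotz_an, bn=config.klotz_bn
    )

    _stage(log, "passive fit")
    active = ActiveParams(t_max=0.0, **config.active)
    init = paper_table1(bulk_modulus=config.bulk_modulus_mpa)
    fit_mesh = mesh_lv(geom0, *config.fit_mesh)
    fit_fibers = assign_fibers(fit_mesh, config.endo_helix_deg, config.epi_helix_deg)
    fit_model = FEModel.from_mesh(fit_mesh, fit_fibers, init, active=active)
    material, fit_report = fit_passive_params(
        fit_model, klotz, init, maxiter=config.fit_maxiter
    )

    _stage(log, "scenario mesh")
    mesh = mesh_lv(geom0, *config.run_mesh)
    fibers = assign_fibers(mesh, config.endo_helix_deg, config.epi_helix_deg)
    model = FEModel.from_mesh(mesh, fibers, material, active=active)
    ed_state = inflate_to_volume(model, patient.edv)

    _stage(log, "baseline T_max calibration")
    afterload = AfterloadParams(**config.afterload)
    baseline_tmax, beat1 = calibrate_tmax_uniform(
        model, afterload, patient.esv, patient.edv,
        dt=config.dt_s, ed_state=ed_state, tol_ml=config.esv_tolerance_ml,
    )
    if config.calibrate_afterload:
        # one frozen resistance adjustment toward the baseline ESP, then
        # recalibrate T_max under the final afterload
        _stage(log, "afterload adjustment")
        factor = float(np.clip(config.target_esp_mmhg / beat1.esp, 1.0 / 3.0, 3.0))
        afterload = dataclasses.replace(
            afterload, arterial_resistance=afterload.arterial_resistance * factor
        )
        baseline_tmax, beat1 = calibrate_tmax_uniform(
            model, afterload, patient.esv, patient.edv,
            dt=config.dt_s, ed_state=ed_state, tol_ml=config.esv_tolerance_ml,
            guesses=(baseline_tmax, 1.15 * baseline_tmax),
        )

    _stage(log, "subepicardial T_max calibration")
    subepi_tmax, beat3 = calibrate_tmax_subepi(
        model, afterload, baseline_tmax, patient.esv, patient.edv,
        dt=config.dt_s, ed_state=ed_state, tol_ml=config.esv_tolerance_ml,
        strict=False,
    )

    _stage(log, "scenarios")
    specs = [
        s for s in scenario_table(baseline_tmax, subepi_tmax) if s.id in config.scenario_ids
    ]
    beats, metrics, table = run_all_scenarios(
        model, fibers, afterload, specs, patient.edv,
        dt=config.dt_s, ed_state=ed_state, precomputed={1: beat1, 3: beat3},
    )

    result = PipelineResult(
        config=config, patient=patient, klotz=klotz, mesh=mesh, fibers=fibers,
        material=material, fit_report=fit_report, afterload=afterload,
        baseline_tmax=baseline_tmax, subepi_tmax=subepi_tmax,
        scenarios=specs, beats=beats, metrics=metrics, table=table,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    """CSV/JSON/VTK output bundle, stamped with the config hash."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    (outdir / "config.json").write_text(cfg.to_json() + "\n")
    table = result.table.copy()
    table.insert(0, "config_hash", cfg.hash)
    table.to_csv(outdir / "metrics.csv", float_format="%.6g")
    for sid, beat in result.beats.items():
        pv = pd.DataFrame(
            {"time_s": beat.times, "pressure_mmhg": beat.pressures, "volume_ml": beat.volumes}
        )
        pv.to_csv(outdir / f"pv_scenario{sid}.csv", index=False, float_format="%.8g")
    for m in result.metrics:
        prof = pd.DataFrame(
            m.transmural, columns=["depth", "fiber_strain", "fiber_stress_mpa"]
        )
        prof.to_csv(outdir / f"transmural_scenario{m.scenario_id}.csv", index=False,
                    float_format="%.6g")
    fit = result.fit_report
    (outdir / "fit_report.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.hash,
                "params_mpa_or_dimensionless": dataclasses.asdict(fit.params),
                "rms_volume_error_ml": fit.rms_volume_error,
                "volume_at_edp_ml": fit.volume_at_edp,
                "n_evaluations": fit.n_evaluations,
                "n_iterations": fit.n_iterations,
                "success": fit.success,
                "message": fit.message,
                "baseline_tmax_mpa": result.baseline_tmax,
                "subepi_tmax_mpa": result.subepi_tmax,
                "afterload": dataclasses.asdict(result.afterload),
            },
            indent=2,
        )
        + "\n"
    )
    if cfg.write_vtk_fields:
        cell = {
            "layer": result.mesh.layer_index.astype(float),
            "region": result.mesh.region.astype(float),
            "fiber": result.fibers.f0,
            "sheet": result.fibers.s0,
        }
        write_vtk(outdir / "mesh.vtk", result.mesh, cell_data=cell)
        for sid, beat in result.beats.items():
            write_vtk(
                outdir / f"es_scenario{sid}.vtk",
                result.mesh,
                displacement=beat.es_state.u,
                cell_data=cell,
            )
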