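"""Echo-style patient measurements.

The pipeline is single-subject: a handful of echocardiographic scalars
(EDV, an E/e' ratio from which EDP is estimated, ESV, the LV internal
diameter and wall thicknesses at end diastole) seed the idealized geometry
and the contractility calibration.  A fixed reference subject reproduces
the measurements the study model was built from; ``sample_patient`` draws
plausible normal subjects so every downstream stage can be exercised
without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PatientMeasurements",
    "estimate_edp_nagueh",
    "paper_patient",
    "sample_patient",
]


@dataclass(frozen=True)
class PatientMeasurements:
    """Echocardiography-derived scalars for one subject.

    Volumes in ml, pressures in mmHg, lengths in cm.  ``e_over_eprime`` is
    the dimensionless ratio of early mitral inflow velocity to early
    diastolic annular velocity used to estimate filling pressure.
    """

    edv: float
    e_over_eprime: float
    edp: float
    esv: float
    lv_internal_diameter_ed: float
    posterior_wall_thickness_ed: float
    septal_wall_thickness_ed: float

    def __post_init__(self) -> None:
        if not (self.edv > self.esv > 0):
            raise ValueError(f"require edv > esv > 0, got edv={self.edv}, esv={self.esv}")
        if self.edp <= 0:
            raise ValueError(f"edp must be positive, got {self.edp}")
        if self.lv_internal_diameter_ed <= 0:
            raise ValueError("lv_internal_diameter_ed must be positive")
        if self.posterior_wall_thickness_ed <= 0 or self.septal_wall_thickness_ed <= 0:
            raise ValueError("wall thicknesses must be positive")

    @property
    def mean_wall_thickness_ed(self) -> float:
        return 0.5 * (self.posterior_wall_thickness_ed + self.septal_wall_thickness_ed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PatientMeasurements":
        return cls(**json.loads(Path(path).read_text()))


def estimate_edp_nagueh(e_over_eprime: float) -> float:
    """Estimate LV end-diastolic pressure (mmHg) from E/e'.

    Linear estimator of mean filling pressure from the tissue-Doppler
    literature, ``P = 1.9 + 1.24 * (E/e')``, treated here as the EDP.
    """
    if e_over_eprime <= 0:
        raise ValueError(f"E/e' must be positive, got {e_over_eprime}")
    return 1.9 + 1.24 * e_over_eprime


#: reference-subject constants (normal adult); diameter/thicknesses are
#: textbook normal values, config-exposed via build_ed_surfaces callers.
_REFERENCE = dict(
    edv=53.0,
    e_over_eprime=10.0,
    edp=14.3,
    esv=24.8,
    lv_internal_diameter_ed=4.6,
    posterior_wall_thickness_ed=0.9,
    septal_wall_thickness_ed=0.9,
)


def paper_patient() -> PatientMeasurements:
    """The fixed reference subject: EDV 53 ml, EDP 14.3 mmHg, ESV 24.8 ml."""
    return PatientMeasurements(**_REFERENCE)


def sample_patient(seed: int) -> PatientMeasurements:
    """Draw one plausible normal subject (deterministic per seed).

    Distributions: EDV ~ N(53, 8) ml, E/e' ~ N(8, 2), ESV/EDV ~ N(0.47,
    0.04), LVIDd ~ N(4.6, 0.3) cm, wall thicknesses ~ N(0.9, 0.1) cm; all
    truncated to physiological bounds so the record invariants hold by
    construction.  EDP is derived from E/e' via ``estimate_edp_nagueh``.
    """
    rng = np.random.default_rng(seed)

    def trunc_normal(mean: float, sd: float, lo: float, hi: float) -> float:
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo < x < hi:
                return float(x)
        return float(np.clip(mean, lo, hi))

    edv = trunc_normal(53.0, 8.0, 30.0, 90.0)
    e_over_eprime = trunc_normal(8.0, 2.0, 3.0, 14.0)
    esv_frac = trunc_normal(0.47, 0.04, 0.30, 0.65)
    lvidd = trunc_normal(4.6, 0.3, 3.5, 6.0)
    pwt = trunc_normal(0.9, 0.1, 0.6, 1.3)
    swt = trunc_normal(0.9, 0.1, 0.6, 1.3)
    return PatientMeasurements(
        edv=edv,
        e_over_eprime=e_over_eprime,
        edp=estimate_edp_nagueh(e_over_eprime),
        esv=esv_frac * edv,
        lv_internal_diameter_ed=lvidd,
        posterior_wall_thickness_ed=pwt,
        septal_wall_thickness_ed=swt,
    )
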