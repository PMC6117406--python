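"""Unit conventions and conversion constants.

External interfaces use clinical units (cm, ml, mmHg, s); all stress-like
quantities inside the solver are MPa and lengths cm, so pressures are
converted exactly once at the solver boundary.  1 ml == 1 cm^3.
"""

#: exact conversion used throughout: 1 mmHg in MPa
MMHG_TO_MPA = 1.33322e-4

#: 1 MPa in mmHg
MPA_TO_MMHG = 1.0 / MMHG_TO_MPA


def mmhg_to_mpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_MPA


def mpa_to_mmhg(p_mpa: float) -> float:
    return p_mpa * MPA_TO_MMHG
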