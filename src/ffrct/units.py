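"""Unit conversions and physical constants.

Clinical units (mmHg, mL/min, mm) appear at every user-facing surface;
all internal computation is SI (Pa, m^3/s, m). Conversions are centralized
here so no other module hard-codes a factor.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
M3_PER_S_TO_ML_PER_MIN = 60.0 / 1e-6

MM_TO_M = 1e-3
M_TO_MM = 1e3


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p * PA_TO_MMHG


def mlmin_to_m3s(q: float) -> float:
    return q * ML_PER_MIN_TO_M3_PER_S


def m3s_to_mlmin(q: float) -> float:
    return q * M3_PER_S_TO_ML_PER_MIN
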