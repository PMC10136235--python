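"""Unit conventions.

All internal physics runs in CGS (cm, g, s, dyn/cm^2); every public
interface speaks clinical units (mmHg, mL, s).  The single conversion
constant lives here so no module hard-codes its own.
"""

#: dyn/cm^2 per mmHg
MMHG = 1333.22

#: default blood density, g/cm^3
RHO_BLOOD = 1.06

#: default blood dynamic viscosity, g/(cm*s)  (= 4 cP)
MU_BLOOD = 0.04


def mmhg_to_cgs(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def cgs_to_mmhg(p_dyn: float) -> float:
    return p_dyn / MMHG
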