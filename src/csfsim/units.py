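"""Unit conventions.

All model quantities are expressed in clinical units: pressure in mmHg,
volumetric flow in ml/s, compliance in ml/mmHg, hydraulic resistance in
mmHg·s/ml, time in s.  SI conversions are only needed by the Poiseuille
and Reynolds helpers, which take geometry in mm and fluid properties in
SI units.
"""

#: Pascal per millimetre of mercury.
PA_PER_MMHG = 133.322

#: Conversion factor from ml/s to ml/min.
ML_S_TO_ML_MIN = 60.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG
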