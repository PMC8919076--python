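"""Unit system and conversions.

The package computes in a (mmHg, mL, s) unit system, the natural one for
lumped cardiovascular models: pressures in mmHg, volumes in mL, flows in
mL/s, resistances in mmHg·s/mL, compliances in mL/mmHg, areas in cm²,
lengths in cm, fiber stress in kPa.  I/O follows clinical convention
(mmHg, mL/min for coronary flows, m/s for velocities, cm² for areas).
"""

from __future__ import annotations

MMHG_TO_PA = 133.322
KPA_TO_MMHG = 1000.0 / MMHG_TO_PA  # 7.5006 mmHg per kPa

#: blood density, kg/m³ (standard value)
RHO_BLOOD = 1050.0
#: blood dynamic viscosity, Pa·s (standard value)
MU_BLOOD = 3.0e-3
#: myocardial tissue density, g/mL
MYOCARDIAL_DENSITY = 1.055

ML_MIN_TO_ML_S = 1.0 / 60.0
ML_S_TO_ML_MIN = 60.0


def wave_speed_m_s(area_cm2: float, dp_da_mmhg_cm2: float) -> float:
    """Linearized tube wave speed c = sqrt((A/ρ)·dp/dA) in m/s.

    ``area_cm2`` is the lumen area (cm²), ``dp_da_mmhg_cm2`` the local
    slope of the transmural pressure–area law (mmHg/cm²).
    """
    a_m2 = area_cm2 * 1e-4
    dpda_si = dp_da_mmhg_cm2 * MMHG_TO_PA / 1e-4  # Pa/m²
    c2 = a_m2 * dpda_si / RHO_BLOOD
    if c2 <= 0.0:
        raise ValueError("non-positive wave speed: tube law slope must be > 0")
    return c2**0.5


def wave_impedance_mmhg_s_ml(area_cm2: float, c_m_s: float) -> float:
    """Characteristic wave impedance Z = ρ·c/A in mmHg·s/mL."""
    z_si = RHO_BLOOD * c_m_s / (area_cm2 * 1e-4)  # Pa·s/m³
    return z_si / (MMHG_TO_PA * 1e6)


def velocity_m_s(flow_ml_s, area_cm2):
    """Cross-section mean velocity q/A in m/s."""
    return (flow_ml_s * 1e-6) / (area_cm2 * 1e-4)


def impedance_from_slope(area_cm2, slope_mmhg_cm2):
    """Vectorized Z = ρc/A (mmHg·s/mL) from the tube-law slope dp/dA.

    Z = sqrt(ρ · (dp/dA) / A) in SI; inputs in cm² and mmHg/cm².
    """
    import numpy as np

    dpda_si = np.asarray(slope_mmhg_cm2, float) * MMHG_TO_PA / 1e-4
    a_si = np.asarray(area_cm2, float) * 1e-4
    z_si = np.sqrt(RHO_BLOOD * dpda_si / a_si)
    return z_si / (MMHG_TO_PA * 1e6)


def inertance_mmhg_s2_ml(length_cm, area_cm2):
    """Blood inertance L = ρ·l/A in mmHg·s²/mL."""
    l_si = RHO_BLOOD * (length_cm / 100.0) / (area_cm2 * 1e-4)
    return l_si / (MMHG_TO_PA * 1e6)


def bernoulli_coeff_mmhg_s2_ml2(area_cm2):
    """Orifice Bernoulli coefficient B = ρ/(2·A²) in mmHg·s²/mL²."""
    b_si = RHO_BLOOD / (2.0 * (area_cm2 * 1e-4) ** 2)
    return b_si / (MMHG_TO_PA * 1e12)
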