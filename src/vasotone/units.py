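"""Unit conversion constants.

Mechanics works internally in kPa-mm-s, chemistry in nM-mm-s, and the lumped
network in mmHg-mL-s.  All cross-system conversions go through the constants
below so they are defined (and tested) in exactly one place.
"""

#: 1 mmHg in kPa
MMHG_TO_KPA = 0.133322
#: 1 mmHg in Pa
MMHG_TO_PA = 133.322
#: 1 kPa in mmHg
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

#: 1 um^2/s in mm^2/s (diffusion constants are tabulated in um^2/s)
UM2_TO_MM2 = 1.0e-6

#: 1 mm^3 in mL
MM3_TO_ML = 1.0e-3
#: 1 mL in mm^3
ML_TO_MM3 = 1.0e3


def poiseuille_resistance_mmhg_s_per_ml(mu_b_pa_s: float, ell_mm: float,
                                        area_mm2: float) -> float:
    """Poiseuille resistance R = 8*pi*mu*ell/A^2 in mmHg*s/mL.

    Parameters are dynamic viscosity in Pa*s, segment length in mm and lumen
    area in mm^2.  Identical to the classical 8*mu*ell/(pi*r^4).
    """
    r_pa_s_per_mm3 = 8.0 * 3.141592653589793 * mu_b_pa_s * ell_mm / area_mm2 ** 2
    # Pa*s/mm^3 -> mmHg*s/mL:  /MMHG_TO_PA * ML_TO_MM3
    return r_pa_s_per_mm3 / MMHG_TO_PA * ML_TO_MM3


def compliance_ml_per_mmhg(ell_mm: float, dA_dp_mm2_per_mmhg: float) -> float:
    """Segment compliance C = ell * dA/dp in mL/mmHg."""
    return ell_mm * dA_dp_mm2_per_mmhg * MM3_TO_ML


def wall_shear_pa(mu_b_pa_s: float, q_ml_s: float, r_mm: float) -> float:
    """Poiseuille wall shear stress tau = 4*mu*q/(pi*r^3) in Pa."""
    q_mm3_s = q_ml_s * ML_TO_MM3
    return 4.0 * mu_b_pa_s * q_mm3_s / (3.141592653589793 * r_mm ** 3)
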