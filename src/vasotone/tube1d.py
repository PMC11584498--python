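"""Semi-analytic inflation of an incompressible thick-walled tube.

Axisymmetric verification oracle for the plane FE solver: for a
region-wise homogeneous wall with uniform inelastic state, exact
incompressibility (J = 1) at fixed axial stretch gives the kinematics

    r(R) = sqrt(r_i^2 + (R^2 - R_i^2) / lambda_z),

and radial equilibrium reduces to the quadrature

    p_i = int_{R_i}^{R_o} (sigma_theta - sigma_r) / r  dr/dR  dR,

with sigma_theta - sigma_r = lambda_theta * dPsi/dlambda_theta evaluated
on the incompressibility manifold lambda_r = 1/(lambda_theta lambda_z).
The energy derivative is taken numerically so the oracle stays independent
of the FE stress implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import units
from .geometry import CrossSectionGeometry
from .mechanics import WallMaterials, smc_energy


def _deviatoric_energy(lam_th, lam_z, materials: WallMaterials,
                       lambda_a, lambda_cs, with_smc: bool):
    """Energy density (kPa) of the incompressible composite at given stretches."""
    ecm = materials.ecm
    lam_r = 1.0 / (lam_th * lam_z)
    I1 = lam_th ** 2 + lam_r ** 2 + lam_z ** 2
    psi = 0.5 * ecm.mu * (I1 - 3.0)
    phi = np.deg2rad(ecm.phi_c_deg)
    I4 = np.cos(phi) ** 2 * lam_th ** 2 + np.sin(phi) ** 2 * lam_z ** 2
    x = np.maximum(I4 / lambda_cs ** 2 - 1.0, 0.0)
    psi = psi + 2.0 * ecm.k1 / (2.0 * ecm.k2) * np.expm1(ecm.k2 * x ** 2)
    if with_smc:
        psi = psi + smc_energy(lam_th / lambda_a, materials.smc)
    return psi


def _hoop_minus_radial(lam_th, lam_z, materials, lambda_a, lambda_cs, with_smc,
                       h=1e-6):
    f = lambda l: _deviatoric_energy(l, lam_z, materials, lambda_a,
                                     lambda_cs, with_smc)
    dpsi = (f(lam_th + h) - f(lam_th - h)) / (2.0 * h)
    return lam_th * dpsi


def _pressure_for_inner_radius(r_i, geom: CrossSectionGeometry,
                               materials: WallMaterials,
                               lambda_a, lambda_cs, n_quad):
    lz = geom.lambda_z
    total = 0.0
    for (Ra, Rb, with_smc) in ((geom.R_i0, geom.R_m, True),
                               (geom.R_m, geom.R_o, False)):
        xg, wg = np.polynomial.legendre.leggauss(n_quad)
        R = 0.5 * (Rb - Ra) * xg + 0.5 * (Ra + Rb)
        w = 0.5 * (Rb - Ra) * wg
        r = np.sqrt(r_i ** 2 + (R ** 2 - geom.R_i0 ** 2) / lz)
        lam_th = r / R
        la = lambda_a if with_smc else 1.0
        lc = lambda_cs if with_smc else 1.0
        integrand = _hoop_minus_radial(lam_th, lz, materials, la, lc, with_smc)
        # dr/dR = R / (lambda_z r)
        total += float(np.sum(w * integrand / r * R / (lz * r)))
    return total  # kPa


def oracle_tube_1d(geom: CrossSectionGeometry,
                   materials: WallMaterials | None = None,
                   lambda_a: float = 1.0, lambda_cs: float = 1.0,
                   p_lumen: float = 0.0, n_quad: int = 200) -> float:
    """Deformed inner radius (mm) of the homogeneous axisymmetric tube.

    ``p_lumen`` in mmHg.  Solves the scalar equilibrium equation for r_i by
    bracketing + Brent; quadrature with ``n_quad`` Gauss points per layer.
    """
    materials = materials or WallMaterials()
    p_kpa = p_lumen * units.MMHG_TO_KPA

    def f(r_i):
        return _pressure_for_inner_radius(r_i, geom, materials,
                                          lambda_a, lambda_cs, n_quad) - p_kpa

    lo, hi = 0.2 * geom.R_i0, 3.0 * geom.R_i0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError("failed to bracket the inflation equilibrium")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
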