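"""Arterial wall mechanics: constitutive models and FE equilibrium solver.

The wall is a fiber-reinforced hyperelastic composite under generalized
plane strain (fixed axial pre-stretch ``lambda_z``, deformation confined to
the cross-sectional plane):

* extracellular matrix (both layers): incompressible Neo-Hookean elastin
  plus two exponential collagen fiber families at +-phi_c from the
  circumferential direction.  Collagen carries an inelastic straightening
  stretch ``lambda_cs`` (multiplicative split) so that its elastic fiber
  invariant is I4e = I4 / lambda_cs**2; compressed fibers store no energy.
* smooth muscle (healthy media only): active-strain formulation.  The
  total deformation splits as F = F_e F_a with F_a an incompressible
  uniaxial contraction of magnitude ``lambda_a`` along the circumferential
  direction; the elastic SMC stretch is lambda_e = lambda_theta / lambda_a
  and the scalar first Piola-Kirchhoff stress follows a sigmoid
  P = P_max tanh(C_smc (lambda_e - 1) / P_max).
* calcified sub-region: three-term Yeoh solid replacing the composite.

Quasi-incompressibility is enforced with an element-constant pressure-like
multiplier (the "five-noded" Q1/P0 element): the multiplier is condensed
statically, giving the mean-dilatation form p_e = kappa (Jbar_e - 1).

The lumen pressure acts as a follower load on the deformed intima.
Internally kPa-mm; lumen pressures are given in mmHg and converted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .geometry import ADVENTITIA, CALCIFIED, MEDIA, Mesh, polygon_area

__all__ = [
    "ECMParams", "SMCParams", "CalcifiedParams", "WallMaterials",
    "InelasticState", "MechanicalSolution", "KinematicsError",
    "ConvergenceError", "ecm_energy_and_stress", "smc_stress",
    "active_elastic_split", "calcified_energy_and_stress",
    "FEModel", "solve_equilibrium", "compute_lumen_area",
]


class KinematicsError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ECMParams:
    """Elastin + collagen parameters (kPa where dimensional)."""
    mu: float = 10.0
    k1: float = 10.0
    k2: float = 2.5
    phi_c_deg: float = 45.0
    kappa: float = 1.0e5  # 100 MPa in kPa

    def __post_init__(self):
        if min(self.mu, self.k1, self.k2, self.kappa) <= 0:
            raise ValueError("ECM parameters must be positive")


@dataclass(frozen=True)
class SMCParams:
    C_smc: float = 100.0
    P_smc_max: float = 100.0

    def __post_init__(self):
        if self.C_smc <= 0 or self.P_smc_max <= 0:
            raise ValueError("SMC parameters must be positive")


@dataclass(frozen=True)
class CalcifiedParams:
    """Three-term Yeoh coefficients (kPa)."""
    c1: float = 302.0
    c2: float = -228.0
    c3: float = 261.0
    kappa: float = 1.0e5


@dataclass(frozen=True)
class WallMaterials:
    ecm: ECMParams = field(default_factory=ECMParams)
    smc: SMCParams = field(default_factory=SMCParams)
    calcified: CalcifiedParams = field(default_factory=CalcifiedParams)


@dataclass
class InelasticState:
    """Per-element inelastic stretches (meaningful in healthy media only)."""
    lambda_a: np.ndarray
    lambda_cs: np.ndarray

    @classmethod
    def uniform(cls, mesh: Mesh, lambda_a: float = 1.0, lambda_cs: float = 1.0):
        la = np.full(mesh.n_elements, float(lambda_a))
        lc = np.full(mesh.n_elements, float(lambda_cs))
        # only the healthy media is chemo-active
        inactive = mesh.region != MEDIA
        la[inactive] = 1.0
        lc[inactive] = 1.0
        return cls(lambda_a=la, lambda_cs=lc)


@dataclass
class MechanicalSolution:
    """Converged FE state at a single lumen pressure."""
    u: np.ndarray                 # (n_nodes, 2) displacements (mm)
    p_elem: np.ndarray            # (n_el,) pressure multiplier (kPa)
    Jbar: np.ndarray              # (n_el,) element-mean volume change
    A_s: float                    # deformed lumen area (mm^2)
    p_lumen_mmhg: float
    sigma: np.ndarray             # (n_el, 3, 3) element-mean Cauchy stress (kPa)
    lambda_theta: np.ndarray      # (n_el,) circumferential stretch
    J_gp: np.ndarray              # (n_el, 4) volume change at Gauss points
    Cinv2d_elem: np.ndarray       # (n_el, 2, 2) element-mean in-plane inv(C)
    residual_norm: float
    newton_iters: int

    @property
    def r_s_i(self) -> float:
        """Mean internal radius (A/pi)^(1/2) (mm)."""
        return float(np.sqrt(self.A_s / np.pi))

    def von_mises(self) -> np.ndarray:
        s = self.sigma
        dev = s - np.trace(s, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
        return np.sqrt(1.5 * np.einsum('eij,eij->e', dev, dev))


# ---------------------------------------------------------------------------
# pointwise constitutive operations (reference implementations; also used by
# the test-suite oracles)
# ---------------------------------------------------------------------------

def _check_spd(C: np.ndarray):
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T):
        raise KinematicsError("C must be a symmetric 3x3 tensor")
    if np.any(np.linalg.eigvalsh(C) <= 0):
        raise KinematicsError("C must be positive definite")
    return C


def _fiber_directions(phi_deg: float, e_theta: np.ndarray, e_z: np.ndarray):
    phi = np.deg2rad(phi_deg)
    a1 = np.cos(phi) * e_theta + np.sin(phi) * e_z
    a2 = np.cos(phi) * e_theta - np.sin(phi) * e_z
    return a1, a2


def ecm_energy_and_stress(C: np.ndarray, params: ECMParams,
                          lambda_cs: float = 1.0,
                          fiber_frame=None):
    """Deviatoric ECM energy (kPa) and Cauchy stress contribution.

    ``fiber_frame`` is a pair (e_theta, e_z) of orthonormal material
    directions; defaults to the y/z axes.  The Cauchy push-forward uses the
    rotation-free deformation F = C^(1/2), which is exact for the
    stretch-only states exercised in verification.
    """
    C = _check_spd(C)
    if lambda_cs <= 0:
        raise KinematicsError("lambda_cs must be positive")
    e_theta, e_z = fiber_frame if fiber_frame is not None else (
        np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    J = np.sqrt(np.linalg.det(C))
    I1b = J ** (-2.0 / 3.0) * np.trace(C)
    energy = 0.5 * params.mu * (I1b - 3.0)

    w, V = np.linalg.eigh(C)
    F = (V * np.sqrt(w)) @ V.T  # symmetric square root
    b = F @ F.T
    sigma = params.mu / J * (J ** (-2.0 / 3.0)) * (b - I1b / 3.0 * np.eye(3))

    for a in _fiber_directions(params.phi_c_deg, e_theta, e_z):
        I4 = a @ C @ a
        I4e = I4 / lambda_cs ** 2
        x = max(I4e - 1.0, 0.0)
        energy += params.k1 / (2.0 * params.k2) * np.expm1(params.k2 * x ** 2)
        dpsi = params.k1 * x * np.exp(params.k2 * x ** 2)
        fa = F @ a
        sigma += 2.0 * dpsi / (J * lambda_cs ** 2) * np.outer(fa, fa)
    return float(energy), sigma


def smc_stress(lambda_e: float, params: SMCParams) -> float:
    """Scalar first Piola-Kirchhoff SMC stress, P = P_max tanh(C (l-1)/P_max).

    Equivalently P_max (2 sigma(x) - 1) with x = 2 C_smc (lambda_e - 1)/P_max
    and sigma the logistic function; bounded in (-P_max, P_max) with slope
    C_smc at lambda_e = 1.
    """
    if np.any(np.asarray(lambda_e) <= 0):
        raise KinematicsError("lambda_e must be positive")
    x = params.C_smc * (np.asarray(lambda_e, dtype=float) - 1.0) / params.P_smc_max
    return params.P_smc_max * np.tanh(x)


def smc_energy(lambda_e: float, params: SMCParams) -> float:
    """SMC strain energy density (kPa), antiderivative of :func:`smc_stress`."""
    P, C = params.P_smc_max, params.C_smc
    x = 2.0 * C * (np.asarray(lambda_e, dtype=float) - 1.0) / P
    return P / C * (P * np.logaddexp(0.0, x) - C * np.asarray(lambda_e, dtype=float))


def active_elastic_split(F: np.ndarray, lambda_a: float,
                         e_theta: np.ndarray | None = None):
    """Multiplicative active-strain split F = F_e F_a.

    Returns (F_e, lambda_smc_e) with F_a the incompressible uniaxial active
    deformation of magnitude lambda_a along e_theta.
    """
    if lambda_a <= 0:
        raise KinematicsError("lambda_a must be positive")
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    if e_theta is None:
        e_theta = np.zeros(n)
        e_theta[min(1, n - 1)] = 1.0
    M = np.outer(e_theta, e_theta)
    Fa_inv = (1.0 / lambda_a) * M + np.sqrt(lambda_a) * (np.eye(n) - M)
    Fe = F @ Fa_inv
    Ce = Fe.T @ Fe
    lam_e = float(np.sqrt(np.trace(Ce @ M)))
    return Fe, lam_e


def calcified_energy_and_stress(C: np.ndarray, params: CalcifiedParams):
    """Deviatoric Yeoh energy (kPa) and Cauchy stress contribution."""
    C = _check_spd(C)
    J = np.sqrt(np.linalg.det(C))
    I1b = J ** (-2.0 / 3.0) * np.trace(C)
    s = I1b - 3.0
    energy = params.c1 * s + params.c2 * s ** 2 + params.c3 * s ** 3
    dpsi = params.c1 + 2.0 * params.c2 * s + 3.0 * params.c3 * s ** 2
    w, V = np.linalg.eigh(C)
    F = (V * np.sqrt(w)) @ V.T
    b = F @ F.T
    sigma = 2.0 * dpsi / J * (J ** (-2.0 / 3.0)) * (b - I1b / 3.0 * np.eye(3))
    return float(energy), sigma


# ---------------------------------------------------------------------------
# vectorized FE solver
# ---------------------------------------------------------------------------

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_NODES_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _shape_gradients(xi, eta):
    """dN/dxi for the 4 bilinear shape functions at one quadrature point."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


def _shape_values(xi, eta):
    return 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                            (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])


class FEModel:
    """Precomputed FE operators for one mesh + material set.

    The model is reusable across pressure levels and inelastic states; a
    pressure sweep therefore pays the quadrature set-up cost once.
    """

    def __init__(self, mesh: Mesh, materials: WallMaterials | None = None,
                 lambda_z: float | None = None):
        self.mesh = mesh
        self.materials = materials or WallMaterials()
        self.lambda_z = float(lambda_z if lambda_z is not None else mesh.geom.lambda_z)
        self._precompute()

    def _precompute(self):
        mesh, m = self.mesh, self.materials
        Xe = mesh.nodes[mesh.elems]                       # (n_el, 4, 2)
        n_el = mesh.n_elements
        dN = np.empty((n_el, 4, 4, 2))                     # (el, gp, node, dim)
        wdet = np.empty((n_el, 4))
        eth = np.empty((n_el, 4, 2))
        Nval = np.empty((4, 4))                            # (gp, node)
        for g, (xi, eta) in enumerate(_GP):
            dNxi = _shape_gradients(xi, eta)               # (4, 2)
            Nval[g] = _shape_values(xi, eta)
            J0 = np.einsum('ean,am->enm', Xe, dNxi)        # dX/dxi, wait order
            # J0[i,j] = sum_a X[a,i] dNxi[a,j]
            J0 = np.einsum('eai,aj->eij', Xe, dNxi)
            det = J0[:, 0, 0] * J0[:, 1, 1] - J0[:, 0, 1] * J0[:, 1, 0]
            inv = np.empty_like(J0)
            inv[:, 0, 0] = J0[:, 1, 1] / det
            inv[:, 0, 1] = -J0[:, 0, 1] / det
            inv[:, 1, 0] = -J0[:, 1, 0] / det
            inv[:, 1, 1] = J0[:, 0, 0] / det
            dN[:, g] = np.einsum('aj,eji->eai', dNxi, inv)
            wdet[:, g] = det                               # unit GP weights
            xgp = np.einsum('a,eai->ei', Nval[g], Xe)
            ang = np.arctan2(xgp[:, 1], xgp[:, 0])
            eth[:, g, 0] = -np.sin(ang)
            eth[:, g, 1] = np.cos(ang)
        if np.any(wdet <= 0):
            raise KinematicsError("non-positive Jacobian in reference mesh")
        self._dN, self._wdet, self._eth = dN, wdet, eth
        self._V0 = wdet.sum(axis=1)
        reg = mesh.region
        self._healthy = reg != CALCIFIED
        self._media = reg == MEDIA
        self._calc = reg == CALCIFIED
        self._mu_e = np.where(self._healthy, m.ecm.mu, 0.0)
        self._k1_e = np.where(self._healthy, m.ecm.k1, 0.0)
        self._smc_e = np.where(self._media, 1.0, 0.0)
        # Calcified deposits form in vivo: their stress-free reference is
        # the isochoric axially-accommodated state diag(lz^-1/2, lz^-1/2, lz),
        # so their elastic volume change equals the global J while their
        # first invariant reads I1_c = lz*||F2d||^2 + 1.
        phi = np.deg2rad(m.ecm.phi_c_deg)
        self._cos2phi = np.cos(phi) ** 2
        self._sin2phi = np.sin(phi) ** 2
        self._kappa = m.ecm.kappa

        # assembly indices: element dofs ordered (n0x, n0y, n1x, n1y, ...)
        edof = np.empty((n_el, 8), dtype=np.int64)
        edof[:, 0::2] = 2 * mesh.elems
        edof[:, 1::2] = 2 * mesh.elems + 1
        self._edof = edof
        self._Krows = np.repeat(edof, 8, axis=1).ravel()
        self._Kcols = np.tile(edof, (1, 8)).ravel()

        # follower-load edges (inner boundary)
        self._inner = mesh.inner_edges
        ldof = np.empty((len(self._inner), 4), dtype=np.int64)
        ldof[:, 0::2] = 2 * self._inner
        ldof[:, 1::2] = 2 * self._inner + 1
        self._ldof = ldof
        self._Lrows = np.repeat(ldof, 4, axis=1).ravel()
        self._Lcols = np.tile(ldof, (1, 4)).ravel()

        self.ndof = 2 * mesh.n_nodes
        self._setup_rigid_body_constraints()

    def _setup_rigid_body_constraints(self):
        """Global mean-translation/rotation constraints (Lagrange rows).

        Pinning individual nodes couples the constraint to the ring's tiny
        bending stiffness and leaves the tangent near-singular for
        non-axisymmetric loads; the three global constraints
        sum(u_x) = sum(u_y) = sum(X x u) = 0 remove exactly the rigid modes
        and nothing else.
        """
        n = self.mesh.n_nodes
        X = self.mesh.nodes
        C = np.zeros((3, self.ndof))
        C[0, 0::2] = 1.0
        C[1, 1::2] = 1.0
        C[2, 0::2] = -X[:, 1]
        C[2, 1::2] = X[:, 0]
        C /= np.linalg.norm(C, axis=1, keepdims=True)
        self._C = sp.csr_matrix(C)
        # orthonormal basis of the rigid space for residual projection
        Q, _ = np.linalg.qr(C.T)
        self._rigidQ = Q

    def _deformational_norm(self, r):
        """Residual norm with rigid-body force components projected out."""
        r_def = r - self._rigidQ @ (self._rigidQ.T @ r)
        return np.linalg.norm(r_def)

    def _constrained_solve(self, K, r, u, beta=0.0):
        """Solve the bordered system [[K + beta I, C^T], [C, 0]]."""
        Kb = K + beta * sp.identity(self.ndof) if beta else K
        A = sp.bmat([[Kb, self._C.T], [self._C, None]], format='csc')
        rhs = np.concatenate([-r, -(self._C @ u)])
        sol = spla.spsolve(A, rhs)
        return sol[:self.ndof]

    # -- element internal forces (complex-step capable) --------------------

    def _element_forces(self, u_e, lam_a, lam_cs):
        dN, wdet, eth = self._dN, self._wdet, self._eth
        lz = self.lambda_z
        eye = np.eye(2)
        F = eye + np.einsum('eai,egaj->egij', u_e, dN)
        det2 = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(np.real(det2) <= 0.0):
            raise ConvergenceError("inverted element during Newton iteration")
        J3 = det2 * lz
        FinvT = np.empty_like(F)
        FinvT[..., 0, 0] = F[..., 1, 1]
        FinvT[..., 0, 1] = -F[..., 1, 0]
        FinvT[..., 1, 0] = -F[..., 0, 1]
        FinvT[..., 1, 1] = F[..., 0, 0]
        FinvT = FinvT / det2[..., None, None]
        nF2 = (F * F).sum(axis=(-2, -1))
        I1 = nF2 + lz ** 2
        Jm23 = J3 ** (-2.0 / 3.0)
        t = np.einsum('egij,egj->egi', F, eth)
        ctt = (t * t).sum(-1)

        Jbar = (wdet * J3).sum(axis=1) / self._V0
        p_e = self._kappa * (Jbar - 1.0)

        devF = F - (I1 / 3.0)[..., None, None] * FinvT
        P = (self._mu_e[:, None] * Jm23)[..., None, None] * devF

        I4 = self._cos2phi * ctt + self._sin2phi * lz ** 2
        lcs2 = (lam_cs ** 2)[:, None]
        I4e = I4 / lcs2
        x = I4e - 1.0
        x = np.where(np.real(x) > 0.0, x, 0.0 * x)
        dpsi = self._k1_e[:, None] * x * np.exp(self.materials.ecm.k2 * x ** 2)
        coef_f = 4.0 * dpsi * self._cos2phi / lcs2
        P = P + coef_f[..., None, None] * np.einsum('egi,egj->egij', t, eth)

        lam_th = np.sqrt(ctt)
        lam_e = lam_th / lam_a[:, None]
        sm = self.materials.smc
        Ps = sm.P_smc_max * np.tanh(sm.C_smc * (lam_e - 1.0) / sm.P_smc_max)
        coef_s = self._smc_e[:, None] * Ps / (lam_a[:, None] * lam_th)
        P = P + coef_s[..., None, None] * np.einsum('egi,egj->egij', t, eth)

        if self._calc.any():
            cp = self.materials.calcified
            I1c = lz * nF2 + 1.0
            s = Jm23 * I1c - 3.0
            dpsi_y = cp.c1 + 2.0 * cp.c2 * s + 3.0 * cp.c3 * s ** 2
            coef_y = np.where(self._calc[:, None], 2.0 * dpsi_y * Jm23, 0.0 * s)
            P = P + coef_y[..., None, None] * (
                lz * F - (I1c / 3.0)[..., None, None] * FinvT)

        P = P + (p_e[:, None] * J3)[..., None, None] * FinvT

        f = np.einsum('eg,egij,egaj->eai', wdet, P, dN)
        return f, p_e, Jbar, J3, F, lam_th

    def _internal_residual(self, u, lam_a, lam_cs):
        u_e = u.reshape(-1, 2)[self.mesh.elems]
        f, p_e, Jbar, J3, F, lam_th = self._element_forces(u_e, lam_a, lam_cs)
        r = np.zeros(self.ndof, dtype=f.dtype)
        np.add.at(r, self._edof.ravel(), f.reshape(-1, 8).ravel())
        return r, p_e, Jbar

    def _element_tangent(self, u, lam_a, lam_cs):
        """Element stiffness by complex-step differentiation (exact)."""
        u_e = u.reshape(-1, 2)[self.mesh.elems].astype(complex)
        n_el = self.mesh.n_elements
        K = np.empty((n_el, 8, 8))
        h = 1e-30
        for k in range(8):
            up = u_e.copy()
            up[:, k // 2, k % 2] += 1j * h
            f, *_ = self._element_forces(up, lam_a, lam_cs)
            K[:, :, k] = f.reshape(n_el, 8).imag / h
        return K

    # -- follower pressure load --------------------------------------------

    def _edge_forces(self, x_edges, p_kpa):
        """Nodal forces from pressure on deformed inner edges (CCW loop).

        The internal work is integrated per unit *reference* axial length,
        so the current surface element carries the axial stretch lambda_z.
        """
        tvec = x_edges[:, 1, :] - x_edges[:, 0, :]
        n = np.stack([tvec[..., 1], -tvec[..., 0]], axis=-1)  # outward of lumen
        f = np.zeros_like(x_edges)
        f[:, 0, :] = 0.5 * p_kpa * self.lambda_z * n
        f[:, 1, :] = 0.5 * p_kpa * self.lambda_z * n
        return f

    def _external_load(self, u, p_kpa):
        x = (self.mesh.nodes.astype(u.dtype).reshape(-1) + u).reshape(-1, 2)
        xe = x[self._inner]
        f = self._edge_forces(xe, p_kpa)
        F = np.zeros(self.ndof, dtype=u.dtype)
        np.add.at(F, self._ldof.ravel(), f.reshape(-1, 4).ravel())
        return F

    def _load_tangent(self, u, p_kpa):
        x = (self.mesh.nodes.reshape(-1) + u).reshape(-1, 2)[self._inner]
        ne = len(self._inner)
        K = np.empty((ne, 4, 4))
        h = 1e-30
        xc = x.astype(complex)
        for k in range(4):
            xp = xc.copy()
            xp[:, k // 2, k % 2] += 1j * h
            f = self._edge_forces(xp, p_kpa)
            K[:, :, k] = f.reshape(ne, 4).imag / h
        return K

    # -- Newton solve -------------------------------------------------------

    def _damped_newton(self, u, lam_a, lam_cs, p_kpa, tol, max_iter=200):
        """Levenberg-damped Newton (pseudo-transient continuation).

        Robust against limit points / local buckling (e.g. a stiff
        calcified wedge under the in-plane compression induced by the
        axial pre-stretch): follows the damped descent flow to an
        equilibrium, then polishes with pure Newton steps as the damping
        vanishes.
        """
        beta = None
        rn_prev = np.inf
        for it in range(max_iter):
            r_int, p_e, Jbar = self._internal_residual(u, lam_a, lam_cs)
            f_ext = self._external_load(u, p_kpa)
            r = r_int - f_ext
            rn = self._deformational_norm(r)
            if it == 0:
                rn0 = max(rn, 1.0)
            scale = max(np.linalg.norm(f_ext), 1e-2 * rn0, 1.0)
            if rn <= tol * scale:
                return u, p_e, Jbar, rn, it
            Ke = self._element_tangent(u, lam_a, lam_cs)
            Kl = self._load_tangent(u, p_kpa)
            K = sp.coo_matrix((Ke.ravel(), (self._Krows, self._Kcols)),
                              shape=(self.ndof, self.ndof)).tocsr()
            K = (K - sp.coo_matrix((Kl.ravel(), (self._Lrows, self._Lcols)),
                                   shape=(self.ndof, self.ndof)).tocsr()).tocsc()
            diag_scale = np.abs(K.diagonal()).max()
            if beta is None:
                beta = 1e-2 * diag_scale
            accepted = False
            for _ in range(25):
                try:
                    du = self._constrained_solve(K, r, u, beta=beta)
                except RuntimeError:
                    beta = max(beta * 10.0, 1e-8 * diag_scale)
                    continue
                if not np.all(np.isfinite(du)):
                    beta *= 10.0
                    continue
                try:
                    r_try, _, _ = self._internal_residual(u + du, lam_a, lam_cs)
                    f_try = self._external_load(u + du, p_kpa)
                    rt = self._deformational_norm(r_try - f_try)
                except ConvergenceError:
                    rt = np.inf
                if np.isfinite(rt) and rt < max(rn, rn_prev):
                    u = u + du
                    rn_prev = rn
                    beta = max(beta / 3.0, 1e-10 * diag_scale)
                    accepted = True
                    break
                beta *= 10.0
                if beta > 1e6 * diag_scale:
                    raise ConvergenceError("damped Newton stalled")
            if not accepted:
                raise ConvergenceError("damped Newton could not accept a step")
        raise ConvergenceError("damped Newton did not converge",
                               {"residual": float(rn)})

    def _newton(self, u, lam_a, lam_cs, p_kpa, tol, max_iter):
        free_scale = None
        for it in range(max_iter):
            r_int, p_e, Jbar = self._internal_residual(u, lam_a, lam_cs)
            f_ext = self._external_load(u, p_kpa)
            r = r_int - f_ext
            rn = self._deformational_norm(r)
            if free_scale is None:
                free_scale = max(rn, 1.0)
            scale = max(np.linalg.norm(f_ext), 1e-2 * free_scale, 1.0)
            if not np.isfinite(rn) or rn > 1e4 * free_scale:
                raise ConvergenceError("Newton residual diverged")
            if rn <= tol * scale:
                return u, p_e, Jbar, rn, it
            Ke = self._element_tangent(u, lam_a, lam_cs)
            Kl = self._load_tangent(u, p_kpa)
            K = sp.coo_matrix((Ke.ravel(), (self._Krows, self._Kcols)),
                              shape=(self.ndof, self.ndof)).tocsr()
            K = K - sp.coo_matrix((Kl.ravel(), (self._Lrows, self._Lcols)),
                                  shape=(self.ndof, self.ndof)).tocsr()
            try:
                du = self._constrained_solve(K, r, u)
            except RuntimeError as exc:
                raise ConvergenceError(f"tangent factorization failed: {exc}")
            if not np.all(np.isfinite(du)):
                raise ConvergenceError("Newton produced non-finite update")
            # backtracking: halve steps that invert elements or go non-finite
            alpha = 1.0
            for _ in range(10):
                try:
                    r_try, _, _ = self._internal_residual(u + alpha * du,
                                                          lam_a, lam_cs)
                    if np.all(np.isfinite(r_try)):
                        break
                except ConvergenceError:
                    pass
                alpha *= 0.5
            else:
                raise ConvergenceError("line search failed (element inversion)")
            u = u + alpha * du
        raise ConvergenceError(
            "Newton did not converge", {"residual": float(rn), "iters": max_iter})

    def solve(self, p_lumen_mmhg: float, inelastic: InelasticState,
              u0: np.ndarray | None = None, tol: float = 1e-8,
              max_iter: int = 30, max_halvings: int = 9,
              fallback: bool = True,
              p0: float | None = None) -> MechanicalSolution:
        """Solve equilibrium at one lumen pressure with load-step halving.

        With ``fallback`` (default) a failed load path is retried by
        ramping the inelastic state under a stabilizing pressure with the
        damped solver; ``fallback=False`` fails fast (used by sweeps that
        can tolerate dropping an unstable low-pressure point).
        """
        if p_lumen_mmhg < 0:
            raise ValueError("lumen pressure must be non-negative")
        lam_a = np.asarray(inelastic.lambda_a, dtype=float)
        lam_cs = np.asarray(inelastic.lambda_cs, dtype=float)
        u = np.zeros(self.ndof) if u0 is None else u0.copy().reshape(-1)
        p_target = p_lumen_mmhg * units.MMHG_TO_KPA
        p_start = (p0 * units.MMHG_TO_KPA if (p0 is not None and u0 is not None)
                   else 0.0)

        try:
            u, p_e, Jbar, rn, it = self._solve_pressure_path(
                u, lam_a, lam_cs, p_target, tol, max_iter, max_halvings,
                p_from=p_start)
        except ConvergenceError:
            if not fallback:
                raise
            # bulk-modulus continuation: the quasi-incompressibility drive
            # under the axial pre-stretch is the stiff part of the problem,
            # so ramp kappa at a stabilizing (tension) pressure, then walk
            # the pressure to its target
            u = np.zeros(self.ndof) if u0 is None else u0.copy().reshape(-1)
            p_stab = max(min(p_target, 25.0 * units.MMHG_TO_KPA),
                         10.0 * units.MMHG_TO_KPA)
            kappa_full = self._kappa
            try:
                for kap in (f * kappa_full for f in
                            (1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0)):
                    self._kappa = kap
                    u, p_e, Jbar, rn, it = self._newton(
                        u, lam_a, lam_cs, p_stab, tol, max_iter)
            except ConvergenceError:
                self._kappa = kappa_full
                u = np.zeros(self.ndof) if u0 is None else u0.copy().reshape(-1)
                for s in np.linspace(0.25, 1.0, 4):
                    u, p_e, Jbar, rn, it = self._damped_newton(
                        u, 1.0 + s * (lam_a - 1.0), 1.0 + s * (lam_cs - 1.0),
                        p_stab, tol)
            finally:
                self._kappa = kappa_full
            u, p_e, Jbar, rn, it = self._solve_pressure_path(
                u, lam_a, lam_cs, p_target, tol, max_iter, max_halvings,
                p_from=p_stab)

        return self._postprocess(u, lam_a, lam_cs, p_e, Jbar, p_lumen_mmhg, rn, it)

    def _solve_pressure_path(self, u, lam_a, lam_cs, p_target, tol,
                             max_iter, max_halvings, p_from=0.0):
        """Walk the pressure from p_from to p_target (kPa) with adaptive
        step halving (budget resets after each accepted step)."""
        if abs(p_target - p_from) < 1e-12:
            return self._newton(u, lam_a, lam_cs, p_target, tol, max_iter)
        sign = 1.0 if p_target > p_from else -1.0
        p_done, dp = p_from, abs(p_target - p_from)
        out = None
        fails = 0
        while sign * (p_target - p_done) > 1e-12:
            p_try = p_done + sign * min(dp, abs(p_target - p_done))
            try:
                out = self._newton(u.copy(), lam_a, lam_cs, p_try, tol, max_iter)
            except ConvergenceError:
                dp *= 0.5
                fails += 1
                if fails > max_halvings:
                    raise ConvergenceError(
                        "load stepping stalled", {"p_reached_kpa": p_done})
                continue
            u, p_e, Jbar, rn, it = out
            p_done = p_try
            dp *= 1.5
            fails = 0
        return out

    def _postprocess(self, u, lam_a, lam_cs, p_e, Jbar, p_mmhg, rn, it):
        mesh = self.mesh
        u_e = u.reshape(-1, 2)[mesh.elems]
        f, p_e, Jbar, J3, F, lam_th = self._element_forces(u_e, lam_a, lam_cs)
        sigma = self._cauchy_stress(F, J3, p_e, lam_a, lam_cs, lam_th)
        # in-plane inverse right Cauchy-Green, element mean (transport metric)
        C2d = np.einsum('egki,egkj->egij', F, F)
        det = C2d[..., 0, 0] * C2d[..., 1, 1] - C2d[..., 0, 1] * C2d[..., 1, 0]
        Cinv = np.empty_like(C2d)
        Cinv[..., 0, 0] = C2d[..., 1, 1] / det
        Cinv[..., 0, 1] = -C2d[..., 0, 1] / det
        Cinv[..., 1, 0] = -C2d[..., 1, 0] / det
        Cinv[..., 1, 1] = C2d[..., 0, 0] / det
        x = mesh.nodes + u.reshape(-1, 2)
        A = polygon_area(x[mesh.inner_loop])
        return MechanicalSolution(
            u=u.reshape(-1, 2), p_elem=p_e, Jbar=Jbar, A_s=float(A),
            p_lumen_mmhg=float(p_mmhg), sigma=sigma,
            lambda_theta=lam_th.mean(axis=1), J_gp=J3,
            Cinv2d_elem=Cinv.mean(axis=1), residual_norm=float(rn),
            newton_iters=int(it))

    def _cauchy_stress(self, F, J3, p_e, lam_a, lam_cs, lam_th):
        """Element-averaged 3D Cauchy stress from the converged state."""
        m = self.materials
        lz = self.lambda_z
        eth = self._eth
        nF2 = (F * F).sum(axis=(-2, -1))
        I1 = nF2 + lz ** 2
        Jm23 = J3 ** (-2.0 / 3.0)
        b2 = np.einsum('egik,egjk->egij', F, F)
        t = np.einsum('egij,egj->egi', F, eth)
        ctt = (t * t).sum(-1)

        sig = np.zeros(F.shape[:2] + (3, 3))
        # isotropic (Neo-Hookean) deviatoric part, healthy tissue
        bbar_ii = Jm23[..., None, None] * b2
        bbar_zz = Jm23 * lz ** 2
        coef = (self._mu_e[:, None] / J3)
        sig[..., :2, :2] += coef[..., None, None] * (bbar_ii - (Jm23 * I1 / 3.0)[..., None, None] * np.eye(2))
        sig[..., 2, 2] += coef * (bbar_zz - Jm23 * I1 / 3.0)
        # collagen families (z-shear terms cancel between +-phi)
        I4 = self._cos2phi * ctt + self._sin2phi * lz ** 2
        lcs2 = (lam_cs ** 2)[:, None]
        I4e = I4 / lcs2
        xm = np.maximum(I4e - 1.0, 0.0)
        dpsi = self._k1_e[:, None] * xm * np.exp(m.ecm.k2 * xm ** 2)
        cf = 4.0 * dpsi / (J3 * lcs2)
        sig[..., :2, :2] += (cf * self._cos2phi)[..., None, None] * np.einsum('egi,egj->egij', t, t)
        sig[..., 2, 2] += cf * self._sin2phi * lz ** 2
        # SMC active-elastic stress
        lam_e = lam_th / lam_a[:, None]
        Ps = m.smc.P_smc_max * np.tanh(m.smc.C_smc * (lam_e - 1.0) / m.smc.P_smc_max)
        cs = self._smc_e[:, None] * Ps / (J3 * lam_a[:, None] * lam_th)
        sig[..., :2, :2] += cs[..., None, None] * np.einsum('egi,egj->egij', t, t)
        # calcified Yeoh
        if self._calc.any():
            cp = m.calcified
            I1c = lz * nF2 + 1.0
            s = Jm23 * I1c - 3.0
            dpsi_y = cp.c1 + 2.0 * cp.c2 * s + 3.0 * cp.c3 * s ** 2
            cy = np.where(self._calc[:, None], 2.0 * dpsi_y / J3, 0.0)
            sig[..., :2, :2] += cy[..., None, None] * (
                lz * bbar_ii - (Jm23 * I1c / 3.0)[..., None, None] * np.eye(2))
            sig[..., 2, 2] += cy * (Jm23 - Jm23 * I1c / 3.0)
        # pressure multiplier
        sig += p_e[:, None, None, None] * np.eye(3)
        return sig.mean(axis=1)


_MODEL_CACHE: dict[int, FEModel] = {}


def _model_for(mesh: Mesh, materials: WallMaterials | None, lambda_z):
    key = (id(mesh), id(materials), lambda_z)
    model = _MODEL_CACHE.get(key)
    if model is None:
        model = FEModel(mesh, materials, lambda_z)
        if len(_MODEL_CACHE) > 8:
            _MODEL_CACHE.clear()
        _MODEL_CACHE[key] = model
    return model


def solve_equilibrium(mesh: Mesh, materials: WallMaterials | None = None,
                      inelastic: InelasticState | None = None,
                      p_lumen: float = 0.0, lambda_z: float | None = None,
                      u0: np.ndarray | None = None,
                      **solver_opts) -> MechanicalSolution:
    """Solve the pressurized cross-section equilibrium (p_lumen in mmHg)."""
    model = _model_for(mesh, materials, lambda_z)
    if inelastic is None:
        inelastic = InelasticState.uniform(mesh)
    return model.solve(p_lumen, inelastic, u0=u0, **solver_opts)


def compute_lumen_area(solution: MechanicalSolution, mesh: Mesh) -> float:
    """Signed shoelace area (mm^2) of the deformed intima loop."""
    x = mesh.nodes + solution.u
    A = polygon_area(x[mesh.inner_loop])
    if A <= 0:
        raise ValueError("deformed intima loop is inverted or self-intersecting")
    return float(A)
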