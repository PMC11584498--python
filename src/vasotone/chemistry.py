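"""NO-ROS reaction-diffusion signaling and vascular tone coupling maps.

Nitric oxide (NO, vasodilator) diffuses from the endothelium into the wall
where it decays, is scavenged by reactive oxygen species (ROS, forming
reactive nitrogen species), and is produced at a basal tissue rate.
Concentrations are *material* (per unit reference volume, nM), transported
on the reference mesh with the pulled-back metric D * J * C^{-1} from the
converged mechanical state.

Boundary conditions: Dirichlet endothelial concentrations on the intima
(shear-stress-driven Michaelis-Menten NO production), natural zero flux on
the outer boundary.  In calcified elements diffusivity, reaction and
production all vanish; nodes supported only by calcified elements are
inert.

The NO field sets the smooth-muscle active stretch through a sigmoid
passing exactly through (C_NO_b, lambda_b) with limits lambda_minus /
lambda_plus, and the collagen straightening stretch follows linearly with
transfer fraction xi_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CALCIFIED, Mesh
from .mechanics import MechanicalSolution, _GP, _shape_gradients, _shape_values

__all__ = [
    "KineticsParams", "ToneParams", "EndothelialState", "SpeciesFields",
    "InvalidRegimeError", "basal_ros_closure", "endothelial_NO_production",
    "endothelial_concentrations", "endothelial_state",
    "active_stretch_from_NO", "collagen_straightening",
    "element_average_NO", "ReactionDiffusion",
]


class InvalidRegimeError(ValueError):
    """Endothelial production balance outside its validity domain."""


@dataclass(frozen=True)
class KineticsParams:
    """NO-ROS kinetics.  Units: mm, s, nM, Pa, mmHg.

    ``eta_NO`` defaults to the value that makes the tabulated basal state
    (P_NO_b = 80 nM/s, C_NO_b = 10 nM, P_ROS_b = 69.9 nM/s) an exact
    homogeneous steady state.
    """
    D_NO: float = 848e-6       # mm^2/s
    D_ROS: float = 848e-6
    eta_NO: float = 1.01       # 1/s
    K_RNS: float = 4.0         # 1/(nM s)
    P_NO_b: float = 80.0       # nM/s
    C_NO_b: float = 10.0       # nM
    R_NO_max: float = 75.0     # nM/s per Pa of TAWSS deviation
    P_O2: float = 90.0         # mmHg
    K_m: float = 5.5           # mmHg
    tau_b: float = 1.74        # Pa

    def __post_init__(self):
        if min(self.D_NO, self.D_ROS, self.eta_NO, self.K_RNS, self.P_NO_b,
               self.C_NO_b, self.R_NO_max, self.P_O2, self.K_m, self.tau_b) <= 0:
            raise ValueError("kinetic parameters must be positive")

    @property
    def C_ROS_b(self) -> float:
        return basal_ros_closure(self.P_NO_b, self.C_NO_b,
                                 self.eta_NO, self.K_RNS)[0]

    @property
    def P_ROS_b(self) -> float:
        return basal_ros_closure(self.P_NO_b, self.C_NO_b,
                                 self.eta_NO, self.K_RNS)[1]

    @property
    def shear_gain(self) -> float:
        """Michaelis-Menten factor R_NO_max * P_O2 / (K_m + P_O2) (nM/s/Pa)."""
        return self.R_NO_max * self.P_O2 / (self.K_m + self.P_O2)


def basal_ros_closure(P_NO_b: float, C_NO_b: float, eta_NO: float,
                      K_RNS: float):
    """Basal ROS concentration and production from the homogeneous balance.

    C_ROS_b = (P_NO_b/C_NO_b - eta_NO)/K_RNS ;  P_ROS_b = K_RNS C_ROS_b C_NO_b.
    """
    if P_NO_b / C_NO_b < eta_NO:
        raise InvalidRegimeError(
            "P_NO_b/C_NO_b must not be below eta_NO (negative basal ROS)")
    C_ROS_b = (P_NO_b / C_NO_b - eta_NO) / K_RNS
    return C_ROS_b, K_RNS * C_ROS_b * C_NO_b


def endothelial_NO_production(tau_bar: float, params: KineticsParams,
                              alpha_dys: float = 0.0) -> float:
    """Shear-driven endothelial NO production rate (nM/s).

    P_NO_e = P_NO_b + (1 - alpha_dys) * gain * (tau_bar - tau_b); dysfunction
    scales only the shear-sensitive term.
    """
    if tau_bar < 0:
        raise ValueError("TAWSS must be non-negative")
    if not 0.0 <= alpha_dys <= 1.0:
        raise ValueError("alpha_dys must lie in [0, 1]")
    P = params.P_NO_b + (1.0 - alpha_dys) * params.shear_gain * (tau_bar - params.tau_b)
    if P <= 0.0:
        raise InvalidRegimeError(
            f"shear {tau_bar:.3g} Pa is far below basal: P_NO_e = {P:.3g} <= 0")
    return float(P)


def endothelial_concentrations(P_NO_e: float, params: KineticsParams):
    """Endothelial (C_NO_e, C_ROS_e) from the intima steady balance.

    The endothelial ROS production scales linearly with P_NO_e, which makes
    C_ROS_e identically equal to its basal value.
    """
    P_ROS_e = params.P_ROS_b * (P_NO_e / params.P_NO_b)
    if P_NO_e <= P_ROS_e:
        raise InvalidRegimeError("endothelial balance requires P_NO_e > P_ROS_e")
    C_NO_e = (P_NO_e - P_ROS_e) / params.eta_NO
    C_ROS_e = P_ROS_e * params.eta_NO / (params.K_RNS * (P_NO_e - P_ROS_e))
    return float(C_NO_e), float(C_ROS_e)


@dataclass(frozen=True)
class EndothelialState:
    P_NO_e: float
    P_ROS_e: float
    C_NO_e: float
    C_ROS_e: float
    alpha_dys: float = 0.0


def endothelial_state(tau_bar: float, params: KineticsParams,
                      alpha_dys: float = 0.0) -> EndothelialState:
    P_NO_e = endothelial_NO_production(tau_bar, params, alpha_dys)
    C_NO_e, C_ROS_e = endothelial_concentrations(P_NO_e, params)
    return EndothelialState(P_NO_e=P_NO_e,
                            P_ROS_e=params.P_ROS_b * P_NO_e / params.P_NO_b,
                            C_NO_e=C_NO_e, C_ROS_e=C_ROS_e,
                            alpha_dys=alpha_dys)


@dataclass(frozen=True)
class ToneParams:
    """NO -> active stretch sigmoid and collagen transfer fraction."""
    lambda_minus: float = 0.59
    lambda_b: float = 0.75
    lambda_plus: float = 1.3
    k_lambda: float = 100.0
    xi_c: float = 0.15

    def __post_init__(self):
        if not self.lambda_minus < self.lambda_b < self.lambda_plus:
            raise ValueError("require lambda_minus < lambda_b < lambda_plus")
        if not 0.0 <= self.xi_c <= 1.0:
            raise ValueError("xi_c must lie in [0, 1]")

    @property
    def c_lambda(self) -> float:
        return (self.lambda_b - self.lambda_minus) / (self.lambda_plus - self.lambda_b)

    @property
    def b_lambda(self) -> float:
        return ((self.lambda_plus - self.lambda_minus)
                * (self.lambda_b - self.lambda_minus)
                / (2.0 * (self.lambda_plus - self.lambda_b)))

    @property
    def a_lambda(self) -> float:
        # lambda_minus + b_lambda: the unique intercept for which the sigmoid
        # passes through (C_NO_b, lambda_b) with the stated limits
        return self.lambda_minus + self.b_lambda


def active_stretch_from_NO(C_NO, tone: ToneParams,
                           C_NO_b: float = 10.0):
    """SMC active stretch lambda_a(C_NO): strictly increasing sigmoid."""
    C = np.asarray(C_NO, dtype=float)
    if np.any(C < 0):
        raise ValueError("C_NO must be non-negative")
    z = np.exp(-tone.k_lambda * (C / C_NO_b - 1.0))
    lam = tone.a_lambda + 2.0 * tone.b_lambda * (1.0 / (tone.c_lambda + z) - 0.5)
    return lam if lam.ndim else float(lam)


def collagen_straightening(lambda_a, xi_c: float):
    """Straightening stretch lambda_c^s = 1 + xi_c (lambda_a - 1)."""
    if not 0.0 <= xi_c <= 1.0:
        raise ValueError("xi_c must lie in [0, 1]")
    return 1.0 + xi_c * (np.asarray(lambda_a) - 1.0)


@dataclass
class SpeciesFields:
    """Nodal material concentrations (nM) on the reference mesh."""
    C_NO: np.ndarray
    C_ROS: np.ndarray
    time: float = 0.0

    @classmethod
    def basal(cls, mesh: Mesh, params: KineticsParams, time: float = 0.0):
        return cls(C_NO=np.full(mesh.n_nodes, params.C_NO_b),
                   C_ROS=np.full(mesh.n_nodes, params.C_ROS_b), time=time)

    def copy(self) -> "SpeciesFields":
        return SpeciesFields(self.C_NO.copy(), self.C_ROS.copy(), self.time)


def element_average_NO(fields: SpeciesFields, mesh: Mesh) -> np.ndarray:
    """Per-element mean of the four nodal NO values."""
    return fields.C_NO[mesh.elems].mean(axis=1)


class ReactionDiffusion:
    """FE discretization of the coupled NO-ROS transport on one mesh.

    Assembled operators are reused across time steps and endothelial
    boundary updates; the deformation metric can be refreshed when a new
    mechanical state becomes available.
    """

    def __init__(self, mesh: Mesh, params: KineticsParams,
                 deformation: MechanicalSolution | None = None):
        self.mesh = mesh
        self.params = params
        self._active = mesh.region != CALCIFIED
        self._setup_topology()
        self.set_deformation(deformation)

    def _setup_topology(self):
        mesh = self.mesh
        Xe = mesh.nodes[mesh.elems]
        n_el = mesh.n_elements
        self._dN = np.empty((n_el, 4, 4, 2))
        self._wdet = np.empty((n_el, 4))
        self._N = np.empty((4, 4))
        for g, (xi, eta) in enumerate(_GP):
            dNxi = _shape_gradients(xi, eta)
            self._N[g] = _shape_values(xi, eta)
            J0 = np.einsum('eai,aj->eij', Xe, dNxi)
            det = J0[:, 0, 0] * J0[:, 1, 1] - J0[:, 0, 1] * J0[:, 1, 0]
            inv = np.empty_like(J0)
            inv[:, 0, 0] = J0[:, 1, 1] / det
            inv[:, 0, 1] = -J0[:, 0, 1] / det
            inv[:, 1, 0] = -J0[:, 1, 0] / det
            inv[:, 1, 1] = J0[:, 0, 0] / det
            self._dN[:, g] = np.einsum('aj,eji->eai', dNxi, inv)
            self._wdet[:, g] = det
        act = self._active
        # nodes supported by at least one non-calcified element
        supported = np.zeros(mesh.n_nodes, dtype=bool)
        supported[np.unique(mesh.elems[act])] = True
        self.inert_nodes = np.where(~supported)[0]
        inner = np.unique(mesh.inner_edges)
        self.dirichlet_nodes = np.array(
            [n for n in inner if supported[n]], dtype=np.int64)
        rows = np.repeat(mesh.elems[act], 4, axis=1).ravel()
        cols = np.tile(mesh.elems[act], (1, 4)).ravel()
        self._rows, self._cols = rows, cols
        self.n = mesh.n_nodes

    def set_deformation(self, deformation: MechanicalSolution | None):
        """(Re)assemble mass and diffusion operators with the pulled-back
        metric J * C^{-1} from a converged mechanical state (identity if
        None, i.e. undeformed transport)."""
        mesh = self.mesh
        act = self._active
        if deformation is None:
            metric = np.broadcast_to(np.eye(2), (mesh.n_elements, 2, 2))
        else:
            metric = deformation.J_gp.mean(axis=1)[:, None, None] \
                * deformation.Cinv2d_elem
        Me = np.zeros((mesh.n_elements, 4, 4))
        Ke = np.zeros((mesh.n_elements, 4, 4))
        for g in range(4):
            N = self._N[g]
            w = self._wdet[:, g]
            Me += w[:, None, None] * np.einsum('a,b->ab', N, N)
            dN = self._dN[:, g]
            Ke += w[:, None, None] * np.einsum('eai,eij,ebj->eab', dN, metric, dN)
        shape = (self.n, self.n)
        self.M = sp.coo_matrix((Me[act].ravel(), (self._rows, self._cols)),
                               shape=shape).tocsr()
        self.K = sp.coo_matrix((Ke[act].ravel(), (self._rows, self._cols)),
                               shape=shape).tocsr()
        self._lumped = np.asarray(self.M.sum(axis=1)).ravel()

    # -- nonlinear reaction operators --------------------------------------

    def _reaction(self, c_no, c_ros):
        """Galerkin reaction+source residual vectors and Jacobian blocks."""
        p = self.params
        mesh = self.mesh
        act = self._active
        el = mesh.elems[act]
        no_e = c_no[el]          # (n_act, 4)
        ros_e = c_ros[el]
        w = self._wdet[act]
        r_no = np.zeros((el.shape[0], 4))
        r_ros = np.zeros_like(r_no)
        j_nn = np.zeros((el.shape[0], 4, 4))
        j_nr = np.zeros_like(j_nn)
        j_rn = np.zeros_like(j_nn)
        for g in range(4):
            N = self._N[g]
            cn = no_e @ N
            cr = ros_e @ N
            f_no = p.eta_NO * cn + p.K_RNS * cn * cr - p.P_NO_b
            f_ros = p.K_RNS * cn * cr - p.P_ROS_b
            r_no += (w[:, g] * f_no)[:, None] * N
            r_ros += (w[:, g] * f_ros)[:, None] * N
            NN = np.outer(N, N)
            j_nn += (w[:, g] * (p.eta_NO + p.K_RNS * cr))[:, None, None] * NN
            j_nr += (w[:, g] * (p.K_RNS * cn))[:, None, None] * NN
            j_rn += (w[:, g] * (p.K_RNS * cr))[:, None, None] * NN
        shape = (self.n, self.n)
        R_no = np.zeros(self.n)
        R_ros = np.zeros(self.n)
        np.add.at(R_no, el.ravel(), r_no.ravel())
        np.add.at(R_ros, el.ravel(), r_ros.ravel())
        J_nn = sp.coo_matrix((j_nn.ravel(), (self._rows, self._cols)), shape=shape)
        J_nr = sp.coo_matrix((j_nr.ravel(), (self._rows, self._cols)), shape=shape)
        J_rn = sp.coo_matrix((j_rn.ravel(), (self._rows, self._cols)), shape=shape)
        return R_no, R_ros, J_nn.tocsr(), J_nr.tocsr(), J_rn.tocsr()

    def _solve_newton(self, fields: SpeciesFields, bc: EndothelialState,
                      dt: float | None, tol: float = 1e-10,
                      max_iter: int = 25) -> SpeciesFields:
        """Backward-Euler step (dt given) or steady solve (dt None)."""
        p = self.params
        n = self.n
        c_no = fields.C_NO.copy()
        c_ros = fields.C_ROS.copy()
        fixed = np.concatenate([self.dirichlet_nodes, self.inert_nodes])
        fix_no = np.zeros(n, dtype=bool)
        fix_no[fixed] = True
        c_no[self.dirichlet_nodes] = bc.C_NO_e
        c_ros[self.dirichlet_nodes] = bc.C_ROS_e
        old_no, old_ros = fields.C_NO, fields.C_ROS
        scale = max(p.P_NO_b, 1.0) * max(self._lumped.max(), 1.0)
        mask = np.ones(n)
        mask[fixed] = 0.0
        D = sp.diags(mask)
        Ifix = sp.diags(1.0 - mask)
        for _ in range(max_iter):
            R_no, R_ros, J_nn, J_nr, J_rn = self._reaction(c_no, c_ros)
            A_no = p.D_NO * self.K
            A_ros = p.D_ROS * self.K
            r1 = A_no @ c_no + R_no
            r2 = A_ros @ c_ros + R_ros
            B_nn = A_no + J_nn
            B_rr = A_ros + J_nr  # d(K_RNS cn cr)/dcr = K_RNS cn
            if dt is not None:
                r1 = r1 + self.M @ (c_no - old_no) / dt
                r2 = r2 + self.M @ (c_ros - old_ros) / dt
                B_nn = B_nn + self.M / dt
                B_rr = B_rr + self.M / dt
            r1[fixed] = 0.0
            r2[fixed] = 0.0
            res = max(np.abs(r1).max(), np.abs(r2).max())
            if res <= tol * scale:
                break
            J = sp.bmat([[D @ B_nn @ D + Ifix, D @ J_nr @ D],
                         [D @ J_rn @ D, D @ B_rr @ D + Ifix]]).tocsc()
            dz = spla.spsolve(J, -np.concatenate([r1, r2]))
            c_no = c_no + dz[:n]
            c_ros = c_ros + dz[n:]
        else:
            raise RuntimeError("reaction-diffusion Newton did not converge")
        if min(c_no.min(), c_ros.min()) < -1e-9:
            import warnings
            warnings.warn("negative species concentration beyond tolerance",
                          RuntimeWarning)
        t_new = fields.time + (dt or 0.0)
        return SpeciesFields(C_NO=c_no, C_ROS=c_ros, time=t_new)

    def step(self, fields: SpeciesFields, bc: EndothelialState,
             dt: float) -> SpeciesFields:
        """One implicit (backward Euler) step of length dt (s)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        try:
            return self._solve_newton(fields, bc, dt)
        except RuntimeError:
            half = self.step(fields, bc, dt / 2.0)
            return self.step(half, bc, dt / 2.0)

    def integrate(self, fields: SpeciesFields, bc: EndothelialState,
                  duration: float, dt_max: float = 30.0) -> SpeciesFields:
        """Advance the fields over ``duration`` seconds in implicit steps."""
        n_sub = max(1, int(np.ceil(duration / dt_max)))
        dt = duration / n_sub
        out = fields
        for _ in range(n_sub):
            out = self.step(out, bc, dt)
        return out

    def steady_state(self, bc: EndothelialState,
                     init: SpeciesFields | None = None) -> SpeciesFields:
        """Direct Newton solve of the time-independent system."""
        f0 = init or SpeciesFields.basal(self.mesh, self.params)
        try:
            return self._solve_newton(f0, bc, dt=None)
        except RuntimeError:
            # continuation from the basal state through a few large steps
            out = SpeciesFields.basal(self.mesh, self.params)
            for dt in (60.0, 600.0, 6000.0):
                out = self.step(out, bc, dt)
            return self._solve_newton(out, bc, dt=None)

    def total_content(self, fields: SpeciesFields) -> tuple[float, float]:
        """Mass-matrix-weighted total NO and ROS content (nM * mm^2)."""
        ones = np.ones(self.n)
        return (float(fields.C_NO @ (self.M @ ones)),
                float(fields.C_ROS @ (self.M @ ones)))
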