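"""Global-local coupling: surrogate tube law, Steffensen fixed point, slow loop.

At each slow-time step the wall-shear stimulus tau must be consistent with
the hemodynamics it generates.  The transfer map g(tau) chains:

    tau -> endothelial NO/ROS boundary values -> reaction-diffusion over the
    slow step -> element active / straightening stretches -> FE pressure
    sweep -> sigmoid pressure-area surrogate A(p) = a/(1+exp(-b(p/c-1)))+d
    -> R_S(p), C_S(p) -> 0D heartbeat run -> TAWSS,

and the fixed point g(tau*) = tau* is found by Aitken-Steffensen iteration
(derivative-free, one-step exact on affine maps) with the averaging
safeguard when the error grows.  The chemistry inside g always restarts
from the state committed at the previous slow step, so g is a pure
function of tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import units
from .chemistry import (KineticsParams, ReactionDiffusion, SpeciesFields,
                        ToneParams, active_stretch_from_NO,
                        collagen_straightening, element_average_NO,
                        endothelial_state)
from .geometry import MEDIA, Mesh
from .hemodynamics import NetworkParams, NetworkResult, backward_euler_run
from .mechanics import (ConvergenceError, FEModel, InelasticState,
                        MechanicalSolution, WallMaterials)

log = logging.getLogger("vasotone")

__all__ = [
    "SurrogateAP", "CouplingState", "SlowStepRecord", "CoupledModel",
    "sweep_pressure_area", "fit_surrogate", "resistance_compliance",
    "aitken_steffensen_solve", "calibrate_viscosity",
]


@dataclass(frozen=True)
class SurrogateAP:
    """Fitted sigmoid tube law A(p) = a / (1 + exp(-b (p/c - 1))) + d."""
    a: float
    b: float
    c: float
    d: float
    rms_residual: float = 0.0
    p_range: tuple = (0.0, 250.0)

    def area(self, p):
        p = np.asarray(p, dtype=float)
        A = self.a / (1.0 + np.exp(-self.b * (p / self.c - 1.0))) + self.d
        return A if A.ndim else float(A)

    def dA_dp(self, p):
        p = np.asarray(p, dtype=float)
        e = np.exp(-self.b * (p / self.c - 1.0))
        d = self.a * self.b / self.c * e / (1.0 + e) ** 2
        return d if d.ndim else float(d)


def sweep_pressure_area(model: FEModel, inelastic: InelasticState,
                        p_max: float = 250.0, n_p: int = 10,
                        u0: np.ndarray | None = None,
                        stop_index: int = 0):
    """FE equilibria at n_p incremental pressures in [0, p_max] (mmHg).

    The sweep anchors at a mid-range pressure (where membrane tension
    stabilizes the thin wall) and walks down to zero and up to p_max,
    warm-starting every step.  An unloaded calcified section can sit at an
    unstable (wrinkling) configuration; failed low-pressure steps are
    dropped and the fit proceeds with the partial results.

    Returns (pressures, areas, solutions), ordered by pressure.
    """
    if p_max <= 0 or n_p < 4:
        raise ValueError("require p_max > 0 and n_p >= 4")
    pressures = np.linspace(0.0, p_max, n_p + 1)
    mid = int(np.searchsorted(pressures, min(100.0, p_max / 2.0)))
    mid = min(max(mid, 1), n_p)
    out: dict[int, "object"] = {}
    sol_mid = model.solve(pressures[mid], inelastic, u0=u0,
                          p0=pressures[mid] if u0 is not None else None)
    out[mid] = sol_mid
    u = sol_mid.u
    for i in range(mid - 1, stop_index - 1, -1):   # downward branch
        try:
            sol = model.solve(pressures[i], inelastic, u0=u, fallback=False,
                              p0=pressures[i + 1], max_halvings=3)
        except ConvergenceError:
            log.warning("pressure sweep: dropping unstable step p=%.1f mmHg",
                        pressures[i])
            break
        out[i] = sol
        u = sol.u
    u = sol_mid.u
    for i in range(mid + 1, n_p + 1):         # upward branch
        sol = model.solve(pressures[i], inelastic, u0=u, p0=pressures[i - 1])
        out[i] = sol
        u = sol.u
    idx = sorted(out)
    sols = [out[i] for i in idx]
    return (pressures[idx], np.array([s.A_s for s in sols]), sols)


def fit_surrogate(pressures, areas, rms_warn_fraction: float = 0.02) -> SurrogateAP:
    """Constrained least-squares fit of the sigmoid tube law (c > 0).

    Multi-start over slope/center initializations; emits a warning through
    the module logger when the RMS residual exceeds ``rms_warn_fraction``
    of the fitted area range.
    """
    p = np.asarray(pressures, dtype=float)
    A = np.asarray(areas, dtype=float)
    if len(p) < 4 or len(np.unique(p)) < 4:
        raise ValueError("need at least 4 distinct (p, A) pairs")
    rng_A = A.max() - A.min()
    scale = max(rng_A, 1e-12)

    def residual(x):
        a, b, c, d = x
        return (a / (1.0 + np.exp(-b * (p / c - 1.0))) + d - A) / scale

    best = None
    p_mid = 0.5 * (p.min() + p.max())
    for b0 in (2.0, 4.0, 8.0):
        for c0 in (0.5 * p_mid, p_mid, 1.5 * p_mid):
            x0 = np.array([1.5 * rng_A, b0, max(c0, 1.0), A.min() - 0.2 * rng_A])
            try:
                fit = least_squares(
                    residual, x0,
                    bounds=([-np.inf, -np.inf, 1e-6, -np.inf],
                            [np.inf, np.inf, np.inf, np.inf]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if best is None or fit.cost < best.cost:
                best = fit
    if best is None:
        raise RuntimeError("surrogate fit failed for all initializations")
    a, b, c, d = best.x
    rms = float(np.sqrt(np.mean((residual(best.x) * scale) ** 2)))
    if rms > rms_warn_fraction * scale:
        log.warning("surrogate RMS residual %.3g exceeds %.1f%% of area range",
                    rms, 100 * rms_warn_fraction)
    sur = SurrogateAP(a=float(a), b=float(b), c=float(c), d=float(d),
                      rms_residual=rms, p_range=(float(p.min()), float(p.max())))
    if np.any(sur.dA_dp(np.linspace(p.min(), p.max(), 101)) <= 0):
        log.warning("fitted surrogate is not strictly increasing on the range")
    return sur


def resistance_compliance(surrogate: SurrogateAP, p: float, ell_S: float,
                          mu_b: float):
    """(R_S, C_S) at pressure p: Poiseuille resistance and ell * dA/dp.

    Units: mmHg s/mL and mL/mmHg; ell_S in mm, mu_b in Pa s.
    """
    A = surrogate.area(p)
    if np.any(np.asarray(A) <= 0):
        raise ValueError("surrogate area non-positive at requested pressure")
    R = units.poiseuille_resistance_mmhg_s_per_ml(mu_b, ell_S, A)
    C = units.compliance_ml_per_mmhg(ell_S, surrogate.dA_dp(p))
    return R, C


# ---------------------------------------------------------------------------
# fixed-point acceleration
# ---------------------------------------------------------------------------

@dataclass
class CouplingState:
    tau: float
    err: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)


def aitken_steffensen_solve(g, tau_init: float, tol: float = 1e-3,
                            max_iter: int = 25, err_of=None) -> tuple[float, CouplingState]:
    """Aitken-Steffensen fixed-point solve of g(tau) = tau.

    Each update tau_{j+1} = tau_j - (g(tau_j)-tau_j)^2 / (g(g(tau_j)) -
    2 g(tau_j) + tau_j) costs two g evaluations (memoized).  Convergence is
    judged on |err_of(tau_{j+1}) - err_of(tau_j)| < tol (err_of defaults to
    identity, i.e. the TAWSS itself); when the error grows between
    iterations the next guess is re-initialized to the average of the last
    two (the safeguard of the source algorithm).
    """
    if err_of is None:
        err_of = lambda t: t
    cache: dict[float, float] = {}

    def G(t):
        if t not in cache:
            cache[t] = g(t)
        return cache[t]

    state = CouplingState(tau=tau_init, err=np.inf, iterations=0, converged=False)
    tau_j = float(tau_init)
    prev_err = None
    for j in range(max_iter):
        g1 = G(tau_j)
        denom_raw = None
        if abs(g1 - tau_j) <= 1e-14 * max(abs(tau_j), 1.0):
            # already at a fixed point; the Steffensen denominator is 0/0
            state.tau, state.err = tau_j, 0.0
            state.iterations = j + 1
            state.converged = True
            state.trace.append((tau_j, g1, 0.0))
            return tau_j, state
        g2 = G(g1)
        denom = g2 - 2.0 * g1 + tau_j
        if abs(denom) < 1e-14 * max(abs(tau_j), 1.0):
            tau_next = 0.5 * (tau_j + g1)   # safeguard averaging
        else:
            tau_next = tau_j - (g1 - tau_j) ** 2 / denom
        err = abs(err_of(tau_next) - err_of(tau_j))
        state.trace.append((tau_j, g1, err))
        if prev_err is not None and err > prev_err:
            tau_next = 0.5 * (tau_next + tau_j)
            err = abs(err_of(tau_next) - err_of(tau_j))
        if err < tol:
            state.tau, state.err = tau_next, err
            state.iterations = j + 1
            state.converged = True
            return tau_next, state
        prev_err = err
        tau_j = tau_next
    state.tau, state.err, state.iterations = tau_j, prev_err or np.inf, max_iter
    raise RuntimeError(
        f"Steffensen iteration did not converge in {max_iter} iterations "
        f"(last err {state.err:.3g}); trace: {state.trace}")


# ---------------------------------------------------------------------------
# the coupled model driver
# ---------------------------------------------------------------------------

@dataclass
class SlowStepRecord:
    t: float
    tau: float
    C_NO_e: float
    p_mean: float
    p_sys: float
    p_dia: float
    r_mean: float
    r_unloaded: float
    R_S: float
    C_S: float
    iterations: int
    err: float
    lambda_a_mean: float
    C_NO_mean: float
    C_ROS_mean: float


class CoupledModel:
    """Two-way coupled local cross-section + 0D network model.

    Holds the committed chemo-mechanical state between slow steps and
    exposes ``evaluate_g``, fixed-point stepping, and the slow-time loop.
    """

    def __init__(self, mesh: Mesh, materials: WallMaterials | None = None,
                 kinetics: KineticsParams | None = None,
                 tone: ToneParams | None = None,
                 network: NetworkParams | None = None,
                 regulation: bool = True,
                 alpha_dys: float = 0.0,
                 p_max: float = 250.0, n_p: int = 10,
                 steady_chemistry: bool = False,
                 rd_dt_max: float = 30.0):
        self.mesh = mesh
        self.materials = materials or WallMaterials()
        self.kinetics = kinetics or KineticsParams()
        self.tone = tone or ToneParams()
        self.network = network or NetworkParams()
        self.regulation = regulation
        self.alpha_dys = alpha_dys
        self.p_max, self.n_p = p_max, n_p
        self.steady_chemistry = steady_chemistry
        self.rd_dt_max = rd_dt_max

        self.fe = FEModel(mesh, self.materials)
        self.rd = ReactionDiffusion(mesh, self.kinetics)
        self.fields = SpeciesFields.basal(mesh, self.kinetics)
        self.tau_committed = self.kinetics.tau_b
        self.t = 0.0
        self._sweep_u0 = None
        self._y_end = None
        self.history: list[SlowStepRecord] = []

    # -- building blocks ---------------------------------------------------

    def basal_inelastic(self) -> InelasticState:
        lam_b = self.tone.lambda_b
        return InelasticState.uniform(
            self.mesh, lam_b, float(collagen_straightening(lam_b, self.tone.xi_c)))

    def inelastic_from_fields(self, fields: SpeciesFields) -> InelasticState:
        if not self.regulation:
            return self.basal_inelastic()
        C_e = element_average_NO(fields, self.mesh)
        lam_a = active_stretch_from_NO(C_e, self.tone, self.kinetics.C_NO_b)
        lam_cs = collagen_straightening(lam_a, self.tone.xi_c)
        media = self.mesh.region == MEDIA
        la = np.where(media, lam_a, 1.0)
        lc = np.where(media, lam_cs, 1.0)
        return InelasticState(lambda_a=la, lambda_cs=lc)

    def chemistry_at(self, tau: float, dt: float | None) -> SpeciesFields:
        """Species fields for shear guess tau, restarted from the committed
        state (transient over dt, or the steady solution)."""
        bc = endothelial_state(tau, self.kinetics, self.alpha_dys)
        if self.steady_chemistry or dt is None:
            return self.rd.steady_state(bc, init=self.fields.copy())
        return self.rd.integrate(self.fields.copy(), bc, dt, self.rd_dt_max)

    _sweep_stop: int = 0

    def surrogate_for(self, inelastic: InelasticState) -> SurrogateAP:
        p, A, sols = sweep_pressure_area(self.fe, inelastic, self.p_max,
                                         self.n_p, u0=self._sweep_u0,
                                         stop_index=self._sweep_stop)
        self._sweep_u0 = sols[len(sols) // 2].u  # warm start next sweep mid-range
        # remember the lowest reachable pressure: unstable unloaded states
        # of a calcified section are not re-probed on every sweep
        self._sweep_stop = max(self._sweep_stop,
                               int(np.searchsorted(
                                   np.linspace(0.0, self.p_max, self.n_p + 1),
                                   p.min() - 1e-9)))
        self._last_sweep = (p, A, sols)
        return fit_surrogate(p, A)

    def network_run(self, surrogate: SurrogateAP, t: float | None = None,
                    f_h: float | None = None) -> NetworkResult:
        f = f_h if f_h is not None else self._current_f_h
        return backward_euler_run(surrogate, self.network, f,
                                  t_start=t if t is not None else self.t)

    _current_f_h: float = 1.0

    # -- the transfer function g -------------------------------------------

    def evaluate_g(self, tau_guess: float, dt: float | None = None,
                   collect: dict | None = None) -> float:
        """One full local->global pass; pure in tau_guess given the
        committed state."""
        fields = self.chemistry_at(tau_guess, dt)
        inelastic = self.inelastic_from_fields(fields)
        surrogate = self.surrogate_for(inelastic)
        result = self.network_run(surrogate)
        tau_new = result.tawss()
        if collect is not None:
            collect.update(fields=fields, inelastic=inelastic,
                           surrogate=surrogate, network=result)
        return tau_new

    def endothelial_C(self, tau: float) -> float:
        return endothelial_state(tau, self.kinetics, self.alpha_dys).C_NO_e

    # -- slow-time stepping -------------------------------------------------

    def step_to(self, t: float, f_h: float, tol: float = 1e-3,
                max_iter: int = 25,
                prescribed_tau: float | None = None) -> SlowStepRecord:
        """Advance the committed state to slow time t at heart rate f_h.

        With ``prescribed_tau`` the 0D solve and the fixed-point loop are
        skipped (local-only mode).
        """
        dt = t - self.t if t > self.t else None
        self._current_f_h = f_h
        payload: dict = {}
        if prescribed_tau is not None:
            tau_star = prescribed_tau
            fields = self.chemistry_at(tau_star, dt)
            inelastic = self.inelastic_from_fields(fields)
            surrogate = self.surrogate_for(inelastic)
            network = self.network_run(surrogate)
            payload.update(fields=fields, inelastic=inelastic,
                           surrogate=surrogate, network=network)
            state = CouplingState(tau=tau_star, err=0.0, iterations=0,
                                  converged=True)
        else:
            g = lambda tau: self.evaluate_g(tau, dt)
            err_of = lambda tau: (self.endothelial_C(tau)
                                  / self.kinetics.C_NO_b)
            tau_star, state = aitken_steffensen_solve(
                g, self.tau_committed, tol=tol, max_iter=max_iter,
                err_of=err_of)
            # final consistent pass at the accepted tau
            self.evaluate_g(tau_star, dt, collect=payload)
        return self._commit(t, tau_star, state, payload)

    def _commit(self, t: float, tau: float, state: CouplingState,
                payload: dict) -> SlowStepRecord:
        self.t = t
        self.tau_committed = tau
        self.fields = payload["fields"]
        network: NetworkResult = payload["network"]
        surrogate: SurrogateAP = payload["surrogate"]
        inelastic: InelasticState = payload["inelastic"]
        ph = network.physical
        p_mean = float(network.p_S[ph].mean())
        p_sys, p_dia = network.systolic_diastolic()
        # refresh the transport metric with the state at mean pressure
        mech = self.fe.solve(p_mean, inelastic, u0=self._sweep_u0)
        self.rd.set_deformation(mech)
        self.mechanical = mech
        self.inelastic = inelastic
        self.surrogate = surrogate
        self.last_network = network
        R_S, C_S = resistance_compliance(surrogate, p_mean,
                                         self.network.ell_S, self.network.mu_b)
        media = self.mesh.region == MEDIA
        healthy = self.mesh.region != 2
        rec = SlowStepRecord(
            t=t, tau=tau, C_NO_e=self.endothelial_C(tau), p_mean=p_mean,
            p_sys=p_sys, p_dia=p_dia,
            r_mean=float(np.sqrt(surrogate.area(p_mean) / np.pi)),
            r_unloaded=float(np.sqrt(max(surrogate.area(0.0), 1e-12) / np.pi)),
            R_S=R_S, C_S=C_S, iterations=state.iterations, err=state.err,
            lambda_a_mean=float(inelastic.lambda_a[media].mean()),
            C_NO_mean=float(self.fields.C_NO.mean()),
            C_ROS_mean=float(self.fields.C_ROS.mean()))
        self.history.append(rec)
        log.info("t=%8.1f s  tau=%.4f Pa  p=%.1f mmHg  iter=%d  err=%.2e",
                 t, tau, p_mean, state.iterations, state.err)
        return rec

    def run_schedule(self, schedule, tol: float = 1e-3) -> list[SlowStepRecord]:
        """Run the slow-time loop over a :class:`ScenarioSchedule`-like
        object exposing ``times``, ``f_h(t)``, ``tau_bar(t)`` (or None) and
        ``alpha_dys``."""
        self.alpha_dys = getattr(schedule, "alpha_dys", self.alpha_dys)
        records = []
        for t_k in schedule.times:
            tau_fixed = None
            if getattr(schedule, "tau_bar", None) is not None:
                tau_fixed = float(schedule.tau_bar(t_k))
            records.append(self.step_to(float(t_k), float(schedule.f_h(t_k)),
                                        tol=tol, prescribed_tau=tau_fixed))
        return records


def calibrate_viscosity(model: CoupledModel, target_tau: float | None = None,
                        tol: float = 1e-12, max_iter: int = 30) -> float:
    """Calibrate the blood viscosity so the basal network run returns the
    tabulated basal TAWSS (the construction used for the printed value).

    TAWSS is nearly proportional to mu_b (the only indirect coupling is the
    small Poiseuille contribution of the segment to the total resistance),
    so scaled fixed-point iteration converges geometrically.  Returns the
    calibrated mu_b and installs it in ``model.network``.
    """
    target = target_tau if target_tau is not None else model.kinetics.tau_b
    surrogate = model.surrogate_for(model.basal_inelastic())
    mu = model.network.mu_b
    for _ in range(max_iter):
        model.network = replace(model.network, mu_b=mu)
        res = model.network_run(surrogate, t=0.0, f_h=model.network.f_h_basal)
        tau = res.tawss()
        if abs(tau / target - 1.0) < tol:
            break
        mu *= target / tau
    model.network = replace(model.network, mu_b=mu)
    return mu
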