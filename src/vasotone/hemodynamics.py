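"""Lumped-parameter (0D) three-segment cardiovascular network.

An upstream artery (constant R1, C1), the chemo-mechanically active
segment of interest (pressure-dependent R_S(p), C_S(p) from the local
model surrogate), and downstream vasculature (constant R3, C3) in series.
The inflow is a half-beat raised-cosine ejection with per-beat volume V_h;
the outflow pressure P_out is fixed.

State y = (P1+, PS+, P3+) evolves on the fast (heartbeat) time scale by
backward Euler with a Newton solve per step.  The run is preceded by
fictitious pre-beats (from y = P_out * 1) so the physical window of n_h
beats is a steady periodic response.

Units: pressures mmHg, flows mL/s, time s, shear Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = [
    "NetworkParams", "NetworkResult", "inflow_waveform", "backward_euler_run",
    "mean_segment_quantities", "wall_shear_series", "tawss",
]


@dataclass(frozen=True)
class NetworkParams:
    R1: float = 0.1        # mmHg s/mL
    C1: float = 0.5        # mL/mmHg
    R3: float = 1.0        # mmHg s/mL
    C3: float = 0.001      # mL/mmHg
    P_out: float = 0.0     # mmHg
    mu_b: float = 3.5e-3   # Pa s (dynamic)
    ell_S: float = 300.0   # mm
    V_h: float = 5600.0 / 60.0  # mL/beat (5.6 L/min at 60 bpm)
    f_h_basal: float = 1.0      # beats/s
    steps_per_beat: int = 200
    n_h: int = 3                # physical beats for the TAWSS window
    pre_seconds: float = 5.0    # fictitious pre-run duration


def inflow_waveform(t_h, t0: float, f_h: float, V_h: float):
    """Cardiac inflow Q_h (mL/s): raised-cosine systolic half, zero diastole.

    The amplitude Q_a = 4 f_h V_h makes the per-beat integral exactly V_h.
    """
    if f_h <= 0:
        raise ValueError("heart rate must be positive")
    T_h = 1.0 / f_h
    s = np.mod(np.asarray(t_h, dtype=float) - t0, T_h)
    Qa = 4.0 * f_h * V_h
    Q = np.where(s < T_h / 2.0,
                 0.5 * Qa * (1.0 - np.cos(4.0 * np.pi * f_h * s)),
                 0.0)
    return Q if Q.ndim else float(Q)


@njit(cache=False)
def _run_loop(t0, dt, n_steps, f_h, Qa, R1, C1, R3, C3, P_out,
              rcoef, ccoef, sa, sb, sc, sd, y0):
    """Backward-Euler time stepping (Newton per step, numeric Jacobian)."""
    T_half = 0.5 / f_h
    T_h = 1.0 / f_h
    P1 = np.empty(n_steps + 1)
    PS = np.empty(n_steps + 1)
    P3 = np.empty(n_steps + 1)
    P1[0], PS[0], P3[0] = y0[0], y0[1], y0[2]
    y = y0.copy()
    for i in range(1, n_steps + 1):
        t = t0 + i * dt
        s = (t - t0) % T_h
        Qh = 0.5 * Qa * (1.0 - np.cos(4.0 * np.pi * f_h * s)) if s < T_half else 0.0
        yo0, yo1, yo2 = y[0], y[1], y[2]
        # Newton iterations
        for _ in range(30):
            r = np.empty(3)
            J = np.empty((3, 3))
            # residual and numeric Jacobian (central differences)
            for col in range(4):
                if col == 0:
                    yy0, yy1, yy2 = y[0], y[1], y[2]
                else:
                    h = 1e-7 * (1.0 + abs(y[col - 1]))
                    yy0, yy1, yy2 = y[0], y[1], y[2]
                    if col == 1:
                        yy0 += h
                    elif col == 2:
                        yy1 += h
                    else:
                        yy2 += h
                pS = 0.5 * (yy1 + yy2)
                A = sa / (1.0 + np.exp(-sb * (pS / sc - 1.0))) + sd
                dAdp = (sa * sb / sc) * np.exp(-sb * (pS / sc - 1.0)) \
                    / (1.0 + np.exp(-sb * (pS / sc - 1.0))) ** 2
                RS = rcoef / (A * A)
                CS = ccoef * dAdp
                f0 = C1 * (yy0 - yo0) / dt - Qh + (yy0 - yy1) / R1
                f1 = CS * (yy1 - yo1) / dt - (yy0 - yy1) / R1 + (yy1 - yy2) / RS
                f2 = C3 * (yy2 - yo2) / dt - (yy1 - yy2) / RS + (yy2 - P_out) / R3
                if col == 0:
                    r[0], r[1], r[2] = f0, f1, f2
                else:
                    J[0, col - 1] = (f0 - r[0]) / h
                    J[1, col - 1] = (f1 - r[1]) / h
                    J[2, col - 1] = (f2 - r[2]) / h
            # solve J dx = -r by Gaussian elimination with partial pivoting
            b0, b1, b2 = -r[0], -r[1], -r[2]
            A = J.copy()
            bb = np.empty(3)
            bb[0], bb[1], bb[2] = b0, b1, b2
            for k in range(2):
                piv = k
                for m in range(k + 1, 3):
                    if abs(A[m, k]) > abs(A[piv, k]):
                        piv = m
                if piv != k:
                    for m in range(3):
                        A[k, m], A[piv, m] = A[piv, m], A[k, m]
                    bb[k], bb[piv] = bb[piv], bb[k]
                for m in range(k + 1, 3):
                    fac = A[m, k] / A[k, k]
                    for nn in range(k, 3):
                        A[m, nn] -= fac * A[k, nn]
                    bb[m] -= fac * bb[k]
            dx2 = bb[2] / A[2, 2]
            dx1 = (bb[1] - A[1, 2] * dx2) / A[1, 1]
            dx0 = (bb[0] - A[0, 1] * dx1 - A[0, 2] * dx2) / A[0, 0]
            y[0] += dx0
            y[1] += dx1
            y[2] += dx2
            if abs(r[0]) + abs(r[1]) + abs(r[2]) < 1e-10 * (1.0 + Qa):
                break
        P1[i], PS[i], P3[i] = y[0], y[1], y[2]
    return P1, PS, P3


@dataclass
class NetworkResult:
    """Beat-resolved pressure/flow history of the three-segment network."""
    t_h: np.ndarray
    P1: np.ndarray
    PS: np.ndarray
    P3: np.ndarray
    params: NetworkParams
    f_h: float
    surrogate: "object"          # SurrogateAP-like: area(p), dA_dp(p)
    n_pre: int

    @property
    def p_S(self) -> np.ndarray:
        """Mean pressure of the segment of interest (mmHg)."""
        return 0.5 * (self.PS + self.P3)

    @property
    def q_S(self) -> np.ndarray:
        """Mean flow of the segment of interest (mL/s)."""
        RS = units.poiseuille_resistance_mmhg_s_per_ml(
            self.params.mu_b, self.params.ell_S, self.surrogate.area(self.p_S))
        q_in = (self.P1 - self.PS) / self.params.R1
        q_out = (self.PS - self.P3) / RS
        return 0.5 * (q_in + q_out)

    @property
    def r_S(self) -> np.ndarray:
        """Lumen radius at the instantaneous mean pressure (mm)."""
        return np.sqrt(self.surrogate.area(self.p_S) / np.pi)

    @property
    def tau_S(self) -> np.ndarray:
        return wall_shear_series(self.q_S, self.r_S, self.params.mu_b)

    @property
    def physical(self) -> np.ndarray:
        """Boolean mask of the physical (post pre-run) window."""
        T_h = 1.0 / self.f_h
        return self.t_h >= self.t_h[0] + self.n_pre * T_h - 1e-12

    def tawss(self) -> float:
        return tawss(self.tau_S[self.physical], self.params.n_h, 1.0 / self.f_h,
                     dt=self.t_h[1] - self.t_h[0])

    def systolic_diastolic(self) -> tuple[float, float]:
        p = self.p_S[self.physical]
        return float(p.max()), float(p.min())


def backward_euler_run(surrogate, params: NetworkParams, f_h: float,
                       t_start: float = 0.0,
                       y0: np.ndarray | None = None) -> NetworkResult:
    """Run the network over the pre-run + physical window at heart rate f_h.

    ``surrogate`` provides area(p) [mm^2] via the fitted sigmoid; the
    segment resistance/compliance follow from Poiseuille and ell*dA/dp.
    """
    if f_h <= 0:
        raise ValueError("heart rate must be positive")
    T_h = 1.0 / f_h
    n_pre = int(np.ceil(params.pre_seconds / T_h))
    dt = T_h / params.steps_per_beat
    n_steps = (n_pre + params.n_h) * params.steps_per_beat
    t0 = t_start - n_pre * T_h
    y0 = np.full(3, params.P_out, dtype=float) if y0 is None else \
        np.asarray(y0, dtype=float)
    a, b, c, d = surrogate.a, surrogate.b, surrogate.c, surrogate.d
    rcoef = units.poiseuille_resistance_mmhg_s_per_ml(
        params.mu_b, params.ell_S, 1.0)  # divide by A^2 in the loop
    ccoef = params.ell_S * units.MM3_TO_ML
    Qa = 4.0 * f_h * params.V_h
    P1, PS, P3 = _run_loop(t0, dt, n_steps, f_h, Qa,
                           params.R1, params.C1, params.R3, params.C3,
                           params.P_out, rcoef, ccoef, a, b, c, d, y0)
    t_h = t0 + dt * np.arange(n_steps + 1)
    res = NetworkResult(t_h=t_h, P1=P1, PS=PS, P3=P3, params=params,
                        f_h=f_h, surrogate=surrogate, n_pre=n_pre)
    if np.any(surrogate.dA_dp(res.p_S) < -1e-12) or np.any(
            surrogate.area(res.p_S) <= 0):
        raise RuntimeError("surrogate invalid (negative compliance or area) "
                           "inside the pressure range of the run")
    return res


def mean_segment_quantities(result: NetworkResult):
    """(p_s, q_s) time series of the segment of interest."""
    return result.p_S, result.q_S


def wall_shear_series(q_S, r_S, mu_b: float):
    """Poiseuille wall shear stress series (Pa): tau = 4 mu q / (pi r^3)."""
    q = np.asarray(q_S, dtype=float)
    r = np.asarray(r_S, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    return units.wall_shear_pa(mu_b, q, r)


def tawss(tau_series, n_h: int, T_h: float, dt: float) -> float:
    """Time-averaged wall shear stress over the n_h-beat physical window."""
    tau = np.asarray(tau_series, dtype=float)
    need = n_h * T_h
    have = (len(tau) - 1) * dt
    if have < need - 1e-9:
        raise ValueError(f"series covers {have:.3f}s < required {need:.3f}s")
    n = int(round(need / dt))
    tau = tau[-(n + 1):]
    return float(np.trapezoid(tau, dx=dt) / (n * dt))
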