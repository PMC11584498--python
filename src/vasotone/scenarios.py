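"""Scenario schedules: the numerical experiments of the study.

Schedules are piecewise-linear functions of the slow time t:

* ``basal_equilibrium`` / ``calcified_equilibrium`` (+ ``_frozen``):
  constant basal heart rate; the loop finds the coupled equilibrium.
* ``local_tawss_up`` / ``local_tawss_down``: local-only mode, the TAWSS is
  prescribed and ramped +-50% over 2 minutes, then held.
* ``heart_rate_ramp``: 60 -> 120 -> 180 bpm plateaus (at ~0, 12, 26 min)
  with 2-minute linear transitions, over 60 minutes; optional endothelial
  dysfunction level applies to the same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import Config

__all__ = ["ScenarioSchedule", "make_scenario", "SCENARIOS", "piecewise_linear"]


def piecewise_linear(knots_t, knots_v) -> Callable[[float], float]:
    t = np.asarray(knots_t, dtype=float)
    v = np.asarray(knots_v, dtype=float)

    def f(x):
        return float(np.interp(x, t, v))
    return f


@dataclass
class ScenarioSchedule:
    kind: str
    times: np.ndarray                       # slow steps t_k (s)
    f_h: Callable[[float], float]           # beats/s
    alpha_dys: float = 0.0
    tau_bar: Callable[[float], float] | None = None   # local-only override
    calcified: bool = False
    regulation: bool = True
    steady_chemistry: bool = False

    def __post_init__(self):
        if len(self.times) == 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("slow steps must be strictly increasing")


def _steps(duration, dt_ramp, dt_plateau, ramps):
    """Slow-step times: fine during ramp windows, coarse on plateaus."""
    ts = [0.0]
    t = 0.0
    while t < duration - 1e-9:
        in_ramp = any(a - 1e-9 <= t < b - 1e-9 for a, b in ramps)
        t = min(t + (dt_ramp if in_ramp else dt_plateau), duration)
        ts.append(t)
    return np.array(ts)


def make_scenario(name: str, config: Config,
                  duration: float | None = None,
                  slow_dt: float | None = None) -> ScenarioSchedule:
    s = config.solver
    fb = config.network.f_h_basal
    tau_b = config.kinetics.tau_b
    dur = duration if duration is not None else config.scenario.duration
    dt_r = slow_dt if slow_dt is not None else s.slow_dt_ramp
    dt_p = slow_dt if slow_dt is not None else s.slow_dt_plateau

    if name == "basal_equilibrium":
        return ScenarioSchedule(
            kind=name, times=_steps(dur, dt_p, dt_p, []),
            f_h=lambda t: fb, steady_chemistry=True)
    if name == "calcified_equilibrium":
        return ScenarioSchedule(
            kind=name, times=_steps(dur, dt_p, dt_p, []),
            f_h=lambda t: fb, calcified=True, steady_chemistry=True)
    if name == "calcified_equilibrium_frozen":
        return ScenarioSchedule(
            kind=name, times=_steps(dur, dt_p, dt_p, []),
            f_h=lambda t: fb, calcified=True, regulation=False,
            steady_chemistry=True)
    if name in ("local_tawss_up", "local_tawss_down"):
        sign = 1.0 if name.endswith("up") else -1.0
        ramp = piecewise_linear([0.0, 120.0, max(dur, 120.0)],
                                [tau_b, tau_b * (1 + 0.5 * sign),
                                 tau_b * (1 + 0.5 * sign)])
        return ScenarioSchedule(
            kind=name, times=_steps(dur, dt_r, dt_p, [(0.0, 120.0)]),
            f_h=lambda t: fb, tau_bar=ramp)
    if name in ("heart_rate_ramp", "dysfunction_mild", "dysfunction_severe"):
        alpha = {"heart_rate_ramp": 0.0, "dysfunction_mild": 0.5,
                 "dysfunction_severe": 0.9}[name]
        dur = duration if duration is not None else 3600.0
        # plateaus at basal (to 10 min), doubled (12-24 min), tripled (26+)
        knots_t = [0.0, 600.0, 720.0, 1440.0, 1560.0, dur]
        knots_f = [fb, fb, 2 * fb, 2 * fb, 3 * fb, 3 * fb]
        return ScenarioSchedule(
            kind=name,
            times=_steps(dur, dt_r, dt_p, [(600.0, 720.0), (1440.0, 1560.0)]),
            f_h=piecewise_linear(knots_t, knots_f), alpha_dys=alpha)
    raise ValueError(
        f"unknown scenario '{name}'; available: {', '.join(SCENARIOS)}")


SCENARIOS = ("basal_equilibrium", "calcified_equilibrium",
             "calcified_equilibrium_frozen", "local_tawss_up",
             "local_tawss_down", "heart_rate_ramp", "dysfunction_mild",
             "dysfunction_severe")
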