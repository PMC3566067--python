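"""First-order muscle activation dynamics.

Sarcolemmal depolarization and calcium release are merged into a single
state ``a`` per unit driven by the binary Stim gate:

    da/dt = (Stim - a) / tau,   tau = t_act while Stim = 1, t_deact while 0.

Because Stim is piecewise constant over a simulation step the ODE has an
exact exponential solution, which is the default integrator; an adaptive
Runge-Kutta route (scipy ``solve_ivp``) is kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import solve_ivp

from .config import ActivationConfig, ConfigurationError

__all__ = [
    "ActivationState",
    "activation_rate",
    "exact_step",
    "integrate_activation",
    "ActivationIntegrator",
]

FloatArray = NDArray[np.float64]


@dataclass
class ActivationState:
    """Per-unit activation level, bounded to [0, 1]."""

    a: FloatArray

    @classmethod
    def initial(cls, n_units: int) -> "ActivationState":
        return cls(a=np.zeros(n_units))


def activation_rate(a, stim, t_act: float, t_deact: float):
    """Instantaneous da/dt for activation ``a`` under gate ``stim`` (0 or 1)."""
    if t_act <= 0 or t_deact <= 0:
        raise ConfigurationError("activation time constants must be positive")
    a = np.asarray(a, dtype=np.float64)
    stim = np.asarray(stim, dtype=np.float64)
    tau = np.where(stim > 0, t_act, t_deact)
    return (stim - a) / tau


def exact_step(a, stim, dt: float, t_act, t_deact):
    """Exact solution of the first-order ODE over one constant-Stim interval."""
    a = np.asarray(a, dtype=np.float64)
    stim = np.asarray(stim, dtype=np.float64)
    tau = np.where(stim > 0, t_act, t_deact)
    return stim + (a - stim) * np.exp(-dt / tau)


class ActivationIntegrator:
    """Vectorized per-step activation update with precomputed decay factors.

    The decay factors ``exp(-dt/t_act)`` and ``exp(-dt/t_deact)`` depend only
    on the (fixed) time constants and step size, so they are computed once.
    """

    def __init__(self, t_act: FloatArray, t_deact: FloatArray, dt: float,
                 config: ActivationConfig | None = None):
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        if np.any(t_act <= 0) or np.any(t_deact <= 0):
            raise ConfigurationError("activation time constants must be positive")
        self.t_act = np.asarray(t_act, dtype=np.float64)
        self.t_deact = np.asarray(t_deact, dtype=np.float64)
        self.dt = float(dt)
        self.config = config if config is not None else ActivationConfig()
        self._decay_on = np.exp(-dt / self.t_act)
        self._decay_off = np.exp(-dt / self.t_deact)

    def step(self, a: FloatArray, stim: FloatArray) -> FloatArray:
        if self.config.integrator == "exact":
            decay = np.where(stim > 0, self._decay_on, self._decay_off)
            return stim + (a - stim) * decay
        return self._rk_step(a, stim)

    def _rk_step(self, a: FloatArray, stim: FloatArray) -> FloatArray:
        tau = np.where(stim > 0, self.t_act, self.t_deact)
        sol = solve_ivp(
            lambda _t, y: (stim - y) / tau,
            (0.0, self.dt),
            a,
            method="RK45",
            rtol=self.config.rel_tol,
            atol=self.config.abs_tol,
        )
        return np.clip(sol.y[:, -1], 0.0, 1.0)


def integrate_activation(
    state: ActivationState,
    stim: FloatArray,
    dt: float,
    t_act: FloatArray,
    t_deact: FloatArray,
    config: ActivationConfig | None = None,
) -> ActivationState:
    """Advance all units over one step of constant Stim.

    Matches the closed-form single-unit solution to floating-point accuracy
    for the default exact integrator.
    """
    integ = ActivationIntegrator(np.asarray(t_act, dtype=np.float64),
                                 np.asarray(t_deact, dtype=np.float64),
                                 dt, config)
    return ActivationState(a=integ.step(state.a, np.asarray(stim, dtype=np.float64)))
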