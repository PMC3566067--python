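"""Canonical parameter sets and reference signals for tests and examples."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import motor_pool as mp
from .config import (
    Protocol,
    SimulationConfig,
    mvc_protocol,
    stimulation_protocol,
    submaximal_protocol,
)

__all__ = [
    "default_config",
    "default_pool",
    "canonical_protocols",
    "reference_pulse_train",
]


def default_config() -> SimulationConfig:
    return SimulationConfig()


def default_pool(config: SimulationConfig | None = None) -> mp.MotorUnitPool:
    cfg = config if config is not None else SimulationConfig()
    return mp.build_pool(
        config=cfg.pool,
        glyc_vmax_fold=cfg.metabolic.glyc_vmax_fold,
        glyc_vmax_weighted_mean=cfg.metabolic.glyc_vmax_weighted_mean,
    )


def canonical_protocols() -> dict[str, Protocol]:
    """The three voluntary protocols plus a 20-Hz stimulation reference."""
    return {
        "mvc": mvc_protocol(),
        "submax_50": submaximal_protocol(0.5),
        "submax_20": submaximal_protocol(0.2),
        "stim_20hz": stimulation_protocol(20.0),
    }


def reference_pulse_train(
    fr_hz: float,
    duration_s: float = 1.0,
    dt: float = 0.001,
    pulse_width_s: float = 0.023,
) -> pd.DataFrame:
    """Stim gate of a single unit firing at a constant rate (time, stim)."""
    n = int(round(duration_s / dt))
    state = mp.PoolState.initial(1)
    fr = np.array([fr_hz], dtype=float)
    times = np.arange(1, n + 1) * dt
    stim = np.empty(n)
    for i in range(n):
        state = mp.advance_pulse_trains(state, fr, dt, pulse_width_s)
        stim[i] = state.stim[0]
    return pd.DataFrame({"time_s": times, "stim": stim})
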