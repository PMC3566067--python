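"""Ankle joint: force-dependent moment arm and torque.

Dorsiflexor force stretches the extensor retinaculum, displacing the tendon
anteriorly and lengthening the moment arm.  The moment arm grows affinely
with the ratio of current to maximal summed force, from its resting value
to at most ``(1 + relative range)`` times that value; torque is the plain
product of summed tendon force and current moment arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import JointConfig

__all__ = ["JointParams", "JointState", "moment_arm", "torque", "peak_capacity"]


@dataclass(frozen=True)
class JointParams:
    l_ma0_m: float = 0.027
    l_ma_rel_range: float = 0.249
    f_max_n: float = 1433.4  # sum of per-unit peak forces

    @classmethod
    def from_config(cls, cfg: JointConfig | None, f_max_n: float) -> "JointParams":
        cfg = cfg if cfg is not None else JointConfig()
        return cls(l_ma0_m=cfg.l_ma0_m, l_ma_rel_range=cfg.l_ma_rel_range,
                   f_max_n=f_max_n)


@dataclass
class JointState:
    f_t_n: float = 0.0
    l_ma_m: float = 0.027
    torque_nm: float = 0.0


def moment_arm(f_t: float, params: JointParams) -> float:
    """Current moment arm (m) at summed tendon force ``f_t``.

    Affine in force: ``l_ma0 * (1 + rel_range * f_t / f_max)``.  The force
    ratio is clamped to [0, 1] so transient force overshoot (eccentric
    spikes) cannot push the moment arm past its anatomical range.
    """
    if f_t < 0:
        raise ValueError("tendon force must be non-negative")
    ratio = min(f_t / params.f_max_n, 1.0)
    return params.l_ma0_m * (1.0 + params.l_ma_rel_range * ratio)


def torque(f_t: float, l_ma: float) -> float:
    """Joint torque (N m) = summed tendon force times current moment arm."""
    if f_t < 0:
        raise ValueError("tendon force must be non-negative")
    return f_t * l_ma


def peak_capacity(params: JointParams, total_fmax: float | None = None) -> float:
    """Estimated peak torque capacity (N m).

    Sum of per-unit peak forces times the longest possible moment arm.  An
    upper-bound normalizer for the controller's torque error, not an
    attainable torque (force-length, pennation and firing-rate limits keep
    realized torque below it).
    """
    f = params.f_max_n if total_fmax is None else total_fmax
    if f <= 0:
        raise ValueError("total peak force must be positive")
    return f * params.l_ma0_m * (1.0 + params.l_ma_rel_range)


def joint_update(f_t: float, params: JointParams) -> JointState:
    """Evaluate moment arm and torque for the current summed force."""
    l_ma = moment_arm(max(f_t, 0.0), params)
    return JointState(f_t_n=f_t, l_ma_m=l_ma, torque_nm=torque(f_t, l_ma))
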