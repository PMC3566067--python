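"""Closed-loop excitation controller.

Each step the normalized torque error ``T_diff = (T_t - T_c) / T_capacity``
nudges the scalar excitation ``S``: upward steps use gain ``k_up``, downward
steps are attenuated by the relaxation factor ``R`` (default 0.7) to avoid
unrealistically fast relaxation.  ``S`` is clamped to [0, 1].  High gains
are intentional: the resulting onset overshoot/oscillation mimics empirical
torque records and is not damped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ControllerConfig, Protocol

__all__ = ["ControllerState", "update_excitation", "target_trajectory"]


@dataclass
class ControllerState:
    s: float = 0.0
    t_target_nm: float = 0.0
    t_diff: float = 0.0


def update_excitation(
    s: float,
    t_c: float,
    t_t: float,
    t_cap: float,
    gains: ControllerConfig | None = None,
) -> float:
    """One controller update of the excitation signal.

    ``S' = S + k_up * T_diff`` when torque is below target, and
    ``S' = S + k_down * R * T_diff`` when above, clamped to [0, 1].
    """
    if t_cap <= 0:
        raise ValueError("torque capacity must be positive")
    g = gains if gains is not None else ControllerConfig()
    t_diff = (t_t - t_c) / t_cap
    if t_diff > 0:
        s = s + g.k_up * t_diff
    elif t_diff < 0:
        s = s + g.k_down * g.r_down * t_diff
    return min(max(s, 0.0), 1.0)


def target_trajectory(protocol: Protocol, t: float, t_cap: float) -> float:
    """Target torque (N m) at time ``t`` for a voluntary protocol.

    Zero before onset and after offset; ``target_fraction * t_cap`` during
    the hold (no anticipatory ramp).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if protocol.mode != "voluntary":
        raise ValueError(f"not a voluntary protocol: {protocol.mode!r}")
    if protocol.onset_s <= t <= protocol.offset_s:
        return protocol.target_fraction * t_cap
    return 0.0
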