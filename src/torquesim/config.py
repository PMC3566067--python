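"""Configuration objects for the torque-simulation model.

All model constants live here as plain dataclasses with physiologic
defaults for the human tibialis anterior / ankle dorsiflexion system.
Every field can be overridden from a YAML mapping via
:func:`SimulationConfig.from_dict` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PoolConfig",
    "ActivationConfig",
    "MuscleConfig",
    "MetabolicConfig",
    "JointConfig",
    "ControllerConfig",
    "SimulationConfig",
    "Protocol",
    "ConfigurationError",
    "load_config",
    "load_protocol",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value is inconsistent or out of range."""


@dataclass(frozen=True)
class PoolConfig:
    """Motor-neuron pool layout.

    ``n_units`` motor neurons with exponentially distributed recruitment
    thresholds spanning an ``a_r``-fold range (highest threshold at
    ``rt_max`` on the excitation scale), a common minimum firing rate and
    a narrow band of peak firing rates, and peak tetanic forces spanning
    ``force_range``-fold and summing to ``total_fmax_n``.
    """

    n_units: int = 120
    a_r: float = 30.0
    rt_max: float = 0.7
    mfr_hz: float = 8.0
    pfr_min_hz: float = 46.0
    pfr_max_hz: float = 56.0
    total_fmax_n: float = 1433.4
    force_range: float = 100.0
    pulse_width_s: float = 0.023
    # activation/deactivation time constants, (unit 1, unit n) endpoints;
    # low-threshold units are the slowest
    t_act_first_s: float = 0.060
    t_act_last_s: float = 0.039
    t_deact_first_s: float = 0.092
    t_deact_last_s: float = 0.064

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigurationError("n_units must be >= 2")
        if self.a_r <= 1:
            raise ConfigurationError("a_r must be > 1")
        if self.total_fmax_n <= 0:
            raise ConfigurationError("total_fmax_n must be > 0")
        if not 0 < self.rt_max <= 1:
            raise ConfigurationError("rt_max must lie in (0, 1]")
        if self.force_range <= 1:
            raise ConfigurationError("force_range must be > 1")


@dataclass(frozen=True)
class ActivationConfig:
    integrator: str = "exact"  # "exact" | "rk45"
    abs_tol: float = 1e-10
    rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.integrator not in ("exact", "rk45"):
            raise ConfigurationError(
                f"unknown activation integrator {self.integrator!r}"
            )


@dataclass(frozen=True)
class MuscleConfig:
    """Hill-type muscle architecture and curve constants (shared by all units)."""

    l_ce_opt_m: float = 0.077
    phi_opt_rad: float = 0.17
    l_see_slack_m: float = 0.223
    fl_width: float = 0.56
    fl_shape: str = "parabola"  # "parabola" | "gaussian"
    a_rel: float = 0.41
    b_rel: float = 4.5  # s^-1, normalized to optimal CE length
    f_ecc: float = 1.5
    ecc_slope_factor: float = 1.0
    see_strain_at_fmax: float = 0.09
    n_substeps: int = 8
    # cap on |v_ce| / l_ce_opt during the equilibrium inversion (s^-1);
    # bounds the clamped eccentric branch so explicit stepping stays stable
    v_rel_cap: float = 26.0

    def __post_init__(self) -> None:
        if self.l_ce_opt_m <= 0 or self.l_see_slack_m <= 0:
            raise ConfigurationError("muscle lengths must be positive")
        if self.fl_shape not in ("parabola", "gaussian"):
            raise ConfigurationError(f"unknown fl_shape {self.fl_shape!r}")
        if self.f_ecc <= 1:
            raise ConfigurationError("f_ecc must exceed 1")
        if self.n_substeps < 1:
            raise ConfigurationError("n_substeps must be >= 1")


@dataclass(frozen=True)
class MetabolicConfig:
    """Intracellular bioenergetics constants.

    The phosphate pool ([Pi] + [PCr]) and [ATP] are conserved quantities.
    The Pi-appearance coefficients (``pi_rate_p1``/``p3``, with p2 = p1 so
    the rate vanishes at zero activation) are repo-calibrated defaults, not
    published values.
    """

    phosphate_pool_mm: float = 42.5
    atp_mm: float = 8.2
    km_glycolysis_mm: float = 18.94
    glyc_vmax_fold: float = 4.0
    glyc_vmax_weighted_mean: float = 1.5  # mM ATP / s, fmax-weighted
    h_per_glycolytic_atp: float = 2.0 / 3.0
    theta_gain: float = 1.4
    pk_ck: float = 6.75
    pk_pi: float = 6.75
    beta0_slykes: float = 20.0
    pi_rest_mm: float = 4.5
    ph_rest: float = 7.0
    pi_rate_p1: float = 0.45
    pi_rate_p3: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "phosphate_pool_mm",
            "atp_mm",
            "km_glycolysis_mm",
            "beta0_slykes",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.pi_rest_mm <= self.phosphate_pool_mm:
            raise ConfigurationError("pi_rest_mm must lie within the phosphate pool")


@dataclass(frozen=True)
class JointConfig:
    l_ma0_m: float = 0.027
    l_ma_rel_range: float = 0.249

    def __post_init__(self) -> None:
        if self.l_ma0_m <= 0:
            raise ConfigurationError("l_ma0_m must be positive")
        if not 0 <= self.l_ma_rel_range < 1:
            raise ConfigurationError("l_ma_rel_range must lie in [0, 1)")


@dataclass(frozen=True)
class ControllerConfig:
    r_down: float = 0.7
    k_up: float = 0.013
    k_down: float = 0.013

    def __post_init__(self) -> None:
        if not 0 < self.r_down <= 1:
            raise ConfigurationError("r_down must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Top-level configuration bundle for a simulation run."""

    dt_s: float = 0.001
    output_stride: int = 1
    seed: int = 0  # unused (model is deterministic); kept for interface stability
    pool: PoolConfig = field(default_factory=PoolConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    muscle: MuscleConfig = field(default_factory=MuscleConfig)
    metabolic: MetabolicConfig = field(default_factory=MetabolicConfig)
    joint: JointConfig = field(default_factory=JointConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ConfigurationError("dt_s must be positive")
        if self.output_stride < 1:
            raise ConfigurationError("output_stride must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any] | None) -> "SimulationConfig":
        if not data:
            return cls()
        data = dict(data)
        kwargs: dict[str, Any] = {}
        sections = {
            "pool": PoolConfig,
            "activation": ActivationConfig,
            "muscle": MuscleConfig,
            "metabolic": MetabolicConfig,
            "joint": JointConfig,
            "controller": ControllerConfig,
        }
        for key, klass in sections.items():
            if key in data:
                kwargs[key] = klass(**data.pop(key))
        for key in ("dt_s", "output_stride", "seed"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ConfigurationError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Protocol:
    """Description of one contraction protocol.

    ``voluntary`` mode drives the model with the feedback controller toward
    ``target_fraction`` of estimated peak torque capacity between ``onset_s``
    and ``offset_s``.  ``stimulation`` mode bypasses the controller and
    delivers a synchronous pulse train at ``freq_hz`` to every unit starting
    at ``onset_s``.
    """

    mode: str = "voluntary"  # "voluntary" | "stimulation"
    target_fraction: float = 1.1
    freq_hz: float = 20.0
    onset_s: float = 1.0
    offset_s: float = 13.0
    duration_s: float = 14.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("voluntary", "stimulation"):
            raise ConfigurationError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "stimulation" and self.freq_hz <= 0:
            raise ConfigurationError("stimulation frequency must be positive")
        if self.onset_s < 0 or self.offset_s < self.onset_s:
            raise ConfigurationError("require 0 <= onset_s <= offset_s")
        if self.duration_s < self.offset_s:
            raise ConfigurationError("duration_s must cover the protocol offset")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Protocol":
        return cls(**dict(data))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def mvc_protocol(hold_s: float = 12.0, onset_s: float = 1.0,
                 tail_s: float = 1.0) -> Protocol:
    """Maximal effort: target held above attainable torque to saturate S."""
    return Protocol(mode="voluntary", target_fraction=1.10, name="mvc",
                    onset_s=onset_s, offset_s=onset_s + hold_s,
                    duration_s=onset_s + hold_s + tail_s)


def submaximal_protocol(fraction: float, hold_s: float = 12.0,
                        onset_s: float = 1.0, tail_s: float = 1.0) -> Protocol:
    return Protocol(mode="voluntary", target_fraction=fraction,
                    name=f"submax_{int(round(fraction * 100))}",
                    onset_s=onset_s, offset_s=onset_s + hold_s,
                    duration_s=onset_s + hold_s + tail_s)


def stimulation_protocol(freq_hz: float, onset_s: float = 0.2,
                         duration_s: float = 2.5) -> Protocol:
    return Protocol(mode="stimulation", freq_hz=freq_hz, onset_s=onset_s,
                    offset_s=duration_s, duration_s=duration_s,
                    name=f"stim_{freq_hz:g}hz")


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data)


def load_protocol(path: str | Path) -> Protocol:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"protocol file {path} must contain a mapping")
    return Protocol.from_dict(data)
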