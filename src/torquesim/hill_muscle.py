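"""Hill-type muscle models: contractile element in series with an elastic tendon.

Each of the pool's units drives its own muscle model; all units share one
architecture (lengths, pennation, curve constants) and differ only in peak
force and kinetics.  The whole muscle-tendon unit (MTU) length is constant
(isometric contraction), but contractile-element (CE) and series-elastic
(SEE) lengths redistribute: at every instant the SEE force equals the
along-tendon component of the CE force, and the CE velocity follows from
inverting the force-velocity relation at the force the SEE demands.

Conventions: CE shortening velocity is negative; velocities are normalized
by optimal CE length when fed through the force-velocity curve; pennation
follows the constant-thickness rule ``l_ce * sin(phi) = const``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .config import MuscleConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MuscleArchitecture",
    "MuscleState",
    "force_length",
    "force_velocity",
    "inverse_force_velocity",
    "see_force",
    "step_muscle",
    "total_force",
]

FloatArray = NDArray[np.float64]

_F_CLAMP_MARGIN = 1e-4  # fraction of f_ecc kept clear of the eccentric asymptote


@dataclass(frozen=True)
class MuscleArchitecture:
    """Shared geometry and Hill-curve constants, derived from :class:`MuscleConfig`."""

    l_ce_opt: float
    l_see_slack: float
    l_mtu: float
    phi_opt: float
    thickness: float  # l_ce_opt * sin(phi_opt), constant
    fl_width: float
    fl_shape: str
    a_rel: float
    b_rel: float
    f_ecc: float
    ecc_slope_factor: float
    see_strain_at_fmax: float
    v_rel_cap: float

    @classmethod
    def from_config(cls, cfg: MuscleConfig | None = None) -> "MuscleArchitecture":
        cfg = cfg if cfg is not None else MuscleConfig()
        phi = cfg.phi_opt_rad
        # rest configuration is force-free with the CE at optimum: the MTU
        # length is sized so the SEE sits exactly at slack there
        l_mtu = cfg.l_see_slack_m + cfg.l_ce_opt_m * np.cos(phi)
        return cls(
            l_ce_opt=cfg.l_ce_opt_m,
            l_see_slack=cfg.l_see_slack_m,
            l_mtu=l_mtu,
            phi_opt=phi,
            thickness=cfg.l_ce_opt_m * np.sin(phi),
            fl_width=cfg.fl_width,
            fl_shape=cfg.fl_shape,
            a_rel=cfg.a_rel,
            b_rel=cfg.b_rel,
            f_ecc=cfg.f_ecc,
            ecc_slope_factor=cfg.ecc_slope_factor,
            see_strain_at_fmax=cfg.see_strain_at_fmax,
            v_rel_cap=cfg.v_rel_cap,
        )

    @property
    def v_max_rel(self) -> float:
        """Maximal shortening velocity in optimal lengths per second."""
        return self.b_rel / self.a_rel

    def pennation(self, l_ce):
        """Pennation angle at CE length ``l_ce`` (constant-thickness rule)."""
        s = np.clip(self.thickness / np.asarray(l_ce, dtype=np.float64), -1.0, 1.0)
        return np.arcsin(s)

    def cos_pennation(self, l_ce):
        s = np.clip(self.thickness / np.asarray(l_ce, dtype=np.float64), 0.0, 1.0)
        return np.sqrt(1.0 - s * s)


@dataclass
class MuscleState:
    """Per-unit CE length/velocity, pennation and tendon force."""

    l_ce: FloatArray
    v_ce: FloatArray
    phi: FloatArray
    force_n: FloatArray

    @classmethod
    def rest(cls, arch: MuscleArchitecture, n_units: int) -> "MuscleState":
        """Force-free configuration: SEE at slack, CE at its optimum."""
        l_ce = np.full(n_units, arch.l_ce_opt)
        return cls(
            l_ce=l_ce,
            v_ce=np.zeros(n_units),
            phi=np.asarray(arch.pennation(l_ce)),
            force_n=np.zeros(n_units),
        )

    def copy(self) -> "MuscleState":
        return MuscleState(self.l_ce.copy(), self.v_ce.copy(),
                           self.phi.copy(), self.force_n.copy())


def force_length(l_ce, arch: MuscleArchitecture):
    """Active force-length scale: 1 at the optimum, 0 at relative lengths 1±W."""
    l_ce = np.asarray(l_ce, dtype=np.float64)
    if np.any(l_ce <= 0):
        raise ValueError("contractile-element length must be positive")
    x = (l_ce / arch.l_ce_opt - 1.0) / arch.fl_width
    if arch.fl_shape == "gaussian":
        return np.exp(-4.0 * x * x)
    return np.maximum(0.0, 1.0 - x * x)


def force_velocity(v_ce, arch: MuscleArchitecture):
    """Force-velocity scale (1 at v=0; shortening negative).

    Concentric branch is the classic rectangular hyperbola reaching zero at
    the maximal shortening velocity; the eccentric branch rises toward the
    ``f_ecc`` asymptote with a slope at v = 0 equal to ``ecc_slope_factor``
    times the concentric slope (factor 1 makes the curve differentiable).
    """
    u = np.asarray(v_ce, dtype=np.float64) / arch.l_ce_opt
    a_rel, b_rel = arch.a_rel, arch.b_rel
    # concentric: f = b(1+a)/(w+b) - a with w = -u (shortening speed)
    w = np.maximum(-u, 0.0)
    f_con = b_rel * (1.0 + a_rel) / (w + b_rel) - a_rel
    f_con = np.maximum(f_con, 0.0)
    # eccentric: f = (F_ecc*u + d)/(u + d), matched slope at zero
    slope0 = (1.0 + a_rel) / b_rel
    d = (arch.f_ecc - 1.0) / (arch.ecc_slope_factor * slope0)
    u_pos = np.maximum(u, 0.0)
    f_ecc = (arch.f_ecc * u_pos + d) / (u_pos + d)
    return np.where(u >= 0, f_ecc, f_con)


def inverse_force_velocity(f, arch: MuscleArchitecture):
    """CE velocity (m/s) at which the force-velocity scale equals ``f``.

    ``f`` is clamped to the attainable range (0, f_ecc); the returned
    velocity is additionally capped at ``±v_rel_cap`` optimal lengths per
    second so the clamped eccentric branch stays bounded.
    """
    a_rel, b_rel = arch.a_rel, arch.b_rel
    f = np.asarray(f, dtype=np.float64)
    f = np.clip(f, 0.0, arch.f_ecc * (1.0 - _F_CLAMP_MARGIN))
    # concentric inversion (f <= 1): w = b(1+a)/(f+a) - b, u = -w
    u_con = -(b_rel * (1.0 + a_rel) / (f + a_rel) - b_rel)
    slope0 = (1.0 + a_rel) / b_rel
    d = (arch.f_ecc - 1.0) / (arch.ecc_slope_factor * slope0)
    with np.errstate(divide="ignore"):
        u_ecc = d * (f - 1.0) / (arch.f_ecc - f)
    u = np.where(f <= 1.0, u_con, u_ecc)
    u = np.clip(u, -arch.v_rel_cap, arch.v_rel_cap)
    return u * arch.l_ce_opt


def see_force(l_see, arch: MuscleArchitecture, fmax):
    """Series-elastic force: zero below slack, quadratic in strain above it.

    Reaches ``fmax`` at strain ``see_strain_at_fmax``.
    """
    l_see = np.asarray(l_see, dtype=np.float64)
    strain = np.maximum((l_see - arch.l_see_slack) / arch.l_see_slack, 0.0)
    return np.asarray(fmax) * (strain / arch.see_strain_at_fmax) ** 2


def _see_length(l_ce, arch: MuscleArchitecture):
    return arch.l_mtu - l_ce * np.asarray(arch.cos_pennation(l_ce))


def step_muscle(
    state: MuscleState,
    a,
    arch: MuscleArchitecture,
    fmax,
    dt: float,
    n_substeps: int = 8,
) -> MuscleState:
    """Advance the CE/SEE equilibrium ODE for all units over one outer step.

    At each substep the SEE force (set by the current length partition)
    prescribes the CE force; inverting the force-velocity relation yields
    the CE velocity, which is integrated explicitly.  Substepping keeps the
    explicit update stable against the stiff SEE at low activation.
    """
    a = np.asarray(a, dtype=np.float64)
    fmax = np.asarray(fmax, dtype=np.float64)
    h = dt / n_substeps
    l_ce = state.l_ce.copy()
    v_ce = np.zeros_like(l_ce)

    l_ce_min = arch.thickness * 1.0001
    l_ce_max = np.hypot(arch.l_mtu, arch.thickness)

    for _ in range(n_substeps):
        cos_phi = arch.cos_pennation(l_ce)
        f_see = see_force(_see_length(l_ce, arch), arch, fmax)
        f_l = force_length(l_ce, arch)
        # along-fiber force demanded of the CE, as a force-velocity scale
        denom = a * fmax * f_l * cos_phi
        active = denom > 1e-9 * fmax
        with np.errstate(divide="ignore", invalid="ignore"):
            f_need = np.where(active, f_see / np.maximum(denom, 1e-300), np.inf)
        if logger.isEnabledFor(logging.DEBUG):
            n_clamped = int(np.count_nonzero(
                f_need > arch.f_ecc * (1.0 - _F_CLAMP_MARGIN)
            ))
            if n_clamped:
                logger.debug(
                    "force-velocity inversion clamped for %d unit(s)", n_clamped
                )
        # inactive units: no CE force available; lengthen at the capped rate
        # if the SEE still holds force, otherwise rest
        v_ce = np.asarray(inverse_force_velocity(f_need, arch))
        v_ce = np.where(active | (f_see > 1e-9 * fmax), v_ce, 0.0)
        l_ce = np.clip(l_ce + v_ce * h, l_ce_min, l_ce_max)

    cos_phi = arch.cos_pennation(l_ce)
    force = np.asarray(see_force(_see_length(l_ce, arch), arch, fmax))
    return MuscleState(
        l_ce=l_ce,
        v_ce=v_ce,
        phi=np.asarray(arch.pennation(l_ce)),
        force_n=force,
    )


def total_force(forces_n) -> float:
    """Linear summation of per-unit tendon forces."""
    forces_n = np.asarray(forces_n, dtype=np.float64)
    if np.any(forces_n < 0):
        raise ValueError("per-unit tendon forces must be non-negative")
    return float(forces_n.sum())


def isometric_steady_force(
    a: float, arch: MuscleArchitecture, fmax: float
) -> tuple[float, float]:
    """Fixed point of the series-equilibrium ODE at constant activation.

    Solves for the CE length where the SEE force equals the along-tendon
    isometric CE force (v = 0) by bracketed 1-D root finding.  Returns
    ``(l_ce, force)``.  Used as an independent oracle for :func:`step_muscle`.
    """
    from scipy.optimize import brentq

    def residual(l_ce: float) -> float:
        f_see = float(see_force(_see_length(l_ce, arch), arch, fmax))
        f_ce = a * fmax * float(force_length(l_ce, arch)) * float(
            arch.cos_pennation(l_ce)
        )
        return f_see - f_ce

    if a <= 0:
        return arch.l_ce_opt, 0.0
    # bracket: at the optimum the SEE is slack (residual < 0); at the short
    # end of the force-length curve the CE produces nothing (residual > 0)
    lo = max(arch.l_ce_opt * (1.0 - arch.fl_width), arch.thickness) + 1e-9
    hi = arch.l_ce_opt
    l_star = brentq(residual, lo, hi, xtol=1e-12)
    return l_star, float(see_force(_see_length(l_star, arch), arch, fmax))
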