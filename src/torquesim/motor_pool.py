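"""Motor-neuron pool: recruitment thresholds, rate coding and pulse trains.

The pool converts a scalar excitation signal ``S`` in [0, 1] into per-unit
firing rates (recruitment + rate coding) and binary ``Stim`` pulse trains
that gate sarcoplasmic-reticulum calcium release.  In electrical-stimulation
mode every unit receives the same synchronous train, bypassing recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .config import ConfigurationError, PoolConfig

__all__ = [
    "MotorUnitParams",
    "MotorUnitPool",
    "PoolState",
    "build_pool",
    "firing_rate",
    "rate_gain",
    "advance_pulse_trains",
    "stimulation_train",
]

FloatArray = NDArray[np.float64]


@dataclass(frozen=True)
class MotorUnitParams:
    """Parameters of a single motor unit (1-based index ``m``)."""

    m: int
    mu_rt: float  # recruitment threshold on the excitation scale
    mfr_hz: float  # minimum firing rate
    pfr_hz: float  # peak firing rate
    t_act_s: float  # activation time constant
    t_deact_s: float  # deactivation time constant
    fmax_n: float  # peak isometric force
    glyc_vmax_mm_s: float  # maximal non-oxidative glycolytic ATP rate


@dataclass(frozen=True)
class MotorUnitPool:
    """Struct-of-arrays view of the full pool; indexable as a sequence."""

    mu_rt: FloatArray
    mfr_hz: FloatArray
    pfr_hz: FloatArray
    t_act_s: FloatArray
    t_deact_s: FloatArray
    fmax_n: FloatArray
    glyc_vmax_mm_s: FloatArray
    pulse_width_s: float = 0.023

    @property
    def n_units(self) -> int:
        return self.mu_rt.size

    def __len__(self) -> int:
        return self.n_units

    def __getitem__(self, i: int) -> MotorUnitParams:
        if not -self.n_units <= i < self.n_units:
            raise IndexError(i)
        i %= self.n_units
        return MotorUnitParams(
            m=i + 1,
            mu_rt=float(self.mu_rt[i]),
            mfr_hz=float(self.mfr_hz[i]),
            pfr_hz=float(self.pfr_hz[i]),
            t_act_s=float(self.t_act_s[i]),
            t_deact_s=float(self.t_deact_s[i]),
            fmax_n=float(self.fmax_n[i]),
            glyc_vmax_mm_s=float(self.glyc_vmax_mm_s[i]),
        )


def _geometric_profile(n: int, fold: float) -> FloatArray:
    """Exponential profile over unit rank with an exact ``fold`` max/min ratio."""
    m = np.arange(n, dtype=np.float64)
    return np.exp(m * np.log(fold) / (n - 1))


def build_pool(
    n: int | None = None,
    a_r: float | None = None,
    total_fmax: float | None = None,
    config: PoolConfig | None = None,
    *,
    glyc_vmax_fold: float = 4.0,
    glyc_vmax_weighted_mean: float = 1.5,
) -> MotorUnitPool:
    """Construct the motor-unit pool deterministically from its configuration.

    Parameters
    ----------
    n, a_r, total_fmax
        Convenience overrides for the corresponding ``config`` fields.
    config
        Pool layout; defaults to :class:`PoolConfig` defaults (120 units,
        30-fold threshold range topping out at 0.7, forces spanning 100-fold
        and summing to 1433.4 N).
    glyc_vmax_fold, glyc_vmax_weighted_mean
        Shape (fold range) and fmax-weighted mean of the per-unit maximal
        glycolytic ATP rates (mM/s).

    Notes
    -----
    Recruitment thresholds follow ``muRT(m) = rt_max * A_r**((m-n)/(n-1))``
    so the highest/lowest ratio is exactly ``A_r``.  Peak firing rates are
    linear in threshold from ``pfr_min`` to ``pfr_max``; activation and
    deactivation time constants are linear in rank with the low-threshold
    units slowest.  Peak forces are geometric with an exact ``force_range``
    ratio, rescaled to the configured total.
    """
    cfg = config if config is not None else PoolConfig()
    overrides = {}
    if n is not None:
        overrides["n_units"] = int(n)
    if a_r is not None:
        overrides["a_r"] = float(a_r)
    if total_fmax is not None:
        overrides["total_fmax_n"] = float(total_fmax)
    if overrides:
        import dataclasses

        cfg = dataclasses.replace(cfg, **overrides)

    n_units = cfg.n_units
    mu_rt = cfg.rt_max * _geometric_profile(n_units, cfg.a_r) / cfg.a_r

    pfr = cfg.pfr_min_hz + (cfg.pfr_max_hz - cfg.pfr_min_hz) * (
        (mu_rt - mu_rt[0]) / (mu_rt[-1] - mu_rt[0])
    )
    mfr = np.full(n_units, cfg.mfr_hz)

    fmax = _geometric_profile(n_units, cfg.force_range)
    fmax *= cfg.total_fmax_n / fmax.sum()

    # kinetics co-vary with recruitment threshold (like the peak firing
    # rates): the numerous low-threshold units keep the slowest constants
    rt_rank = (mu_rt - mu_rt[0]) / (mu_rt[-1] - mu_rt[0])
    t_act = cfg.t_act_first_s + (cfg.t_act_last_s - cfg.t_act_first_s) * rt_rank
    t_deact = cfg.t_deact_first_s + (cfg.t_deact_last_s - cfg.t_deact_first_s) * rt_rank

    # glycolytic capacity rises with threshold (same ordering as fmax); the
    # scale is fixed so the fmax-weighted mean matches the configured value
    glyc = _geometric_profile(n_units, glyc_vmax_fold)
    glyc *= glyc_vmax_weighted_mean / (np.sum(fmax * glyc) / fmax.sum())

    return MotorUnitPool(
        mu_rt=mu_rt,
        mfr_hz=mfr,
        pfr_hz=pfr,
        t_act_s=t_act,
        t_deact_s=t_deact,
        fmax_n=fmax,
        glyc_vmax_mm_s=glyc,
        pulse_width_s=cfg.pulse_width_s,
    )


def rate_gain(pool: MotorUnitPool) -> float:
    """Global excitation-to-rate gain.

    Chosen so the highest-threshold unit reaches its peak firing rate
    exactly at S = 1; lower-threshold units saturate earlier.
    """
    rt_top = float(pool.mu_rt[-1])
    if rt_top >= 1.0:
        raise ConfigurationError("highest recruitment threshold must be < 1")
    return (float(pool.pfr_hz[-1]) - float(pool.mfr_hz[-1])) / (1.0 - rt_top)


def firing_rate(
    s: float, pool: MotorUnitPool, gain: float | None = None
) -> FloatArray:
    """Per-unit firing rate (Hz) at excitation ``s``.

    Zero below each unit's recruitment threshold, then
    ``min(PFR, MFR + G * (s - muRT))``.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"excitation S must lie in [0, 1], got {s}")
    g = rate_gain(pool) if gain is None else gain
    fr = np.minimum(pool.pfr_hz, pool.mfr_hz + g * (s - pool.mu_rt))
    fr[s < pool.mu_rt] = 0.0
    return fr


@dataclass
class PoolState:
    """Per-unit pulse-train state: firing rate, IPI phase counter and Stim gate."""

    fr_hz: FloatArray
    phase_s: FloatArray
    stim: FloatArray

    @classmethod
    def initial(cls, n_units: int) -> "PoolState":
        return cls(
            fr_hz=np.zeros(n_units),
            phase_s=np.zeros(n_units),
            stim=np.zeros(n_units),
        )

    @property
    def ipi_s(self) -> FloatArray:
        with np.errstate(divide="ignore"):
            return np.where(self.fr_hz > 0, 1.0 / self.fr_hz, np.inf)


_GOLDEN = 0.6180339887498949


def recruitment_phase_offsets(n_units: int) -> FloatArray:
    """Deterministic per-unit phase offsets (fractions of an IPI).

    Units recruited at the same instant start their interpulse counters at
    staggered phases (a golden-ratio low-discrepancy sequence), mimicking
    the asynchronous discharge of real motor units; without this, jointly
    recruited units fire in lockstep and their unfused force ripple adds
    coherently.
    """
    return ((np.arange(n_units) + 1) * _GOLDEN) % 1.0


def advance_pulse_trains(
    state: PoolState,
    fr_hz: FloatArray,
    dt: float,
    pulse_width_s: float = 0.023,
    phase_offsets: FloatArray | None = None,
) -> PoolState:
    """Advance every unit's interpulse-interval counter by ``dt``.

    A unit's counter runs through its current IPI (= 1/FR) and wraps; the
    Stim gate is 1 during the first ``pulse_width_s`` of each IPI.  Inactive
    units (FR = 0) have their counter reset and Stim forced to 0.  If the
    pulse width meets or exceeds the IPI the gate never closes (fused
    stimulation).  ``phase_offsets`` (fractions of an IPI) stagger the
    counters of newly recruited units; by default units start at phase 0
    and pulse immediately on recruitment.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    fr = np.asarray(fr_hz, dtype=np.float64)
    if np.any(~np.isfinite(fr)) or np.any(fr < 0):
        raise ValueError("firing rates must be finite and non-negative")

    active = fr > 0
    with np.errstate(divide="ignore"):
        ipi = np.where(active, 1.0 / np.maximum(fr, 1e-300), np.inf)
    phase = state.phase_s
    if phase_offsets is not None:
        newly = active & (state.fr_hz <= 0)
        if newly.any():
            phase = np.where(newly, phase_offsets * ipi - dt, phase)
    phase = phase + dt
    phase = np.where(active & (phase >= ipi), phase % ipi, phase)
    phase = np.where(active, phase, 0.0)
    stim = np.where(active & (phase < pulse_width_s), 1.0, 0.0)
    return PoolState(fr_hz=fr, phase_s=phase, stim=stim)


def stimulation_train(
    freq_hz: float,
    t: float,
    n_units: int,
    pulse_width_s: float = 0.023,
) -> FloatArray:
    """Synchronous electrical-stimulation gate at time ``t`` after train onset.

    Every unit receives an identical train: Stim = 1 during the first
    ``pulse_width_s`` of each 1/freq period.  Above ~1/pulse_width Hz the
    pulse width exceeds the period and the train saturates at 1.
    """
    if freq_hz <= 0:
        raise ValueError("stimulation frequency must be positive")
    if t < 0:
        return np.zeros(n_units)
    period = 1.0 / freq_hz
    on = (t % period) < pulse_width_s or period <= pulse_width_s
    return np.full(n_units, 1.0 if on else 0.0)
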