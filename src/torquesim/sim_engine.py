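"""Simulation engine: the per-millisecond forward loop over all motor units.

Each outer step executes, in order: excitation update (controller or
stimulation schedule) -> pool rate coding and pulse trains -> activation
dynamics -> Hill muscle equilibrium -> force summation -> joint torque ->
metabolic update.  Mechanical and activation states use exact/sub-stepped
integration inside the outer step; metabolic states advance by explicit
Euler at the outer step (their rates are slow on that scale).

The model contains no randomness: identical configuration and protocol
yield bit-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import bioenergetics as bio
from . import controller as ctrl
from . import hill_muscle as hill
from . import joint_mechanics as joint
from . import motor_pool as mp
from .activation_dynamics import ActivationIntegrator
from .config import Protocol, SimulationConfig

__all__ = [
    "SimResult",
    "run_protocol",
    "run_voluntary",
    "run_stimulation",
    "torque_frequency_curve",
    "write_result",
    "read_result",
]

FloatArray = NDArray[np.float64]


@dataclass
class SimResult:
    """Full time-series output of one simulation run.

    All arrays share the time grid; per-unit arrays have shape
    ``(n_samples, n_units)``.
    """

    time_s: FloatArray
    s: FloatArray
    target_nm: FloatArray
    torque_nm: FloatArray
    force_total_n: FloatArray
    l_ma_m: FloatArray
    fr_hz: FloatArray
    stim: FloatArray
    activation: FloatArray
    force_n: FloatArray
    pi_mm: FloatArray
    ph: FloatArray
    pooled_pi_mm: FloatArray
    pooled_ph: FloatArray
    pooled_h2po4_mm: FloatArray
    config: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.fr_hz.shape[1]

    @property
    def pooled_pcr_mm(self) -> FloatArray:
        return self.config["metabolic"]["phosphate_pool_mm"] - self.pooled_pi_mm

    @property
    def pcr_mm(self) -> FloatArray:
        return self.config["metabolic"]["phosphate_pool_mm"] - self.pi_mm

    @property
    def h2po4_mm(self) -> FloatArray:
        """Per-unit diprotonated phosphate, derived from [Pi] and pH."""
        pk = self.config["metabolic"]["pk_pi"]
        return bio.h2po4(self.pi_mm, self.ph, pk)

    def peak_torque(self) -> float:
        return float(self.torque_nm.max())

    def to_frame(self, per_unit: bool = False) -> pd.DataFrame:
        """Wide table of the run; optionally includes per-unit columns."""
        data: dict[str, FloatArray] = {
            "time_s": self.time_s,
            "s": self.s,
            "target_nm": self.target_nm,
            "torque_nm": self.torque_nm,
            "force_total_n": self.force_total_n,
            "l_ma_m": self.l_ma_m,
            "pooled_pi_mm": self.pooled_pi_mm,
            "pooled_ph": self.pooled_ph,
            "pooled_h2po4_mm": self.pooled_h2po4_mm,
        }
        if per_unit:
            for name, arr in (
                ("fr_hz", self.fr_hz),
                ("stim", self.stim),
                ("activation", self.activation),
                ("force_n", self.force_n),
                ("pi_mm", self.pi_mm),
                ("ph", self.ph),
            ):
                for u in range(self.n_units):
                    data[f"{name}_unit_{u + 1}"] = arr[:, u]
        return pd.DataFrame(data)


def _config_hash(config: dict, protocol: dict) -> str:
    payload = json.dumps({"config": config, "protocol": protocol},
                         sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_protocol(protocol: Protocol, config: SimulationConfig | None = None) -> SimResult:
    """Run one protocol (voluntary or stimulation) to completion."""
    cfg = config if config is not None else SimulationConfig()
    dt = cfg.dt_s
    n_steps = int(round(protocol.duration_s / dt))
    pool = mp.build_pool(
        config=cfg.pool,
        glyc_vmax_fold=cfg.metabolic.glyc_vmax_fold,
        glyc_vmax_weighted_mean=cfg.metabolic.glyc_vmax_weighted_mean,
    )
    n = pool.n_units
    gain = mp.rate_gain(pool)

    arch = hill.MuscleArchitecture.from_config(cfg.muscle)
    joint_params = joint.JointParams.from_config(cfg.joint, float(pool.fmax_n.sum()))
    t_cap = joint.peak_capacity(joint_params)
    consts = bio.MetabolicConstants.from_config(cfg.metabolic)

    pool_state = mp.PoolState.initial(n)
    act = np.zeros(n)
    act_integrator = ActivationIntegrator(pool.t_act_s, pool.t_deact_s, dt,
                                          cfg.activation)
    muscle = hill.MuscleState.rest(arch, n)
    met = bio.MetabolicState.resting(
        n, consts, pi_rest_mm=cfg.metabolic.pi_rest_mm, ph_rest=cfg.metabolic.ph_rest
    )

    stride = cfg.output_stride
    kept = np.arange(0, n_steps + 1, stride)
    n_out = kept.size
    out = SimResult(
        time_s=kept * dt,
        s=np.zeros(n_out),
        target_nm=np.zeros(n_out),
        torque_nm=np.zeros(n_out),
        force_total_n=np.zeros(n_out),
        l_ma_m=np.full(n_out, joint_params.l_ma0_m),
        fr_hz=np.zeros((n_out, n)),
        stim=np.zeros((n_out, n)),
        activation=np.zeros((n_out, n)),
        force_n=np.zeros((n_out, n)),
        pi_mm=np.zeros((n_out, n)),
        ph=np.zeros((n_out, n)),
        pooled_pi_mm=np.zeros(n_out),
        pooled_ph=np.zeros(n_out),
        pooled_h2po4_mm=np.zeros(n_out),
        config=cfg.to_dict(),
        protocol=protocol.to_dict(),
    )

    weights = pool.fmax_n
    phase_offsets = mp.recruitment_phase_offsets(n)
    stimulation = protocol.mode == "stimulation"
    s = 0.0
    torque_now = 0.0

    def record(i: int, t_t: float, l_ma: float) -> None:
        out.s[i] = s
        out.target_nm[i] = t_t
        out.torque_nm[i] = torque_now
        out.force_total_n[i] = muscle.force_n.sum()
        out.l_ma_m[i] = l_ma
        out.fr_hz[i] = pool_state.fr_hz
        out.stim[i] = pool_state.stim
        out.activation[i] = act
        out.force_n[i] = muscle.force_n
        out.pi_mm[i] = met.pi_mm
        out.ph[i] = met.ph
        pooled = bio.pooled_observables(met, weights)
        out.pooled_pi_mm[i] = pooled["pi_mm"]
        out.pooled_ph[i] = pooled["ph"]
        out.pooled_h2po4_mm[i] = pooled["h2po4_mm"]

    record(0, 0.0, joint_params.l_ma0_m)

    for step in range(1, n_steps + 1):
        t = step * dt
        if stimulation:
            t_t = 0.0
            if protocol.onset_s <= t <= protocol.offset_s:
                s = 1.0
                stim_vec = mp.stimulation_train(
                    protocol.freq_hz, t - protocol.onset_s, n, pool.pulse_width_s
                )
            else:
                s = 0.0
                stim_vec = np.zeros(n)
            fr = np.full(n, protocol.freq_hz if s > 0 else 0.0)
            pool_state = mp.PoolState(fr_hz=fr, phase_s=pool_state.phase_s,
                                      stim=stim_vec)
        else:
            t_t = ctrl.target_trajectory(protocol, t, t_cap)
            s = ctrl.update_excitation(s, torque_now, t_t, t_cap, cfg.controller)
            fr = mp.firing_rate(s, pool, gain)
            pool_state = mp.advance_pulse_trains(pool_state, fr, dt,
                                                 pool.pulse_width_s,
                                                 phase_offsets)
            stim_vec = pool_state.stim

        act = act_integrator.step(act, stim_vec)
        muscle = hill.step_muscle(muscle, act, arch, pool.fmax_n, dt,
                                  cfg.muscle.n_substeps)
        f_t = hill.total_force(muscle.force_n)
        l_ma = joint.moment_arm(f_t, joint_params)
        torque_now = joint.torque(f_t, l_ma)
        met = bio.ph_step(met, act, pool.glyc_vmax_mm_s, consts, dt)

        if step % stride == 0:
            record(step // stride, t_t, l_ma)

    return out


def run_voluntary(protocol: Protocol, config: SimulationConfig | None = None) -> SimResult:
    """Run a feedback-controlled voluntary contraction protocol."""
    if protocol.mode != "voluntary":
        raise ValueError("run_voluntary requires a voluntary protocol")
    return run_protocol(protocol, config)


def run_stimulation(
    freq_hz: float,
    config: SimulationConfig | None = None,
    *,
    onset_s: float = 0.2,
    duration_s: float = 2.5,
) -> SimResult:
    """Run a constant-frequency synchronous stimulation train (controller bypassed)."""
    if not 1.0 <= freq_hz <= 100.0:
        raise ValueError("stimulation frequency must lie in [1, 100] Hz")
    from .config import stimulation_protocol

    return run_protocol(stimulation_protocol(freq_hz, onset_s, duration_s), config)


def torque_frequency_curve(
    freqs_hz: Sequence[float],
    config: SimulationConfig | None = None,
    *,
    duration_s: float = 2.5,
) -> pd.DataFrame:
    """Peak torque as a function of stimulation frequency."""
    freqs = list(freqs_hz)
    if not freqs:
        raise ValueError("frequency list must be non-empty")
    rows = []
    for f in freqs:
        res = run_stimulation(float(f), config, duration_s=duration_s)
        rows.append({"freq_hz": float(f), "peak_torque_nm": res.peak_torque()})
    return pd.DataFrame(rows)


def write_result(result: SimResult, path: str | Path, format: str | None = None,
                 per_unit: bool = True) -> None:
    """Serialize a run to CSV (wide table) or an HDF5 bundle.

    The HDF5 bundle embeds the configuration and a content hash for
    provenance; :func:`read_result` verifies the hash.
    """
    path = Path(path)
    fmt = format or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    try:
        if fmt == "csv":
            result.to_frame(per_unit=per_unit).to_csv(path, index=False)
            return
        if fmt != "h5":
            raise ValueError(f"unknown result format {fmt!r}")
        import h5py

        with h5py.File(path, "w") as fh:
            for f in dataclasses.fields(result):
                val = getattr(result, f.name)
                if isinstance(val, np.ndarray):
                    fh.create_dataset(f.name, data=val)
            fh.attrs["config"] = json.dumps(result.config, default=float)
            fh.attrs["protocol"] = json.dumps(result.protocol, default=float)
            fh.attrs["config_hash"] = _config_hash(result.config, result.protocol)
    except OSError as exc:
        raise OSError(f"failed writing result to {path}: {exc}") from exc


def read_result(path: str | Path) -> SimResult:
    """Load an HDF5 result bundle, verifying its embedded config hash."""
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as fh:
        config = json.loads(fh.attrs["config"])
        protocol = json.loads(fh.attrs["protocol"])
        if fh.attrs["config_hash"] != _config_hash(config, protocol):
            raise ValueError(f"config hash mismatch in {path}")
        arrays = {name: fh[name][()] for name in fh.keys()}
    return SimResult(config=config, protocol=protocol, **arrays)
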