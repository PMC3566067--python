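# torquesim

Forward-dynamics simulation of voluntary human ankle-dorsiflexion torque.

A scalar excitation signal, adjusted each millisecond by a feedback
controller tracking a target torque, drives a pool of 120 motor units.
Each unit has:

- a recruitment threshold and linear rate coding (8 Hz minimum firing
  rate; peak rates 46–56 Hz), producing a binary Stim pulse train that
  gates the first 23 ms of every interpulse interval;
- first-order activation dynamics (merged sarcolemmal depolarization and
  calcium release), integrated exactly per constant-Stim segment;
- a Hill-type muscle model (contractile element with force-length,
  force-velocity and pennation; quadratic series-elastic tendon) solved
  under the isometric whole-muscle constraint;
- an intracellular bioenergetics compartment: activation-driven Pi
  appearance inside a conserved phosphate pool ([Pi] + [PCr] = 42.5 mM),
  Michaelis-Menten non-oxidative glycolysis, creatine-kinase proton
  stoichiometry, buffering-capacity pH updates and diprotonated-phosphate
  partitioning ([ATP] fixed at 8.2 mM).

Per-unit forces sum linearly and act through a force-dependent moment arm
(0.027 m at rest, +24.9% at maximal force) to give joint torque.  The
model is fully deterministic.  An electrical-stimulation mode bypasses the
controller and delivers a synchronous train to every unit, e.g. for
torque–frequency curves.

## CLI

```sh
# run a protocol (YAML) and store the full time-series table
torquesim simulate --protocol examples/mvc.yaml --config examples/config.yaml --out run.h5

# summary statistics of a stored run
torquesim report --result run.h5

# torque-frequency sweep
torquesim tf-curve --freqs 10,15,20,25,30,35,40,45,50 --out tf.csv

# fit Pi-rate coefficients to activation:rate anchor points
torquesim calibrate-pi --anchors "0.3:0.30,0.6:0.42,1.0:0.45"
```

Protocols are small YAML files (see `examples/`): voluntary mode takes a
target fraction of estimated peak torque capacity with onset/offset times;
stimulation mode takes a frequency in Hz.  Every model constant can be
overridden from the config file; `examples/config.yaml` lists them all.

Results are written as wide CSV tables or HDF5 bundles with the full
configuration and a content hash embedded (`torquesim.read_result`
verifies the hash on load).

## Python API

```python
from torquesim import SimulationConfig, mvc_protocol, run_voluntary

result = run_voluntary(mvc_protocol(), SimulationConfig())
print(result.peak_torque())
frame = result.to_frame(per_unit=True)  # pandas DataFrame
```

Module layout: `motor_pool` (recruitment, rate coding, pulse trains),
`activation_dynamics`, `hill_muscle`, `bioenergetics`, `joint_mechanics`,
`controller`, `sim_engine` (per-millisecond orchestration and I/O),
`fixtures` (canonical parameter sets), `config`, `cli`.

## Notes and limitations

- Contractions are isometric only; the muscle-tendon unit length is fixed.
- No oxidative phosphorylation, PCr recovery, proton efflux, or metabolite
  feedback on force: the model targets brief (~12 s) contractions.
- The Pi-rate coefficients (`pi_rate_p1`, `pi_rate_p3`) and buffering
  default are repo-calibrated to produce physiologic Pi/pH trajectories;
  they are not literature values.
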