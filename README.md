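# gaitsim

Co-simulation toolkit for virtual wearable inertial sensors and rule-based
gait event detection.  It synthesises triaxial accelerometer and gyroscope
signals from rigid-body segment kinematics at hundreds of systematic grid
positions on the lower limbs and shoes, runs threshold-based gait event
detectors (1-, 2- and 4-phase gait models), and evaluates timing error under
several parameterisation/cross-validation strategies — including the
rotatory-vs-translatory sensor-repositioning decomposition.  A bundled
synthetic gait generator provides bilateral stride kinematics with exact
event ground truth, so the whole pipeline runs without any external data.

## Layout

| module                  | role |
|-------------------------|------|
| `gaitsim.kinematics_io` | pose-trajectory / GRF data model and columnar text I/O (OpenSim-style `.sto` dialect), resampling, rigid sensor attachment |
| `gaitsim.sensor_grid`   | cylindrical leg grids (12 rings x 16 slots = 192 per segment), 96-sensor shoe grids, 960-sensor default build, rotatory/translatory subsets |
| `gaitsim.imu_synthesis` | additive accelerometer model (dynamic + gravity share), body-rate gyroscope extraction, Butterworth + Savitzky–Golay preprocessing |
| `gaitsim.gait_detection`| peak detection with trained height thresholds, sign-change rule, algorithms A1 (accel-only IC) and A2 (gyro+accel fusion for IC/TO/MSw/MSt), cyclic phase-model state machine |
| `gaitsim.evaluation`    | GRF reference events, MAE/nMAE timing error, 5-fold / leave-one-participant-out cross-validation (variants A1, A2a, A2b, A2c), repositioning error decomposition, Fisher-z pooled agreement metrics |
| `gaitsim.synthetic_gait`| deterministic scenario generator (stride jitter, left/right asymmetry, kinematic noise) with exact IC/MSt/TO/MSw ground truth and synthetic GRF |
| `gaitsim.cli`           | `gaitsim` command: `generate` / `synth` / `detect` / `evaluate` / `demo` |

## CLI

```bash
# 1. generate a synthetic scenario (trajectories.sto, grf.sto, ground_truth.json)
gaitsim generate --seed 3 --n-strides 12 --out run/

# 2. synthesise one virtual sensor to CSV
gaitsim synth --trajectories run/trajectories.sto \
    --segment lower_leg_left --ring 1 --slot 1 --out run/left.csv
gaitsim synth --trajectories run/trajectories.sto \
    --segment lower_leg_right --ring 1 --slot 1 --out run/right.csv

# 3. detect gait events (A2, 4-phase model)
gaitsim detect --imu-left run/left.csv --imu-right run/right.csv \
    --algo A2 --phase-model 4 --out run/events.csv

# 4. cross-validated error report (A2a/A2b/A2c/A1)
gaitsim evaluate --seed 1 --variant A2a --phase-model 4 \
    --profile small --out run/eval/

# end-to-end demo over the full 960-sensor grid (takes a few minutes)
gaitsim demo --seed 1 --out demo_out/
```

Every command writes a machine-readable `*_params.json` log next to its
outputs; error classes map to distinct non-zero exit codes
(`gaitsim.errors`).

## Conventions worth knowing

* Global frame: x anterior, y vertical (gravity axis), z medio-lateral;
  rotation matrices map global into local/sensor coordinates.
* Accelerometers follow the reaction convention: an upright sensor at rest
  reads `(0, 9.81, 0)`; the gravity share has norm `g` at every sample.
* Gyroscope output is rad/s internally; degrees/s only at reporting
  boundaries (`ImuSignal.omega_deg`).
* Leg sensor mounts use a minimal-rotation convention: the sensor's normal
  axis faces outward on the ventral half-ring and inward on the dorsal
  half, so no sensor is mounted upside down and the medio-lateral gyro
  component never flips sign; the exactly medial/lateral slots are
  degenerate (sensor z falls on the anterior-posterior axis), which
  reproduces the circular error patterns around the limb.
* The default shoe profile is three rings of (36, 35, 25) sensors; the two
  36-ring + one 25-ring layout printed elsewhere sums to 97 and is
  incompatible with the stated totals of 96 per shoe and 960 overall, so
  the middle ring defaults to 35.  Ring sizes are overridable as long as
  they sum to 96.
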