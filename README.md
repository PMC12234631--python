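# buccalsim

A planar quasi-static neuromechanical simulator of *Aplysia californica*
feeding. A six-degree-of-freedom biomechanical model of the buccal mass —
a rigid circular odontophore (grasper) moving inside the muscular I1/I3
lumen, driven by line-element and wrapping muscles — is controlled in
closed loop by a three-layer Boolean neural network with proprioceptive
feedback. The model reproduces the animal's three multifunctional feeding
behaviors (biting, swallowing, rejection), switches between them when
sensory cues change, feeds on seaweed of finite breaking strength, and
predicts the I2 muscle activation time constant from a damping sweep.

## Model summary

- **Mechanics** — inertia-free Lagrangian force balance: each generalized
  coordinate obeys `qdot = Q/c`. The odontophore's vertical position is
  slaved to its rotation by a pin-slot constraint (eliminated
  analytically); interpenetration is prevented by linear penalty laws
  (a rotational stop and a ventral-wall contact force).
- **Muscles** — Boolean neural input filtered through a double first-order
  activation cascade (`N -> A -> T~`), active tension `T_max * T~`, plus
  piecewise-linear passive springs. The wrapped I2 protractor follows the
  circle tangency geometry; bulk I3 and the hinge act through
  configuration-dependent mechanical-advantage functions.
- **Controller** — synchronous Boolean network (cerebral cue-selection
  layer, buccal interneurons with latched protraction/retraction phase,
  motor neurons), updated every 10 ms from thresholded proprioception
  (relative grasper position, normalized grasper pressure). The wiring is
  a declarative YAML document (`buccalsim/data/default_rules.yaml`).
- **Seaweed** — memoryless stick-slip friction at the grasper and jaws;
  boundary conditions: detached, fixed, or finite breaking strength.

All lengths are in model units (odontophore radius = 1; `mm_per_unit`
converts to mm), all times in model units of the I2 activation time
constant (`time_scale` converts to seconds).

## CLI

```sh
# one behavior, metrics to stdout, trajectory to CSV
buccalsim behavior bite --out bite.csv

# arbitrary cue protocol (YAML list of segments)
buccalsim simulate --protocol cues.yaml --duration 20 --out traj.csv --metrics-out m.json

# computational experiments
buccalsim switching --phase-duration 15 --out switching.csv
buccalsim sweep-seaweed --strengths 0,0.3,0.6,1.2,2.0 --out sweep.json
buccalsim sweep-damping --n 15 --out damping.json

# compare a simulated cycle against a reference trace (CSV: t,value[,sd])
buccalsim compare --behavior bite --reference ref.csv --signal translation_mm
```

A cue protocol file is a YAML list of segments:

```yaml
- {t_start: 0.0, t_end: 8.0, chem_lips: true, mech_lips: true}
- {t_start: 8.0, t_end: 20.0, chem_lips: true, mech_lips: true,
   mech_grasper: true, seaweed_mode: finite_strength, strength: 0.8}
```

## Package layout

| module | contents |
| --- | --- |
| `buccalsim.geometry` | coordinate conventions, circle tangency, muscle path lengths, overlap, radular cusp |
| `buccalsim.muscles` | passive/active tension laws, force vectors, mechanical-advantage functions |
| `buccalsim.contact` | pin-slot constraint elimination, penalty torque and wall force |
| `buccalsim.seaweed` | stick-slip friction, grasp indicator, seaweed boundary states |
| `buccalsim.controller` | Boolean network, sensory thresholding, proprioception |
| `buccalsim.dynamics` | generalized forces, hybrid integrator, trajectories |
| `buccalsim.observables` | cycle detection, kinematic metrics, ingestion |
| `buccalsim.compare` | Fourier/spline resampling, zero-lag cross-correlation, RMSE, synthetic references |
| `buccalsim.experiments` | behavior protocols, switching, seaweed-strength and damping sweeps |
| `buccalsim.cli` | command-line entry points |
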