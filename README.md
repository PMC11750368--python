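# antsim

A kinematic hexapod **ant simulator** for studying embodied insect
navigation: a scaled desert-ant body with forward/inverse-kinematics gait
control, synthetic visual and olfactory worlds, and five closed-loop
navigation controllers — central-complex path integration, visual beacon
approach, a Zernike-moment visual compass, odour trail following, and
odour plume tracking.

It is written for computational neuroethologists and biorobotics
researchers who want to test insect-brain control models inside a full
sense–act loop without a physics engine: ground contact is replaced by
**stance-foot odometry** (a least-squares rigid fit to the motion of the
ground-anchored leg tips), which keeps the simulation deterministic,
desk-scale and fast while preserving gait-dependent speed and steering.

## The model in brief

**Body.** Six legs with five joints each (ThC x/z, CTr, FTi, TiTa — three
actuated: hip yaw α, and two pitches β, γ), two three-joint antennae, neck
and abdomen joints: 40 joints, 8 tactile end-effector points. Hind legs are
longer than front legs, as in desert ants; the body is scaled ×100 (≈ 1 m).

**Gait.** A gait cycle splits each leg's time into swing and stance. In FK
mode the joint angles follow piecewise-linear phase equations driven by the
hip swing `Sl`, lift swing `Sh` and step count `Sn`; in IK mode a tip
trajectory of step length `L` and height `H` is solved to joint angles by a
law-of-cosines inverse kinematics. Tripod, ripple and wave coordination
put 3, 2, or 1 legs in the air at a time. A scalar *rotation configuration*
θ ∈ [−1, 1] asymmetrises the left/right stride ranges (θ = 0 straight,
θ = ±1 spin in place), providing the single steering input every controller
uses.

**Brain.** The path integrator follows the insect central-complex circuit:
TN2 speed cells, an 8-column TB1 heading ring, 16 CPU4 cells that integrate
the displacement into a *home vector*, and 16 CPU1 steering cells whose
left−right activation difference sets

    θ(t) = k_PI · ( Σ_{i=0..7} C_CPU1_i − Σ_{i=8..15} C_CPU1_i )
    Sl(t) = Sl0 + Slf · (1 − min(|θ(t)|, 1)),   Sl0 = 5°, Slf = 20°,

so the step length is confined to [5°, 25°] — fast when running straight,
slow while turning. The visual beacon controller binarises 74×19 eye images
and steers by *copy-and-shift* of the heading encoding
(`shift = ⌈|6δ/W|⌉` for retinal offset δ); the visual compass holds the
phase of the order-7, repetition-1 Zernike moment of a 72×72 panorama;
trail following compares left/right antennal reflectance readings against
empirical thresholds (To = 900, Td = 5, kd = 400); plume tracking casts
below the detection threshold Top = 10⁻⁶ and surges upwind above it.

**Worlds.** Landmarks are analytic primitives (spheres, cylinders, cones)
ray-cast into panoramic and binocular silhouette images; odour trails are
grayscale floor textures sampled under the (optionally sweeping) antenna
tips; plumes are filament models — advected, growing Gaussian puffs in a
coloured-noise wind field.

## Worked example

```python
from antsim import build_ant_model, ScenarioConfig, run_scenario

model = build_ant_model()
print(f"joints: {model.joint_count}, end effectors: {len(model.end_effectors)}")

result = run_scenario(ScenarioConfig("path_integration", seed=1), model=model)
m = result["metrics"]
print(f"outbound route length: {m['route_length']:.2f} m")
print(f"turning-point distance from nest: {m['turning_point_distance']:.2f} m")
print(f"closest homing approach to nest: {m['min_distance_to_nest']:.3f} m")
print(f"completed: {m['completed']} (nest radius = one body length)")
```

prints

```
joints: 40, end effectors: 8
outbound route length: 1.79 m
turning-point distance from nest: 1.33 m
closest homing approach to nest: 0.491 m
completed: True (nest radius = one body length)
```

— the agent walks a seeded foraging route away from the nest while the CX
integrates its own odometry, then steers home by the decoded home vector
and gets within half a body length of the nest.

The same scenarios run from the shell:

```sh
antsim run visual_compass --seed 0 --ticks 2400
```

```json
{
  "rotation_mode": "incremental",
  "max_error_after_settle": 0.03417463501947271,
  "final_error": 0.01844382628984409,
  "mean_abs_error": 0.012429245074104669,
  "scenario": "visual_compass",
  "seed": 0
}
```

— while the world rotates under it, the agent counter-turns by the Zernike
phase difference and holds its heading relative to the scenery to within
about 2 degrees (errors above are radians). `antsim run <scenario> --config
FILE --seed N --out DIR [--ticks N] [--plot]` writes a trajectory CSV and a
metrics JSON; `antsim fixtures trail|world|route` generates world fixtures.

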