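# Methods

This note documents the models inside `antsim`, the conventions and
constants they depend on, what the synthetic worlds do and do not emulate,
and the design choices made where the design was genuinely open.

## Frames, units, conventions

* Body frame: +x forward, +y left, +z up. World heading `h` is CCW from
  world +x, wrapped to (−π, π].
* Gait-level angles are in **degrees** (the natural unit of the stride
  parameters); transform-level rotations are in **radians**. The conversion
  lives in the body module only.
* `homogeneous_transform` uses fixed-axis roll–pitch–yaw order
  (R = Rz·Ry·Rx).
* Lengths are metres after the ×100 morphological scale; one tick is one
  gait-control step (a tripod cycle is 4·Sn = 40 ticks by default).
* The steering scalar θ is dimensionless; positive θ turns the body CCW
  (left). sign(0) := 0 wherever a controller takes a sign.

## Body model

Morphology constants (segment lengths, leg-base positions and yaws, antenna
geometry, joint limits, scale) are declared once in `antsim/config.py`; all
code and tests reference them there. Defaults are plausible desert-ant
proportions with the species-typical ordering hind > middle > front total
leg length, and exact left/right mirror symmetry (validated at build time).
The supplied values are stand-ins, not measurements: replacing them with
measured segment lengths is a config edit.

Each leg is treated as a yaw–pitch–pitch chain (ThCz active; ThCx and TiTa
held at fixed angles; CTr and FTi rotate about the local −y axis so that
positive angles lift the tip). Forward kinematics composes the chain
analytically; inverse kinematics assigns the target's azimuth to the hip
yaw and solves the two pitch joints in the leg's vertical plane by the law
of cosines, folding the tarsus (with its fixed TiTa bend) into an effective
distal link. The knee branch is fixed to the rest posture's (γ ≤ 0), making
the solution unique; FK∘IK round-trips are exact to numerical precision.
Targets outside the reachable annulus raise a reachability error carrying
the offending distance.

## Gait control

The FK phase equations (two swing halves and a stance sweep, each linear in
the step index k) close the cycle exactly: swing1 end = swing2 start,
swing2 end = stance start, stance end = swing1 start. Ripple and wave
coordination reuse the same equations with the stance sweep stretched over
the longer ground phase, so exactly 3/2/1 legs are airborne at every tick
for tripod/ripple/wave. Steering commands are latched at cycle boundaries.

**Turn table.** The hip-swing range R of each side follows the yaw-control
table: for θ ≥ 0, left R = Sl·d·(2θ−1) and right R = Sl·d; for θ < 0,
left R = −Sl·d and right R = Sl·d·(2θ+1). The two rows are exact mirror
images, so the table is continuous through θ = 0 and negating θ mirrors the
generated angle series — properties the closed-loop controllers rely on,
since their steering outputs oscillate around zero.

**IK gait.** Tip targets follow the stride equations literally, expressed
in a stride frame whose +x points to the body's rear (the walking robot the
equations were written for faces the opposite world axis); mapping to the
body frame negates x and z and flips the tip yaw, which makes the stance
sweep run front-to-back and gives θ the same CCW sign as in FK mode. The
literal swing profile descends monotonically to −H and therefore leaves a
z-discontinuity at touch-down (the tip is pressed through the contact
plane, which a physics engine resolves as ground contact); a `lift` swing
profile that rises and lands at 0 is available via config. The z profile
does not affect the planar odometry either way.

Default Sn = 10 ticks per half-swing balances angular resolution against
simulation cost; it is a config value.

## Locomotion without a physics engine

Ground contact is replaced by stance odometry: legs are "in stance" when
their schedule says so, their tips are assumed anchored to the ground, and
the rigid planar motion (least-squares rotation + translation, closed-form
2-D Kabsch fit) that maps the new body-frame tip positions back onto the
old ones is applied to the body pose. The fit is exact on rigid
displacement fields and averages the slight non-rigidity of hip arcs
rotating about different leg bases. Consequences worth knowing:

* straight walking drifts < 1° per 10 cycles (a fixed sub-degree startup
  transient, not an accumulating error);
* tripod > ripple > wave mean speed falls out of the stance-duty ratios;
* speeds are *kinematic* — comparable across gaits and parameters within
  the model, but not calibrated to any measured robot or animal speed, so
  only orderings and rates are meaningful;
* the body height is fixed: no pitch/roll, slippage, adhesion or terrain.

## Sensors and worlds

**Cameras.** Panoramic (72×72, spherical: rows zenith→nadir, columns
azimuth CCW from the heading) and two planar pinhole eyes (74×19,
horizontal FOV 2 rad, vertical 0.5 rad) are rendered by analytic
nearest-hit ray casting against dark primitives on a bright background; no
texture or lighting. Panorama yaw equivariance is exact for whole-column
rotations, which the compass tests exploit. The eyes sit at the head sides
and their optical axes toe **outward** by 20° (config `eye_toe_out_deg`),
as in lateral compound eyes. This matters behaviourally: a monocular agent
that centres the landmark in its single eye tracks it with a ~20° lead
angle, which produces the ipsilateral-biased, slower curved approaches that
distinguish monocular from binocular agents; with parallel axes (toe-out 0)
the two conditions become nearly indistinguishable in a kinematic model.

**Trail sensing.** The trail is a grayscale floor raster with an invertible
world-to-pixel transform; an antenna tip reads 1000 × (bilinear intensity /
255), an abstraction of an infra-red reflectance sensor calibrated so the
empirical thresholds (on-trail ≥ 900, background < 5) are meaningful.
Antenna sweeping oscillates the lateral joint sinusoidally (default
amplitude 30°, period 40 ticks — one gait cycle; both are assumptions
exposed in config, as no behavioural values are available), the two
antennae in antiphase.

**Plume.** Puffs are released at a source (carry-over fractional release
accumulator), advected by mean wind + AR(1) coloured noise + per-puff
centreline dispersion, grow linearly in squared radius, and are culled at
the domain boundary (released − culled = live, exactly). Concentration is
the superposition of normalised 3-D Gaussian kernels
q·(2πs)^(−3/2)·exp(−d²/2s); the kernel normalisation is a convention fixed
in config — every controller decision depends only on ratios and
thresholds. The 2-D agent samples the field at its antenna height. Plume
parameter defaults are sized so that the stated cast-and-surge controller
can solve the tracking scenario (the underlying filament model publishes no
canonical parameter set); they are study conditions, not fitted values.

## Controllers

**Path integration.** Deterministic clipped-linear cell model: TN2 encodes
speed (normalised by `v_max` = 0.02 units/tick) on two ±45° axes; TB1 is
the 8-column sinusoidal heading encoding; CPU4 integrates TN2 gated by the
(1 − TB1) profile measured about the ring midpoint — i.e. signed
displacement integration, so memory accumulated outbound is depleted on the
homeward leg instead of saturating the [0, 1] cell range; CPU1 compares the
memory shifted by one column against the heading ring, and θ = k_PI ×
(left − right sum). The home vector decodes exactly (the 8-point DFT of a
sinusoidal bump) whenever clipping is inactive. k_PI = 3 and the CPU4 gain
0.005 were selected empirically for closed-loop homing performance, the
same procedure the underlying robot model uses for its motor constants. An
optional seeded Gaussian noise on the steering cells (std 0.01 in the
closed-loop scenarios, 0 in deterministic tests) breaks the unstable
equilibrium at exact anti-alignment, standing in for the stochastic units
of the reference circuit.

**Steering circuit** (shared by beacon and compass): θ = k(ΣL − ΣR) of the
clipped comparison between a desired and the current heading encoding; zero
at alignment, sign = shorter turn direction, near-zero again at 180°
(unstable). The magnitude peaks between 45° and 90° offset — a property of
the clipped one-column-shift comparison.

**Visual beacon.** Images are binarised at threshold 18 (midpoint of the
empirical 10–25 range); δ is measured from the image **centre** (W/2 − Pl).
The printed width-based form (W − Pl) is retained behind the config switch
`beacon_delta_mode="width"`, but the centre-based reading follows the
mechanism's description and makes δ = 0 mean "landmark centred". The shift
is ⌈|6δ/W|⌉ columns of the 8-column ring, applied with δ's sign;
k_vb = 0.15 keeps the one-column quantisation from saturating the turn
command (an empirically selected motor scale, as above). When the required
eye(s) see no landmark the controller reports no-detection and the caller
keeps its previous command; the scenario's initial command is a scan
(monocular: towards the sighted field; binocular: seeded random direction).

**Visual compass.** θ = sign(Δ), Sl = |Δ/5| with Δ the wrapped phase
difference of the Zernike (7, 1) coefficient in radians; the scenario maps
the phase measure to degrees of hip swing (equivalently |Δ_deg|/5). A
coefficient magnitude below 10⁻⁹ (featureless panorama) flags low
confidence and holds the previous command.

**Trail following.** Odour is "sensed" iff max(Ol, Or) ≥ To = 900 (the
no-odour column requires both below threshold). Sensed and balanced
(|Ol − Or| < Td = 5): straight, Sl = 8°; unbalanced: θ = (Ol − Or)/400,
Sl = 4°; not sensed: θ random ±1, Sl = 3°. The gait-loop decision uses the
maximum reading each antenna collected during the loop, so a sweeping
antenna samples a wider band — the mechanism by which moving antennae beat
fixed ones on wide trails. Trail-width conditions are sized relative to
the antenna geometry: the default width (0.6) just covers the fixed tips
(±0.27 lateral), the widened trail (1.0) reaches the edge of the moving
sweep (±0.43).

**Plume tracking.** Below Top = 10⁻⁶: random ±1 scan at Sl = 5°. Above:
upwind bearing m = atan2(−wy, −wx) of the wind sensed on the
higher-concentration side (the two-argument arctangent resolves the
quadrant ambiguity of tan⁻¹(wy/wx)); Δ = wrap(m − h); θ = sign(Δ),
Sl = min(5 + |Δ_deg| mod 5, 15)°. The literal mod-5 form keeps Sl < 10°, so
the min(·, 15) bound is never active — it is retained as printed. Each
sensory decision is followed by two straight surge loops at Sl = 15°.

## Scenarios and study conditions

All scenarios run the same tick loop (sense → controller → (θ, Sl) → gait →
FK → odometry), are bit-for-bit reproducible under their seed, and write
trajectory CSV + metrics JSON. Completion radii default to one body length.

* *Path integration*: outbound correlated random walk from the origin
  (initial heading uniform on [0, 2π), per-tick heading noise std 0.05 rad
  — visibly tortuous foraging routes; a straighter default leaves the
  homing start near the unstable anti-aligned equilibrium), then closed-loop
  homing. A reduced point-kinematics loop (`pi_closed_loop`) isolates the
  controller from gait granularity for property testing; the embodied
  scenario couples it to the full gait.
* *Visual beacon*: one dark cylinder 6 m away; initial headings sampled
  per mode (left eye [0, π/2], right eye [π/2, π], binocular [π/4, 3π/4]).
* *Visual compass*: asymmetric landmark panorama; the world rotates
  incrementally or in jumps and the error is measured scene-relative.
* *Trail following*: start [5, 0], heading π, on the trail's end.
* *Plume tracking*: source at the origin, mean wind +x, agent ~3 body
  lengths downwind after a 600-tick plume pre-roll.

## What the synthetic worlds do not emulate

No rigid-body dynamics, torques, slippage, adhesion or uneven terrain; no
compound-eye optics, texture or lighting; no gridded CFD (the plume is a
puff model); no multi-agent interaction. Passing tests therefore
demonstrate the *control logic* closed through an idealised body–world
loop — orderings, completion rates and invariants — not calibrated physical
performance. Quantities tied to physics (absolute speeds, task times in
seconds) are compared only ordinally.

## Numerical notes and degenerate inputs

* θ outside [−1, 1] is clipped with a warning at the turn table; the speed
  rule already saturates there.
* IK targets outside the reachable annulus raise; the gait layer annotates
  the error with leg/phase/step context.
* Zero stance legs: pose held, warning logged. Flat CPU4: home bearing is
  NaN with magnitude 0. Featureless panorama or empty eye masks: previous
  command held.
* All RNGs are `numpy.random.default_rng` children of the scenario seed;
  no global state.
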