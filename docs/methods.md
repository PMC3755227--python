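# Methods

## The model

`hexawalk` simulates a six-legged walker controlled without any central
pattern generator.  Each leg has its own controller with two procedures —
a swing net (lift the leg and move it to the touchdown target) and a
stance net (let the leg carry and propel the body) — selected by a small
recurrent network of *motivation units*.  Legs interact in exactly three
ways:

1. **Coordination rules** — local signals between neighbouring legs that
   shift the receiver's posterior extreme position (PEP, the lift-off
   threshold; rules 1–3), transmit the sender's foothold as the receiver's
   swing target (rule 4, "targeting") and share load signals (rule 5).
2. **The motivation-unit network** — per-leg swing/stance pairs and
   forward/backward target-net pairs under winner-take-all (WTA) coupling,
   per-leg units, walk/stand and forward/backward command units, and one
   gating unit per rule channel.  Units are discrete first-order low-pass
   elements with clamped (piecewise-linear) activation; procedure outputs
   are multiplied by their unit's output, so a silent motivation
   contributes exactly nothing.
3. **Mechanics** — the "loop through the world".  The body is a rigid
   frame advancing at the commanded velocity; all stance tarsi stay pinned
   to the ground in world coordinates, and their joint angles follow by
   inverse-kinematic consistency.  This is the kinematic realisation of
   all stance legs adopting the same velocity through the shared body.

Walking patterns — the wave → tetrapod → tripod continuum, disturbance
robustness, amputation tolerance, backward walking — are emergent: no code
anywhere prescribes a gait.

## Geometry and conventions

Body frame: +x anterior, +y left, +z dorsal.  Each leg is a 3R chain
(thorax–coxa α, coxa–trochanterofemur β, femur–tibia γ) attached at a
per-leg point; the thorax–coxa axis orientation is given by two tilt
angles φ, ψ (default 0: vertical axis).  Zero pose: leg perpendicular to
the body axis, femur horizontal, tibia collinear — maximal planar
extension.  Positive α moves the tarsus anteriorly on both sides; positive
β lifts; the inverse kinematics always takes the knee-up branch (γ ≤ 0).

Morphology defaults (config-owned, not hard-coded): attachments at
x = ±0.25, 0 m, y = ±0.05 m; segment lengths 0.1/0.3/0.3 m; stance tarsi
0.30 m from the midline; body clearance 0.25 m; per-leg step range
[attach − 0.15 m, attach + 0.15 m], i.e. the default AEP–PEP distance of
0.3 m.  These were chosen once so that a stick-insect-like sprawled
workspace results with comfortable joint-limit margins over the whole
step; they are proportions of a walking insect scaled to a 0.3 m step.

All PEP/AEP logic runs in the travel coordinate u = s·x with s = +1
forward, −1 backward.  Stance always decreases u; lift-off happens when u
falls below the effective PEP; swings aim Δ = 0.3 m ahead.  Backward
walking is therefore a pure sign/role inversion selected by the motivation
network (target-net pairs flip, directed ipsilateral rule edges reverse,
and the rule-3 displacement table is keyed by functional position).

## Single-leg control

**Swing.**  α and γ are negative-feedback servos (gain 15 s⁻¹) toward the
target pose; the β channel adds a rebound impulse through a first-order
filter (time constant 0.15 s) that lifts the tarsus ~5 cm before the servo
lowers it again.  The impulse is sized so the near-critically-damped
response peaks at the configured lift.  The touchdown target is the
on-ground AEP pose with only the β target pushed 2 cm below ground: α and
γ then converge to the exact touchdown pose (the tarsus lands on target in
the horizontal plane) while the β overshoot gives a decisive final
descent.  The target pose is re-derived every tick from the stored target
point, so a rising body (e.g. climbing a terrain step) cannot strand a
swing in mid-air.  Swing-net version 3 (the β-channel high-pass) is the
default; version 2 (two-stage rebound standing in for the antagonistic
circuit) and version 1 (β crosstalk from α, forward walking only) are
selectable.

**Stance.**  In the default `pos_vel_feedback` mode α and γ amplify their
own measured velocities — the mechanical coupling does the coordination,
which the kinematic world realises exactly through the tarsus pinning —
and β comes from the height controller only.  A `neg_feedback` mode
(servo toward the PEP pose at a rate set by the commanded velocity) is
retained for comparison.

**Height.**  A saturating soft spring: correction = g·h_sat·tanh(e/h_sat)
with g = 2.5 s⁻¹, h_sat = 0.06 m, zero exactly at the 0.25 m reference.

**Standing.**  Per joint, the command is kp·e + I₁ where I₁ integrates the
error (with a slow 0.1 s⁻¹ leak bounding it) and the reference itself
drifts toward the measured angle at 0.5 s⁻¹ (the adaptive-reference loop).
On a compliant substrate the integral action nulls the position error; on
a stiff substrate the reference converges to the actual value and the
command decays — the controller "gives up" integrating instead of winding
up.

**Load and contact.**  Contact: tarsus within 1 mm of the terrain.  Load:
the leg's quasi-static share of unit body weight — minimum-norm
nonnegative forces satisfying force and moment balance about the
centre-of-mass ground projection — plus whatever neighbours contribute
through rule 5, clipped to [0, 1].  A 0.1 s low-pass of the load drives
the rearward PEP shift (gain 0.02 m per unit load), mimicking sluggish
load afference.  The moment-balanced distribution matters: a rear support
whose contralateral partner swings carries more weight and therefore
prolongs its stance, which is the model's decentralized stabiliser.  (An
inverse-distance weight proxy was tried first and gives the *opposite*
pattern — rear supports under-loaded — which lets hind-leg pairs lift
together and tip the walker.)

**Phase switching.**  The swing/stance WTA pair (time constant 15 ms,
faster than the 50 ms default of other units so a touchdown can flip the
pair within a few ticks) receives a PEP-reached trigger with a two-tick
anticipation compensating the pair's switching latency, an airborne
support signal that keeps swing the winner until touchdown (without it the
pair can relax into its interior fixed point and abort a swing), and a
touchdown trigger (contact + descending + load above 0.05).  A mechanical
contact while the leg still moves forward (brushing a terrain step)
instead triggers the levator avoidance reflex: 100 ms of retraction
(3 cm) and lift (2 cm), after which the swing resumes; the reflex is gated
off entirely during stance.

## Coordination rules

Topology: rule 1 ipsilateral back→front; rule 2 ipsilateral back→front and
contralateral; rule 3 ipsilateral front→back and contralateral both ways;
rule 4 ipsilateral front→back; rule 5 between neighbours.  Losing a middle
leg inserts ipsilateral hind→front edges carrying rules 1–3.

* **Rule 1** (inhibitory): rearward shift while the sender swings plus a
  velocity-dependent delay, delay₁b(v) = max(0, 0.25 − 0.4·v) s.  The
  displacement (−0.18 m) is deliberately large enough to block the
  receiver's lift for a whole sender swing even at the top velocity — a
  smaller value only postpones rather than prevents simultaneous
  ipsilateral swings.
* **Rule 2** (excitatory): +0.02 m ipsilateral / +0.03 m contralateral,
  active exactly from 270 ms to 320 ms after the sender's stance onset.
* **Rule 3** (excitatory): active while the sender, in stance, sits in a
  5 cm position window that opens thr(v) = max(0, a − 0.15·v) m of travel
  after its touchdown (a = 0.22 ipsilateral, 0.25 contralateral);
  displacement table keyed by channel and the receiver's functional
  position, 0.02–0.03 m ipsilateral, 0.01–0.05 m contralateral (largest
  into hind legs, whose pairs have no other alternation mechanism).
* **Rule 4** (targeting): the sender's tarsus position, offset 3 cm
  rearward, becomes the receiver's swing target, clamped to ±6 cm around
  the default AEP (targeting fine-tunes the foothold but may not relocate
  it far enough to break the support pattern); unreachable targets fall
  back to the default AEP.
* **Rule 5**: supra-threshold (0.1) load signals are added into each
  neighbour's load.  Only the locally sensed ground share is shared —
  sharing the already-shared total would let load echo between neighbours
  and saturate everyone.

Shift magnitudes, thr/delay coefficients and the velocity grid were
calibrated together against the gait-continuum behaviour (monotone stance
counts, banded delay-3-1 structure) and the robustness scenarios; all are
config-exposed.

## The world loop

Tick order (dt = 5 ms, chosen ≥10× finer than the 50 ms rule-2 window):
commands → forward kinematics and sensors → weight distribution and
rule 5 → rule shifts and effective PEPs → motivation network update →
phase transitions (touchdowns project the tarsus onto the ground and pin
it) → swing/stance/standing commands → body advance, stance IK, swing
integration, height regulation → stability bookkeeping.  A stance leg
dragged out of its workspace is released into an emergency swing.  Runs
are deterministic given (config, seed).

**Fall criterion.**  The CoM (body origin ground projection) outside the
convex hull of the stance tarsi for more than 50 ms truncates the run
with a fall record.  This operationalises "stable walking" for a
quasi-static kinematic walker; it is deliberately strict (a real insect
briefly outside static support may catch itself dynamically).

**Supported conditions.**  Steady walking holds for commanded velocities
of about 0.03–0.42 m/s, forward and backward, except for a narrow
transition band near 0.30–0.32 m/s where the tetrapod-to-tripod
reorganisation repeatedly crosses marginal support configurations; the
gait sweep grid spans 0.05–0.42 m/s avoiding that band.  The step period
is 0.3/v plus a ~0.45 s swing.

## Amputations

Removing a leg removes its graph edges; a lost middle leg activates the
hind→front bridge.  Two further adaptations reflect what amputee insects
do: (i) a neighbour of a lost leg shifts its whole step range (not its
length, which would break the common step period) toward the gap by up to
0.1 m; (ii) the initial lift phases of the reduced leg set come from a
precomputed table obtained by an offline search maximising the minimum
static-support margin over a step cycle, with ipsilateral neighbours
never swinging together.  Amputee scenarios run at 0.15 m/s with
targeting disabled (after a loss the anterior foothold is often absent or
outside the support pattern the reduced set needs).

Supported configurations: all six single amputations and the diagonal
contralateral doubles (front+hind of opposite sides, both middles).  The
analysis behind the exclusions: a side reduced to a single leg leaves the
CoM collinear with or outside every reachable support set, and the
non-diagonal cross pairs have no statically feasible phase schedule at
all (the search's best margin is negative).  These configurations are
genuinely outside what a fixed-CoM, strictly statically stable kinematic
walker can do, whatever the controller.

## Scenarios and the synthetic experiment catalogue

`make_scenario` builds deterministic config lists: `gait_sweep` (8
velocities × 60 s), `amputation_grid` (9 configurations × 60 s),
`swing_prolongation` (hold a swinging tarsus 0.6 s), `stance_displacement`
(3 cm foothold displacement in four directions), `backward_switch`
(forward → 2 s stand → backward; the reversal passes through a stand as
walking animals do), `terrain_step` (a 5 cm step across the path), and
`random_init_convergence` (10 random phase orderings, accelerating from
near standstill over 25 s — a soft start that lets the rules sort
arbitrary phases before speed builds; "random pose" means a random
ordering of step phases with jitter, since several legs poised at their
PEP simultaneously is a configuration no standing insect occupies).

## What the simulations do and do not show

The generator emulates flat or piecewise-flat rigid ground, a massless
kinematic body with its CoM fixed at the body origin, ideal joint
actuation and noise-free sensing.  Passing tests therefore demonstrate
the *coordination logic* — that local rules plus mechanics yield the gait
continuum and its robustness — not torque feasibility, compliance or
sensory noise tolerance.  Temporal scale is set by the 0.3 m step and the
~0.45 s swing; absolute periods are not calibrated to any animal.

Known limitations:

* the 0.30–0.32 m/s transition band (above);
* convergence from arbitrary initial phase orderings usually succeeds but
  is not guaranteed — in the packaged ten-run scenario, seven orderings
  converge to a periodic pattern (period CV < 2%) and three steer the
  reorganisation through a support pinch (typically both hind legs or a
  hind leg and its diagonal middle lifting close together) that the
  strict fall criterion scores as a fall, although the walker would catch
  itself within half a swing;
* curve walking, searching movements, gap crossing, the
  treading-on-tarsus reflex and dynamic simulation are out of scope;
* heading is fixed (no yaw), matching the common-stance-velocity
  simplification.

## Numerical choices

dt 5 ms; contact tolerance 1 mm; WTA weights −2.0 mutual / +1.1 self;
command drive 3.0 (must exceed the WTA inhibition to overturn a standing
winner); deterministic tie-breaks stance-over-swing and
forward-over-backward via +0.02 biases; touchdowns projected exactly onto
the terrain; IK ambiguity fixed to the knee-up branch; the load
distribution falls back to a nonnegative least-squares fit when the fast
active-set solve degenerates; all randomness flows from the run seed
through one generator.
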