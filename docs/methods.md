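# Methods

## Model and assumptions

The body is a planar four-link chain in the sagittal plane: a triangular
foot (vertices at the posterior calcaneus C, distal toe T and ankle A)
pinned at the origin O where the perpendicular from A meets the ground
line CT; a shank A→K; a thigh K→H; and a lumped head-arms-torso (HAT)
segment from H to the HAT center of mass. +X is anterior, +Y superior,
rotations counterclockwise. Link *i*'s direction is the cumulative angle
θ₀+…+θᵢ+90°, so the zero posture is an upright stack. Foot-flat states
fix θ₀ = 0; this is a state-selection rule, not a dynamic constraint —
no ground-reaction or contact force is modeled, the chain is simply
pinned at O.

A muscle potential is the induced COM acceleration per Newton of muscle
force under **static** conditions. Three consequences of that definition
shape the implementation:

* gravity, Coriolis/centrifugal and intersegmental terms never enter the
  potential operator (they cancel from a per-Newton contribution); the
  full equations of motion exist in the code only as a verification
  oracle (`dynamics.eom_terms`);
* the task-space projection uses Ẍ = J q̈ with the J̇q̇ term dropped,
  exact at zero velocity;
* potentials are independent of muscle force, activation and
  force–length–velocity properties, which are out of scope.

In minimal coordinates the internal pin forces do no virtual work, so the
oracle integrates M q̈ = G + V + Q with no separate intersegmental term;
its correctness is checked by an energy-balance test along a simulated
trajectory (drift < 10⁻⁶ relative).

## Mass matrix and Jacobians

M(q) = Σ mᵢ Jᵥᵢᵀ Jᵥᵢ + Iᵢ Jωᵢᵀ Jωᵢ with analytic link Jacobians (the
truncated cumulative-angle sums) and the planar reduction: only the
z-row of each angular Jacobian (ones up to the link's joint) and the
scalar z-axis inertia are kept, since the x/y rows vanish identically in
plane motion. Joint potentials solve M P = R by Cholesky factorization
(never explicit inversion) with a condition-number guard at 10¹². The
suite proves M against the finite-difference Hessian of kinetic energy
in the generalized velocities (< 10⁻⁶ relative) and the Jacobians
against central differences of the forward kinematics (< 10⁻⁸ m/rad),
and verifies symmetry/positive-definiteness over all enumerated states.

## Angle conventions and the state grid

Anatomical (MSK) angles relate to chain coordinates by ankle = −θ₁,
knee = −θ₂, hip = θ₂+θ₁+θ₀−tilt, lumbar = hip+θ₃, with positive =
dorsiflexion, knee extension, hip flexion, lumbar extension, posterior
pelvic tilt. Pelvic tilt is an anatomical degree of freedom of the
five-angle description, not a chain coordinate: on a foot-flat chain the
five angles are linked by tilt = −(ankle+knee+hip), and the moment-arm
providers derive the consistent tilt from the declared joint angles so
that arms are pure functions of (ankle, knee, hip, lumbar).

One documented convention conflict: the strength-of-correlation tables
use positive = lumbar **flexion** while the state tables here follow the
joint definition positive = lumbar **extension**. The correlation layer
therefore exposes the modifier `lumbar_flexion = −lumbar` so its signs
read in the flexion-positive sense.

The default grid steps θ₁ ∈ [−40°, 0°], θ₂ ∈ [75°, 100°],
θ₃ ∈ [−150°, −60°] and tilt ∈ [−60°, 20°] in 5° increments (inclusive
bounds, integer-degree arithmetic — no floating-point accumulation) and
keeps states with hip ∈ [15°, 120°] and lumbar ∈ [−90°, 60°]: 14,758
states, enumerated lexicographically and deterministically. With the
printed grid these box constraints subsume the narrative hip-flexion and
lumbar-range limits, so the boxes are the implemented rule.

Derived metrics per state, both normalized to leg length L₁+L₂:
pelvis height = L₂·cos(hip+tilt) + L₁·cos(ankle), the vertical
ankle-to-hip distance; foot position = L₂·sin(hip+tilt) − L₁·sin(ankle),
the horizontal hip-to-ankle distance (0 = ankle under the hip, positive
= more anterior foot). The ankle term enters foot position with a minus
sign — dorsiflexion carries the ankle posterior relative to the knee —
which is the form that telescopes to x_A − x_H and matches the
distance-based definition; both metrics are verified against the
forward kinematics for every foot-flat state.

## Moment arms

A moment arm is the tendon excursion −∂ℓ/∂θ about an anatomical joint.
Two providers sit behind one interface:

* **Geometric** — straight-segment paths over attachment frames: the
  four links plus an anatomical *pelvis* frame whose origin rides on the
  hip and whose orientation is the pelvic tilt alone. Hip muscles anchor
  on the pelvis, so they carry no lumbar arm and their generalized
  column is the (r, r, r, 0) pattern of a pure hip torque. Arms are
  computed analytically from attachment-point Jacobians; a central
  finite difference of path length in MSK angle space (0.1° step) is the
  cross-check route.
* **Tabulated** — multilinear interpolation of a long-format CSV
  (muscle, joint, four angle columns, arm in meters) on a full-factorial
  angle grid, exact at nodes, with a hard error outside the tabulated
  range. This is the ingestion path for arms exported from any
  musculoskeletal modeling tool; a 23-muscle table reproduces the 4×23
  [R] of a full lower-limb model.

Anatomical arms map to generalized torques through the constant Jacobian
D = ∂θ_msk/∂q of the angle conversions, R_gen = Dᵀ R_msk (pelvic tilt
held fixed). The strongest internal check in the suite is chain-rule
consistency: for every fixture muscle at 100 random enumerated states
the mapped column equals −∂(path length)/∂q differentiated directly
through the forward kinematics, to 10⁻⁶ m/rad.

## Synthetic fixtures

**Anthropometry.** Per-link values are not published for the source
generic model; the bundled fixture builds them from standard gait-model
segment proportions — torso+pelvis lumped into the HAT and
talus+calcaneus+toes into the foot via the parallel-axis rule, both legs
folded into each leg link so the single chain carries the whole body —
then normalizes so the two published totals hold exactly: 75.2 kg total
mass and 0.826 m leg length (L₁ = 0.430 m shank, L₂ = 0.396 m thigh).
Ankle height is 0.080 m with OA ⟂ CT by construction; θ_c and r₀ follow
from the lumped foot COM.

**Muscle geometry.** Eight actuators: gluteus maximus, biceps femoris
(long head), rectus femoris, vasti, medial and lateral gastrocnemius,
soleus, tibialis anterior (gastrocnemius heads report their mean when
grouped; configurable to sum). Attachment coordinates are original,
anatomically plausible approximations. Straight segments lose their arm
when a chord migrates into a joint center at deep flexion, so each joint
carries pulley-style via points — retro-malleolar groove and dorsal
retinaculum at the ankle, a patellar via and posterior-shaft vias at the
knee, ischial/pelvic-rim and femoral-head wrap points at the hip — the
standard device of straight-line muscle models. Via placements were
chosen so that, across the whole grid, every arm keeps its anatomical
sign and centimeter scale *and* follows the published angle trends:
soleus/gastrocnemius plantarflexion arms ≈ 3–5 cm, tibialis anterior
dorsiflexion ≈ 4–5 cm, vasti/rectus knee extension ≈ 3–3.5 cm, hamstring
knee flexion ≈ 1.5–3 cm shrinking with flexion, biceps femoris hip
extension growing with hip flexion (≈ 5–10 cm), and gluteus maximus
extension largest near hip extension (≈ 6 cm) and shrinking with deep
flexion. The gluteus maximus arm falls below 1 cm near 120° hip flexion,
steeper than cadaver data suggest — a known limitation of a two-point
straight-line wrap.

**What passing tests do and do not show.** The fixtures make every
structural claim testable offline: oracle equivalences, conversion
algebra, scaling laws, and the *sign* structure of the correlation table
(all sixteen published |r| ≥ 0.8 entries match, and tibialis anterior
opposes the plantarflexors on foot position). They do not reproduce
exact correlation coefficients or potential values of any specific
musculoskeletal model — those depend on that model's moment arms, which
are not distributed. Users with such a model should export its arms and
use the tabulated provider.

## Statistics

Potentials across the grid are strongly non-normal, so both variables
receive a rank-based inverse normal transform before Pearson
correlation: Φ⁻¹((rank − 3/8)/(n + 1/4)) — Blom scores, the common
default where the offset is not specified — with average ranks on ties;
the offset is configurable. A Lilliefors normality p-value is available
as an optional report field, but the pipeline always transforms
(matching the published final procedure). Strength categories apply to
|r| (boundaries 0.2 / 0.4 / 0.6 / 0.8) with the sign reported
separately; α = 0.05. Degenerate (constant) columns are flagged in the
report rather than aborting it. Aggregation for summary plots groups
states by exact grid value for angles and by value rounded to six
decimals for the continuous derived metrics, weighting states uniformly.

## Numerical choices

* Radians internally; degrees at every file/CLI boundary.
* Linear solves via Cholesky; condition guard 10¹² (no enumerated state
  comes near it).
* Analytic derivatives everywhere in the production path; finite
  differences (steps 10⁻⁶ rad for Jacobians, 0.1° for MSK arms) only in
  oracles and cross-checks.
* The Coriolis oracle uses Christoffel symbols from finite-differenced
  M (step 10⁻⁶ rad) — adequate for verification, never in the
  potential path.
* Grid arithmetic in integer degrees; enumeration is deterministic and
  duplicate-free by construction.
* The full 14,758-state × 8-actuator sweep runs in about a minute on one
  CPU (~4 ms per state), far under the several seconds per state of
  simulation-based pipelines; test and acceptance runs use the full grid.

## Known limitations

* Static by design: no joint-velocity effects, no phase of a measured
  trial, no time series.
* Sagittal plane only; single-leg muscle columns with bilaterally lumped
  segment inertia.
* No muscle force estimation: potentials weight all muscles equally per
  Newton.
* The synthetic geometry is a stand-in: correlation signs and trends are
  meaningful, coefficients are not.
* No wrapping surfaces or via-point engagement logic; pulley vias are
  always active.
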