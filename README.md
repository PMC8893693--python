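# stspotentials

Muscle potentials for the sit-to-stand transfer: an induced-acceleration
toolkit for a four-link sagittal-plane model.

## The problem

Rising from a chair is one of the most mechanically demanding activities
of daily living, and the muscles that power it — gluteus maximus,
quadriceps, plantarflexors — do not act in isolation: how much whole-body
center-of-mass (COM) acceleration a Newton of muscle force can buy
depends on the entire kinematic state of the body. Traditional induced
acceleration analysis answers this with subject-specific motion capture
and hours of dynamic simulation. This package implements the efficient
alternative: a static, per-state computation over a planar model that
maps out, in minutes, how kinematic modifications (foot placement, chair
height, trunk lean, pelvic tilt) change each muscle's *potential* to
contribute to support and progression. It is aimed at movement-science
researchers and clinician-scientists exploring rehabilitation strategies
for populations with altered sit-to-stand mechanics (e.g. knee
osteoarthritis).

## The model

The body is a chain of four rigid links — foot (pinned at the ground
origin), shank, thigh, and a lumped head-arms-torso (HAT) segment —
with generalized coordinates θ₀..θ₃ and foot-flat states (θ₀ = 0). For a
static kinematic state *q* the induced joint accelerations per Newton of
muscle force are

    Potential = M(q)⁻¹ R(q),

where M is the 4×4 Lagrangian mass matrix assembled from link Jacobians,

    M = Σᵢ mᵢ Jᵥᵢᵀ Jᵥᵢ + Iᵢ Jωᵢᵀ Jωᵢ,

and R maps muscle forces to generalized torques through their moment
arms. Gravity, Coriolis and intersegmental terms drop out of a
per-Newton contribution. Projecting through the COM Jacobian under the
static (zero-velocity) assumption, Ẍ = J q̈, gives each muscle's

* **support potential** — vertical COM acceleration per Newton, m/(N·s²);
* **progression potential** — anteroposterior COM acceleration per
  Newton, m/(N·s²).

States use two conventions: the chain coordinates θ₀..θ₃ and anatomical
(MSK) angles related by ankle = −θ₁, knee = −θ₂,
hip = θ₂+θ₁+θ₀−tilt, lumbar = hip+θ₃ (positive = dorsiflexion, knee
extension, hip flexion, lumbar extension, posterior pelvic tilt). The
sit-to-stand state space is the 5°-step grid over the momentum-transfer
ranges (ankle 0..40°, knee −100..−75°, θ₃ −150..−60°, tilt −60..20°)
constrained to hip ∈ [15°, 120°] and lumbar ∈ [−90°, 60°] — exactly
14,758 states. Derived per state: foot position (horizontal hip→ankle
distance) and pelvis height (vertical ankle→hip distance), both
normalized to leg length L₁+L₂.

Moment arms come from pluggable providers: a bundled synthetic 2D muscle
geometry (eight actuators, straight-segment paths with pulley-style via
points) or a tabulated CSV of arms exported from any musculoskeletal
modeling tool. The statistical layer applies a rank-based inverse normal
transform (Blom scores) and Pearson correlations of potentials against
four kinematic modifiers, with the published strength bands (very weak
|r| < 0.2 … very strong |r| ≥ 0.8).

## Worked example

Compute potentials for one forward-leaning mid-transfer state
(ankle 20°, knee −90°, hip 100°, lumbar −15°, pelvic tilt −30°):

```sh
cat > state.toml <<'EOF'
[grid.ranges]
theta1 = [-20, -20]
theta2 = [90, 90]
theta3 = [-115, -115]
pelvic_tilt = [-30, -30]
EOF
stspotentials potentials --config state.toml --out-dir out
```

which writes `out/potentials.csv` containing (×10⁻³ m/(N·s²)):

```
state: ankle 20, knee -90, hip 100, lumbar -15, tilt -30
foot_position 0.272, pelvis_height 0.653
gluteus_maximus          support +0.53e-3  progression +0.09e-3
biceps_femoris_lh        support +1.10e-3  progression +0.54e-3
rectus_femoris           support +0.34e-3  progression -0.44e-3
vasti                    support +1.47e-3  progression -0.25e-3
gastrocnemius_medialis   support +0.42e-3  progression +3.22e-3
gastrocnemius_lateralis  support +0.52e-3  progression +3.20e-3
soleus                   support +1.53e-3  progression +3.03e-3
tibialis_anterior        support -1.84e-3  progression -3.64e-3
```

Every extensor and plantarflexor buys upward COM acceleration in this
posture (about 1.5 mm·s⁻² of vertical COM acceleration per Newton of
soleus force), the plantarflexors dominate forward progression, and
tibialis anterior opposes both — the expected division of labor during
the momentum-transfer phase.

Other entry points:

```sh
stspotentials enumerate  --out-dir out    # the 14,758-state grid as CSV
stspotentials potentials --out-dir out --aggregate-by pelvic_tilt --plot
stspotentials correlate  --out-dir out    # 56-row rank-INT Pearson report
stspotentials fixtures   --out-dir out    # write the bundled input files
```

## Fidelity boundary

Per-link anthropometry and muscle attachment coordinates are original
synthetic fixtures constrained to the generic-model totals (75.2 kg body
mass, 0.826 m leg length); they reproduce anatomical moment-arm signs,
magnitudes and angle trends, not any specific musculoskeletal model's
values. Correlation *signs* and strength structure are therefore
meaningful; exact coefficients depend on the moment-arm source. See
`docs/methods.md`.
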