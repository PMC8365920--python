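# Methods

This note documents the models, the numerical choices, and the places where
the design was genuinely open. Everything quantitative here is computed by
the test suite or `scripts/acceptance.py`; nothing is asserted from memory.

## Skeleton and dynamics

The walker is a planar (sagittal) kinematic tree with 9 generalized
coordinates: pelvis translation (x, y), trunk pitch, and hip/knee/ankle
angles per leg. All angles are counter-clockwise rotations in the x-up
plane, so a *forward* trunk lean is negative pitch; hip flexion is
positive, knee flexion negative (0 = straight), ankle dorsiflexion
positive (0 = foot flat). Both hips coincide with the pelvis origin — the
sagittal projection has no pelvis width.

Default anthropometry (`data/default_model.yaml`) is a 75 kg / 1.8 m adult
from standard segment-parameter tables: a 50.85 kg head-arms-trunk segment
and per-leg thigh (7.5 kg, 0.44 m), shank (3.5 kg, 0.43 m) and foot
(1.1 kg, 0.25 m). Joint limits are soft: outside the range a stiff
spring-damper (2000 N·m/rad, 30 N·m·s/rad) opposes the violation, and a
small passive viscous damping (0.3 N·m·s/rad) acts at every joint. The
limit stiffness must dominate the strongest knee extensor torque
(~360 N·m), otherwise sustained co-activation parks the knee far beyond
its stop and statics become wrong.

Dynamics are assembled from point Jacobians. For a planar tree, the
velocity of any material point is `v = v_base + Σ_a q̇_a R90 (p − c_a)`
over the angle dofs above it (c_a = joint center of dof a, R90 = +90°
rotation); the columns `R90 (p − c_a)` are the Jacobian, the mass matrix is
`M = Σ_b J_bᵀ diag(m, m, I) J_b`, and the velocity-product forces follow by
differentiating the same identity, so the bias term is analytic (no finite
differences). The identical assembly code drives an n-link serial pendulum
(`SerialChain`) used by the validation oracles: single-pendulum
acceleration matches the closed form to machine precision and a double
pendulum conserves energy to < 0.1 % over 5 s at a 0.1 ms substep. The
momentum-conservation property is checked on the equations of motion
(dP/dt = 0 under zero gravity and no contact), separating the assembly
property from integrator truncation, which for the semi-implicit scheme is
first-order (the ballistic test's COM altitude carries the expected
0.5·g·h·t bias).

Time stepping is semi-implicit (symplectic) Euler, 10 substeps of 1 ms per
0.01 s control step — stable for the stiff contact at desk-scale cost and
bit-deterministic for identical inputs. The conservative-dynamics tests
choose finer substeps (0.25–0.1 ms) because they measure integrator
quality itself; the environment default stays at 1 ms.

Ground contact: three spheres per foot (heel/mid/toe, radius 2.5 cm). The
normal law is Hunt–Crossley style, `F_n = k d^1.5 (1 + c ḋ)` with
k = 1.2·10⁶ N/m^1.5 and c = 1.2 s/m, clamped at zero (no adhesion);
tangential force is smoothed Coulomb, `−μ F_n tanh(v_x / v_s)` with
μ = 0.8 and v_s = 0.05 m/s, so it opposes slip and saturates at μF_n.

## Muscles

Each of the 22 muscle-tendon units (11 per leg: HAB, HAD, HFL, GLU, HAM,
RF, VAS, BFSH, GAS, SOL, TA) is a Hill-type model:

* **Activation**: first-order ODE `ȧ = (e − a)/τ`, τ_act = 15 ms rising,
  τ_deact = 50 ms falling, integrated exactly (exponential update).
  Excitations outside [0, 1] are clamped and flagged, not rejected — RL
  policies emit unconstrained outputs.
* **Active force-length**: Gaussian bell, unit peak at the optimal CE
  length, half-width 0.45 l_opt.
* **Force-velocity**: rectangular hyperbola on the concentric side (1 at
  v = 0, 0 at the maximum shortening velocity, curvature 0.25) and a
  slope-matched hyperbolic eccentric branch saturating at 1.5 f_max.
* **Passive element**: engages at the optimal length, quadratic up to a
  stretch of 0.5 l_opt (where it reaches f_max), then *linear* with
  matched slope. The linear continuation bounds the passive joint
  stiffness, which keeps the rigid-tendon model integrable under the large
  normalized excursions short-fibered muscles (SOL, GAS) see.
* **Tendon**: rigid by default — CE length = path length − slack length.
  An elastic-tendon mode (stiff quadratic tendon reaching f_max at 4 %
  strain, per-step CE/SE force balance by root-finding) exists behind
  `elastic_tendon=True` but is off by default for speed and robustness.

The muscle path model is affine: constant moment arms per muscle-joint
pair, calibrated so the neutral standing pose has every normalized CE
length at 1. Biarticular coupling (HAM, RF, GAS) is preserved through two
nonzero arms. This is the simplest model that keeps the force-sharing
structure of the leg; it ignores arm variation with joint angle.

Effort is `Σ_m A_m² Δt` per simulation step — activation squared, not a
metabolic model.

## Reward, footsteps, targets

The scoring constants and the J = R_alive + R_step + R_target
decomposition are in the README. Choices the reward text leaves open:

* **Footstep segmentation**: a footstep closes when a foot that has been
  airborne ≥ 50 ms regains contact (the minimum-swing filter removes
  contact chatter); a *forced closure* fires after 5 s without an event so
  standing is still scored; the trailing partial step is closed and scored
  at episode end (config-exposed). Under this rule Σ b_s over an episode
  always equals the episode duration, which yields the segmentation
  invariance the step bonus is designed for (tested: any partition of a
  zero-cost episode gives the same Σ w_s·b_s).
* **v_tgt0** is the commanded field evaluated at the pelvis position at
  each simulation step.
* **Field geometry**: vectors point at the current target with magnitude
  equal to the commanded speed (default 1.4 m/s, a typical human walking
  speed), tapering linearly to zero inside the 0.3 m proximity radius, so
  stopping on the target is the commanded behavior.
* **Target sampling**: uniform annulus 2–6 m around the current pelvis
  position, dwell uniform in [2, 4] s, all from the episode seed. In the
  planar environment binding targets are placed on the +x axis (the
  walker's reachable direction); the task module itself is fully 2-D and
  is exercised in 2-D by the fixtures.
* **Local map**: 11 × 11 grid, 0.5 m spacing, body-heading frame,
  flattened as 121 forward components (row-major) then 121 lateral ones —
  11·11·2 = 242, the unique natural square-grid factorization of the map
  size.

## Observations

compat-22 body vector (97) = 9 pelvis entries (height, pitch, roll,
3 linear + 3 angular velocities — out-of-plane slots exact zeros) + per leg
44: 3 GRF components normalized by body weight (z = 0), 4 joint angles and
4 speeds (abduction slots zero), and 11 muscles × (force/f_max,
l_ce/l_opt, v_ce/(l_opt·v_max)); right leg first. planar-18 (81) = 5
pelvis entries + per leg 38: 2 GRF, foot pose relative to the pelvis
(x, y, orientation), 3 angles, 3 speeds, 9 muscles × 3. The layouts are
frozen interface; tests pin them.

Termination: pelvis height < 0.6 m (config-exposed fall threshold) or
2500 steps.

## Baseline controllers

`stand_policy` holds quiet standing with constant knee/hip co-activation,
a trunk-lean PD mapped to GLU/HFL/HAM, and an ankle strategy (mean ankle
dorsiflexion angle drives SOL vs TA). Its gains were tuned once with the
package's own ES; standing is verified for ≥ 5 s in the suite. The policy
biases slightly toward forward sway because the plantarflexors (SOL,
240 N·m capacity) can arrest a forward fall while TA (32 N·m) cannot
arrest a backward one — the same asymmetry human posture shows.

`reflex_policy` is a reflex-style lower layer: per-leg stance/swing finite
state machine gated on the leg's normalized vertical GRF; stance uses
positive force feedback on the extensors (SOL, GAS, VAS), trunk-balance
feedback at the hip (GLU/HAM vs HFL), and SOL-force inhibition of TA;
swing uses HFL/TA offsets with HAM-stretch length feedback and an
early-swing BFSH knee-flexion burst. A short forced-swing lead-in on the
left leg breaks the symmetry of the standing start. All feedback reads
observation entries only. The shipped parameter vector
(`data/reflex_walker.json`) is the output of the repository's own
(μ,λ)-ES run (`examples/tune_reflex_gait.py` with a larger budget); the
acceptance property is *sustained stepping* — ≥ 10 footstep events without
falling — not human-likeness, which would require gait-data comparisons
out of scope here.

`search_params` is a seeded (μ,λ) evolution strategy: Gaussian proposals
around the elite mean (top quarter), geometric per-coordinate step-size
decay, bound clipping, non-finite fitness treated as worst. It is
deliberately small and dependency-free; its sanity oracle (10-D sphere to
< 10⁻² in 2000 evaluations) runs in the suite.

## Synthetic fixtures and what they show

The harness generates trajectory logs whose rewards are known in closed
form: piecewise-constant pelvis-velocity errors, alternating zero-mean
within-footstep fluctuation, scheduled footstep boundaries realized by
60 ms swings, constant activation vectors, and target-course episodes in
which the pelvis follows the commanded field exactly (constant speed
outside the proximity radius, exponential approach inside it — the
velocity error is identically zero by construction). The expected J and
its decomposition are computed by a literal transcription of the reward
sum over these segments, deliberately independent of the incremental
ledger; 200 random fixtures agree to 10⁻⁹ in the suite.

The fixtures emulate the *reward-relevant* structure of an episode —
velocity traces, contact sequences, activation traces, target reaches —
but not physical consistency: positions need not integrate velocities, and
contact flags are scheduled, not simulated. Passing fixture tests
therefore validates the scoring system exactly, and says nothing about
gait realism; the dynamics are validated separately by the closed-form
mechanics oracles, and the two meet in the environment tests (per-step
rewards of simulated episodes sum to the episode decomposition).

## Known limitations

* Planar core: no lateral balance, no internal yaw; HAB/HAD are
  effort-and-observation channels only (compat-22).
* Constant moment arms; rigid tendon by default; no pennation,
  history-dependent force, or metabolic energetics.
* The shipped reflex gait is a stability baseline; its kinematics are not
  matched to human data.
* No claim of numerical equivalence with any other simulation platform:
  interface shapes and scoring constants are reproduced, model internals
  (inertial parameters, contact constants, activation constants) are this
  package's own documented defaults.
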