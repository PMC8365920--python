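# planargait

A desk-scale, fully self-contained neuromechanical locomotion environment:
a sagittal-plane 7-segment human walker (HAT trunk, two legs of thigh,
shank, foot) actuated by 22 Hill-type muscle-tendon units, with ground
contact, a footstep-segmented reward system, a target-velocity navigation
task, an agent-facing reset/step interface, and non-learned reflex baseline
controllers. It is written for researchers who want a reproducible,
dependency-light testbed for locomotion control — reinforcement learning,
reflex models, or derivative-free policy search — without any external
simulator or download.

## The reward system

An episode runs at Δt = 0.01 s for up to 2500 simulation steps. The return
decomposes exactly into three terms:

```
J = R_alive + R_step + R_target
  = Σ_{i_sim} b_alive
    + Σ_{i_step} ( w_s·b_s − w_v·c_v − w_e·c_e )
    + Σ_{i_target} b_target
```

with b_alive = 0.1 per non-fallen step, w_s = 10, w_v = 3, w_e = 1 and
b_target = 500. Footsteps (`i_step`) are the intervals between successive
foot touch-down events; per footstep,

* `b_s = Σ Δt` — the footstep duration, so the step bonus cannot be gamed
  by taking many small steps;
* `c_v = ‖Σ (v_pel − v_tgt0) Δt‖₂` — the norm of the *integrated* velocity
  error against the commanded field `v_tgt0`, so instantaneous velocity may
  fluctuate freely within a footstep;
* `c_e = Σ Σ_m A_m² Δt` — integrated squared muscle activations, a standard
  fatigue proxy.

Targets are sampled 2–6 m away; holding the pelvis within 0.3 m of a target
for a required dwell time (uniform in 2–4 s) pays `b_target` and advances to
the next of the episode's two targets. The hypothetical maximum of a
zero-cost, full-length, two-target episode is `250 + 250 + 1000 = 1500`.

The agent interface (compat-22 mode) is a 97-dim body observation, a
242-dim local target-velocity map (11×11 grid × 2 components), and a 22-dim
muscle-excitation action. Because the dynamics core is planar, the hip
ab-/adductors (HAB/HAD) have no mechanical action in compat-22: they cost
effort and appear in the observation, keeping the published interface
shape. The native `planar-18` mode exposes 18 muscles and an 81-dim body
vector. See `docs/methods.md` for the model, the layouts, and every
numerical choice.

## Worked example

```bash
python examples/score_max_reward_fixture.py
```

builds the maximum-reward synthetic episode with the harness and scores it
with the footstep ledger:

```
closed-form expectation: J = 1500.0
episode score report
  J        = 1500
  R_alive  = 250
  R_step   = 250
  R_target = 1000
  steps simulated: 2500, targets reached: 2
  footsteps (b_s [s], c_v [m], c_e [a^2 s], reward):
      1    0.5000    0.000000    0.000000    5.000000
      ...
     50    0.5000    0.000000    0.000000    5.000000
```

Every one of the fifty 0.5 s footsteps earns `w_s·b_s = 5` with zero
velocity and effort cost (the pelvis tracks the commanded field exactly and
all activations are zero); the alive bonus contributes 2500 × 0.1 = 250 and
the two dwell bonuses 1000.

Other entry points:

```bash
python examples/run_standing_episode.py     # physics + stand controller
python examples/reflex_walking.py           # shipped reflex gait
python examples/tune_reflex_gait.py         # (mu,lambda)-ES search demo
planargait simulate --steps 200             # CLI: constant excitation
planargait rollout-baseline --policy reflex --steps 1000 --log ep.csv
planargait score-trajectory ep.csv          # offline reward decomposition
planargait replay-plot ep.csv --out ep.png
```

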