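"""Agent-facing locomotion environment.

Binds the planar walker dynamics, the Hill-type muscles, and the
target-velocity task into a reset/step loop mirroring the de-facto RL
environment API: ``reset() -> observation`` and
``step(action) -> (observation, reward, done, info)``. One control step is
0.01 s; an episode caps at 2500 steps (25 s) or ends when the pelvis drops
below the fall threshold.

Two interface modes:

* ``compat-22`` — the full published interface: 22 muscle excitations
  (11 per leg including the hip ab-/adductors HAB and HAD), a 97-dim body
  observation and a 242-dim target-velocity map. Because the dynamics core
  is sagittal, HAB/HAD carry no mechanical action: their excitations drive
  activation dynamics (and hence the effort cost and their observation
  entries) but never the equations of motion, and the out-of-plane
  observation slots (roll, lateral velocities, abduction angles) are exact
  zeros.
* ``planar-18`` — the native planar interface: 18 excitations (9 muscles
  per leg) and an 81-dim body observation with no zero-padded slots.

Body observation layouts (documented interface, frozen):

compat-22 (97) = pelvis block 9
    [height, pitch, roll=0, vx, vy, vz=0, pitch_rate, roll_rate=0,
     yaw_rate=0]
  + per leg (right first) 44
    [GRF_x/W, GRF_y/W, GRF_z=0,
     hip_abduction=0, hip, knee, ankle angles,
     abduction_rate=0, hip, knee, ankle rates,
     11 muscles x (force/f_max, l_ce/l_opt, v_ce/(l_opt v_max))]

planar-18 (81) = pelvis block 5
    [height, pitch, vx, vy, pitch_rate]
  + per leg (right first) 38
    [GRF_x/W, GRF_y/W,
     foot position relative to pelvis x, y, foot orientation,
     hip, knee, ankle angles, hip, knee, ankle rates,
     9 muscles x (force/f_max, l_ce/l_opt, v_ce/(l_opt v_max))]

where W is body weight. Muscle order within a leg is always
HAB, HAD, HFL, GLU, HAM, RF, VAS, BFSH, GAS, SOL, TA (HAB/HAD dropped in
planar-18).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import (BodyState, Kinematics, MusclePaths, SkeletonParams,
                   WalkerDynamics, standing_state)
from .config import build_model, load_model_config
from .muscle import MUSCLES_PER_LEG, MuscleState
from .task import RewardConfig, TaskScorer, TargetSpec

BODY_DIM = {"compat-22": 97, "planar-18": 81}
MAP_DIM = 242
ACTION_DIM = {"compat-22": 22, "planar-18": 18}
PLANAR_MUSCLES = tuple(m for m in MUSCLES_PER_LEG if m not in ("HAB", "HAD"))


@dataclass
class Observation:
    """Body sensory vector plus the local target-velocity map."""

    body: np.ndarray
    vtgt_map: np.ndarray

    def __post_init__(self) -> None:
        self.body = np.asarray(self.body, float)
        self.vtgt_map = np.asarray(self.vtgt_map, float)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.body, self.vtgt_map])


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode-level settings of the environment."""

    seed: int = 0
    mode: str = "compat-22"
    max_steps: int = 2500
    fall_threshold: float = 0.6      # m pelvis height
    substeps: int = 10
    speed: float = 1.4               # commanded walking speed, m/s
    annulus: tuple[float, float] = (2.0, 6.0)
    elastic_tendon: bool = False

    def __post_init__(self) -> None:
        if self.mode not in BODY_DIM:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_steps < 1 or self.substeps < 1:
            raise ValueError("max_steps and substeps must be >= 1")
        if self.fall_threshold <= 0:
            raise ValueError("fall_threshold must be positive")


def _muscle_names(mode: str) -> list[str]:
    per_leg = MUSCLES_PER_LEG if mode == "compat-22" else PLANAR_MUSCLES
    return [f"{m}_{s}" for s in ("R", "L") for m in per_leg]


def build_observation(
    state: BodyState,
    muscle_states: list[MuscleState],
    muscle_params: list,
    paths: MusclePaths,
    skel: SkeletonParams,
    vtgt_map: np.ndarray,
    mode: str = "compat-22",
) -> Observation:
    """Assemble the documented observation layout from raw state."""
    q, qdot = state.q, state.qdot
    weight = skel.total_mass * skel.gravity
    _, mtu_vels, _ = paths.muscle_geometry(q, qdot)
    kin = Kinematics(skel, q, qdot)

    def leg_block(side: int) -> np.ndarray:
        # side 0 = right, 1 = left
        grf = state.contact_forces[3 * side:3 * side + 3].sum(axis=0) / weight
        j = 3 + 3 * side
        angles = q[j:j + 3]
        rates = qdot[j:j + 3]
        n_leg = len(muscle_states) // 2
        entries = []
        for k in range(n_leg):
            m = side * n_leg + k
            mp, ms = muscle_params[m], muscle_states[m]
            entries += [
                ms.force / mp.f_max,
                ms.l_ce_norm,
                mtu_vels[m] / (mp.l_opt * mp.v_max),
            ]
        if mode == "compat-22":
            return np.concatenate([
                [grf[0], grf[1], 0.0],
                [0.0], angles,
                [0.0], rates,
                entries,
            ])
        ankle = kin.joints["ankle_r" if side == 0 else "ankle_l"]
        foot_ang = kin.seg_angles[3 if side == 0 else 6]
        rel = ankle - kin.pelvis
        return np.concatenate([
            [grf[0], grf[1]],
            [rel[0], rel[1], foot_ang],
            angles, rates,
            entries,
        ])

    if mode == "compat-22":
        pelvis = np.array([
            q[1], q[2], 0.0,
            qdot[0], qdot[1], 0.0,
            qdot[2], 0.0, 0.0,
        ])
    else:
        pelvis = np.array([q[1], q[2], qdot[0], qdot[1], qdot[2]])

    body = np.concatenate([pelvis, leg_block(0), leg_block(1)])
    assert len(body) == BODY_DIM[mode]
    obs = Observation(body=body, vtgt_map=np.asarray(vtgt_map, float))
    if not (np.all(np.isfinite(obs.body))
            and np.all(np.isfinite(obs.vtgt_map))):
        raise FloatingPointError("non-finite observation")
    return obs


def check_termination(state: BodyState, step_count: int,
                      config: EpisodeConfig) -> bool:
    """True iff the pelvis fell below the threshold or the episode capped."""
    return (state.pelvis_height < config.fall_threshold
            or step_count >= config.max_steps)


class PlanarWalkEnv:
    """Planar musculoskeletal walking environment with target navigation.

    Parameters
    ----------
    config : EpisodeConfig
        Mode, seed, episode length, fall threshold.
    model_config : dict, optional
        Model config (see ``planargait.config``); packaged default if None.
    reward_config : RewardConfig, optional
        Scoring constants; standard-task defaults if None.
    targets : list[TargetSpec], optional
        Fixed target sequence overriding seeded sampling (for tests).
    """

    def __init__(
        self,
        config: EpisodeConfig | None = None,
        model_config: dict | None = None,
        reward_config: RewardConfig | None = None,
        targets: list[TargetSpec] | None = None,
    ):
        self.config = config or EpisodeConfig()
        self.model_config = model_config or load_model_config()
        self.reward_config = reward_config or RewardConfig(
            max_sim_steps=self.config.max_steps)
        skel, muscles22, paths = build_model(self.model_config)
        if self.config.mode == "planar-18":
            keep = [i for i, mp in enumerate(muscles22)
                    if mp.name.rsplit("_", 1)[0] not in ("HAB", "HAD")]
            muscles = [muscles22[i] for i in keep]
            paths = MusclePaths(
                muscles, paths.joint_index,
                paths.neutral_lengths[keep], paths.moment_arms[keep])
        else:
            muscles = muscles22
        self.skel = skel
        self.muscles = muscles
        self.paths = paths
        self.dynamics = WalkerDynamics(
            skel, paths, muscles, elastic_tendon=self.config.elastic_tendon)
        self._fixed_targets = targets
        self.state: BodyState | None = None
        self.muscle_states: list[MuscleState] = []
        self.scorer: TaskScorer | None = None
        self.step_count = 0
        self.done = True
        self.result = None
        self.trajectory: list[dict] = []

    # -- core loop --------------------------------------------------------

    def reset(self) -> Observation:
        """Start a new episode: standing pose, first target sampled."""
        self.state = standing_state(self.skel)
        self.muscle_states = [MuscleState() for _ in self.muscles]
        rng = np.random.default_rng(self.config.seed)
        self.scorer = TaskScorer(
            self.reward_config,
            targets=self._fixed_targets,
            rng=rng,
            speed=self.config.speed,
            annulus=self.config.annulus,
            along_x=True,
        )
        self.scorer.start(self._pelvis_xy())
        self.step_count = 0
        self.done = False
        self.result = None
        self.trajectory = []
        return self._observe()

    def step(self, action: np.ndarray
             ) -> tuple[Observation, float, bool, dict]:
        """Advance one 0.01 s control step under the given excitations."""
        if self.done or self.scorer is None:
            raise RuntimeError("step() called on a finished episode; "
                               "call reset() first")
        act = np.asarray(action, float).ravel()
        n = ACTION_DIM[self.config.mode]
        if act.shape != (n,):
            raise ValueError(f"action must have length {n}")
        if not np.all(np.isfinite(act)):
            bad = int(np.flatnonzero(~np.isfinite(act))[0])
            raise ValueError(f"non-finite action entry at index {bad}")

        cfg = self.reward_config
        self.state, self.muscle_states, step_info = \
            self.dynamics.integrate_step(
                self.state, self.muscle_states, np.clip(act, 0.0, 1.0),
                dt=cfg.dt, substeps=self.config.substeps)
        self.step_count += 1

        fallen = self.state.pelvis_height < self.config.fall_threshold
        foot_contact = np.array([
            self.state.contact_flags[:3].any(),
            self.state.contact_flags[3:].any(),
        ])
        activations = np.array([s.activation for s in self.muscle_states])
        reward = self.scorer.step(
            pelvis_xy=self._pelvis_xy(),
            v_pel=self.state.v_pel,
            foot_contact=foot_contact,
            activations=activations,
            alive=not fallen,
        )

        self.done = check_termination(
            self.state, self.step_count, self.config)
        if self.done:
            r_step_before = self.scorer.R_step
            self.result = self.scorer.finish()
            reward += self.scorer.R_step - r_step_before

        self._log_row(act, activations)
        obs = self._observe()
        info = {
            "step": self.step_count,
            "fallen": fallen,
            "R_alive": self.scorer.R_alive,
            "R_step": self.scorer.R_step,
            "R_target": self.scorer.R_target,
            "ledger": self.scorer.ledger.copy_summary(),
            "target_index": (self.scorer.current_target.index
                             if self.scorer.current_target else None),
            "targets_reached": self.scorer.targets_reached,
            "clamped": step_info["clamped"],
            "degenerate": step_info["degenerate"],
            "result": self.result,
        }
        return obs, reward, self.done, info

    # -- helpers ----------------------------------------------------------

    def _pelvis_xy(self) -> np.ndarray:
        # ground-plane position of the planar walker: (world x, 0)
        return np.array([self.state.q[0], 0.0])

    def _observe(self) -> Observation:
        vmap = self.scorer.field.local_map(self._pelvis_xy(), heading=0.0) \
            if self.scorer.current_target is not None else np.zeros(MAP_DIM)
        return build_observation(
            self.state, self.muscle_states, self.muscles, self.paths,
            self.skel, vmap, self.config.mode)

    def _log_row(self, action, activations) -> None:
        s = self.state
        tgt = self.scorer.current_target
        self.trajectory.append({
            "time": s.time,
            "q": s.q.copy(), "qdot": s.qdot.copy(),
            "contact": s.contact_flags.copy(),
            "action": np.asarray(action, float).copy(),
            "activations": activations.copy(),
            "target_x": tgt.location[0] if tgt else np.nan,
            "target_y": tgt.location[1] if tgt else np.nan,
            "target_index": tgt.index if tgt else 0,
            "required_dwell": tgt.required_dwell if tgt else np.nan,
        })

    @property
    def observation_dims(self) -> tuple[int, int]:
        return BODY_DIM[self.config.mode], MAP_DIM

    @property
    def action_dim(self) -> int:
        return ACTION_DIM[self.config.mode]

    @property
    def muscle_names(self) -> list[str]:
        return _muscle_names(self.config.mode)
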