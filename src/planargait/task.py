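"""Target-velocity task and footstep-segmented reward computation.

The total return of an episode decomposes into three terms:

    J = R_alive + R_step + R_target
      = sum_{i_sim} b_alive
        + sum_{i_step} (w_s * b_s  -  w_v * c_v  -  w_e * c_e)
        + sum_{i_target} b_target

* ``R_alive`` pays a small bonus ``b_alive`` at every simulation step the
  model has not fallen.
* ``R_step`` scores each *footstep* (the interval between successive
  foot-contact events). The step bonus ``b_s`` is the footstep duration
  (sum of simulation steps, so segmentation cannot be gamed by taking many
  tiny steps); the velocity cost ``c_v`` is the Euclidean norm of the
  time-integral of (v_pel - v_tgt0) over the footstep, i.e. it penalizes the
  *average* velocity error and lets instantaneous velocity fluctuate freely
  within a footstep; the effort cost ``c_e`` integrates the summed squared
  muscle activations.
* ``R_target`` pays a large bonus per target location reached and held
  within the proximity radius for the required dwell time.

With default constants (b_alive=0.1, w_s=10, w_v=3, w_e=1, b_target=500,
dt=0.01 s, 2500 steps, two targets) the hypothetical maximum of a zero-cost
trial is 250 + 250 + 1000 = 1500.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RewardConfig:
    """Constants of the scoring system (defaults: the standard two-target task)."""

    b_alive: float = 0.1
    w_s: float = 10.0
    w_v: float = 3.0
    w_e: float = 1.0
    b_target: float = 500.0
    dt: float = 0.01
    max_sim_steps: int = 2500
    n_targets: int = 2
    proximity_radius: float = 0.3
    dwell_range: tuple[float, float] = (2.0, 4.0)
    # footstep segmentation (the reward text defines footsteps only
    # implicitly; these rules are the package's, see docs/methods.md)
    min_swing_time: float = 0.05      # s airborne before touch-down counts
    forced_closure: float = 5.0       # s without an event closes the step
    score_trailing_partial: bool = True

    def __post_init__(self) -> None:
        if min(self.b_alive, self.w_s, self.w_v, self.w_e, self.b_target,
               self.dt, self.proximity_radius) <= 0:
            raise ValueError("reward constants must be positive")
        if self.max_sim_steps < 1 or self.n_targets < 1:
            raise ValueError("max_sim_steps and n_targets must be >= 1")
        if not (0 < self.dwell_range[0] <= self.dwell_range[1]):
            raise ValueError("invalid dwell range")


def alive_increment(config: RewardConfig) -> float:
    """Per-simulation-step survival bonus (model has not fallen)."""
    return config.b_alive


@dataclass
class TargetSpec:
    """One target location with its dwell requirement."""

    index: int                      # i_target, 1-based
    location: np.ndarray            # (2,) world ground-plane position, m
    required_dwell: float           # s
    awarded: bool = False
    dwell_accrued: float = 0.0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        if self.location.shape != (2,):
            raise ValueError("target location must be a 2-vector")
        if self.required_dwell <= 0:
            raise ValueError("required_dwell must be positive")


def sample_target(
    rng: np.random.Generator,
    pelvis_xy: np.ndarray,
    index: int,
    config: RewardConfig,
    annulus: tuple[float, float] = (2.0, 6.0),
    along_x: bool = False,
) -> TargetSpec:
    """Sample a new target uniformly in an annulus around the pelvis.

    The dwell requirement is uniform in ``config.dwell_range``. With
    ``along_x`` the target is placed on the +x axis (the reachable direction
    of the planar walker); otherwise the angle is uniform in the plane.
    Deterministic for a given generator state.
    """
    r = rng.uniform(*annulus)
    theta = 0.0 if along_x else rng.uniform(0.0, 2.0 * np.pi)
    loc = np.asarray(pelvis_xy, float) + r * np.array(
        [np.cos(theta), np.sin(theta)])
    dwell = rng.uniform(*config.dwell_range)
    return TargetSpec(index=index, location=loc, required_dwell=dwell)


def update_target(
    spec: TargetSpec, pelvis_xy: np.ndarray, dt: float, config: RewardConfig
) -> tuple[float, TargetSpec, bool]:
    """Advance the dwell clock; award the bonus when the dwell completes.

    The clock accrues while the pelvis stays within the proximity radius of
    the target and resets to zero when it leaves. Returns
    (bonus, updated spec, advance) where ``advance`` signals that the next
    target should be sampled.
    """
    if spec.awarded:
        return 0.0, spec, False
    dist = float(np.linalg.norm(np.asarray(pelvis_xy, float) - spec.location))
    if dist <= config.proximity_radius:
        spec.dwell_accrued += dt
    else:
        spec.dwell_accrued = 0.0
    if spec.dwell_accrued >= spec.required_dwell:
        spec.awarded = True
        return config.b_target, spec, True
    return 0.0, spec, False


@dataclass
class VelocityField:
    """Commanded-velocity field pointing toward the current target.

    Outside the proximity radius the field magnitude is the commanded speed;
    inside it tapers linearly to zero at the target, so stopping on the
    target is the commanded behavior.
    """

    target: np.ndarray                     # (2,) world position
    speed: float = 1.4                     # m/s commanded walking speed
    proximity_radius: float = 0.3
    grid_n: int = 11                       # local map is grid_n x grid_n
    grid_spacing: float = 0.5              # m

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, float)

    def velocity_at(self, xy: np.ndarray) -> np.ndarray:
        """Field vector (world frame) at a ground-plane position."""
        xy = np.asarray(xy, float)
        d = self.target - xy
        dist = float(np.linalg.norm(d))
        if dist < 1e-12:
            return np.zeros(2)
        mag = self.speed * min(1.0, dist / self.proximity_radius)
        return (mag / dist) * d

    def local_map(self, pelvis_xy: np.ndarray, heading: float = 0.0
                  ) -> np.ndarray:
        """Flattened body-frame local velocity map.

        An 11 x 11 grid of field vectors centered on the pelvis, axes
        aligned with the body heading, flattened as all forward components
        (row-major) followed by all lateral components: 2 * 11^2 = 242
        entries. The center cell is the v_tgt0 the reward uses.
        """
        n, s = self.grid_n, self.grid_spacing
        c, sn = np.cos(heading), np.sin(heading)
        fwd = np.array([c, sn])
        lat = np.array([-sn, c])
        offs = (np.arange(n) - n // 2) * s
        base = np.asarray(pelvis_xy, float)
        # row-major: rows = forward offset, cols = lateral offset
        df, dl = np.meshgrid(offs, offs, indexing="ij")
        pts = base + df[..., None] * fwd + dl[..., None] * lat
        d = self.target - pts
        dist = np.linalg.norm(d, axis=-1)
        mag = self.speed * np.minimum(1.0, dist / self.proximity_radius)
        scale = np.where(dist > 1e-12, mag / np.maximum(dist, 1e-12), 0.0)
        v = scale[..., None] * d
        return np.concatenate([(v @ fwd).ravel(), (v @ lat).ravel()])


def local_velocity_map(field: VelocityField, pelvis_xy, heading=0.0):
    """Module-level alias of :meth:`VelocityField.local_map`."""
    return field.local_map(pelvis_xy, heading)


# --------------------------------------------------------------------------
# Footstep segmentation and accounting
# --------------------------------------------------------------------------

@dataclass
class FootstepRecord:
    duration: float          # b_s (s)
    velocity_cost: float     # c_v (m)
    effort_cost: float       # c_e (activation^2 s)
    reward: float


@dataclass
class FootstepLedger:
    """Per-footstep accumulators for b_s, the c_v integrand, and c_e.

    An *open* step accrues duration, the 2-vector velocity-deviation
    integral, and the effort integral; closing it computes the step reward
    and appends an immutable record.
    """

    i_step: int = 0
    open_duration: float = 0.0
    open_velocity_integral: np.ndarray = field(
        default_factory=lambda: np.zeros(2))
    open_effort: float = 0.0
    records: list[FootstepRecord] = field(default_factory=list)
    # airborne-time trackers for the two feet, for event detection
    airborne_time: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def copy_summary(self) -> dict:
        return {
            "i_step": self.i_step,
            "open_duration": self.open_duration,
            "open_velocity_integral": self.open_velocity_integral.copy(),
            "open_effort": self.open_effort,
            "n_closed": len(self.records),
        }


def detect_footstep_event(
    ledger: FootstepLedger,
    prev_contact: np.ndarray,
    curr_contact: np.ndarray,
    dt: float,
    config: RewardConfig,
) -> str:
    """Classify this simulation step: ``"none"`` or ``"new_step"``.

    A new footstep begins when a foot that has been airborne for at least
    ``min_swing_time`` regains ground contact (touch-down), filtering out
    contact chatter. A forced closure fires when the open step has lasted
    ``forced_closure`` seconds without an event, so standing phases are
    still scored. Updates the ledger's airborne timers in place.

    ``prev_contact`` / ``curr_contact`` are per-foot booleans (any sphere of
    that foot in contact).
    """
    prev = np.asarray(prev_contact, bool)
    curr = np.asarray(curr_contact, bool)
    event = "none"
    for foot in range(2):
        if curr[foot]:
            if (not prev[foot]
                    and ledger.airborne_time[foot] >= config.min_swing_time):
                event = "new_step"
            ledger.airborne_time[foot] = 0.0
        else:
            ledger.airborne_time[foot] += dt
    if event == "none" and ledger.open_duration >= config.forced_closure:
        event = "new_step"
    return event


def accumulate_step(
    ledger: FootstepLedger,
    v_pel: np.ndarray,
    v_tgt0: np.ndarray,
    activations: np.ndarray,
    dt: float,
) -> FootstepLedger:
    """Accrue one simulation step into the open footstep (in place)."""
    from .muscle import effort_increment

    ledger.open_duration += dt
    ledger.open_velocity_integral += (
        np.asarray(v_pel, float) - np.asarray(v_tgt0, float)) * dt
    ledger.open_effort += effort_increment(activations, dt)
    return ledger


def close_footstep(
    ledger: FootstepLedger, config: RewardConfig
) -> tuple[float, FootstepLedger]:
    """Close the open footstep, score it, and open the next one.

    reward = w_s * b_s - w_v * ||velocity integral||_2 - w_e * c_e
    """
    b_s = ledger.open_duration
    if b_s <= 0.0:
        warnings.warn("closing a zero-duration footstep", stacklevel=2)
        return 0.0, ledger
    c_v = float(np.linalg.norm(ledger.open_velocity_integral))
    c_e = ledger.open_effort
    reward = config.w_s * b_s - config.w_v * c_v - config.w_e * c_e
    ledger.records.append(FootstepRecord(b_s, c_v, c_e, reward))
    ledger.i_step += 1
    ledger.open_duration = 0.0
    ledger.open_velocity_integral = np.zeros(2)
    ledger.open_effort = 0.0
    return reward, ledger


# --------------------------------------------------------------------------
# Episode result
# --------------------------------------------------------------------------

@dataclass
class EpisodeResult:
    """Total return J with its exact three-term decomposition."""

    J: float
    R_alive: float
    R_step: float
    R_target: float
    r_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    footsteps: list[FootstepRecord] = field(default_factory=list)
    n_steps: int = 0
    targets_reached: int = 0

    def __post_init__(self) -> None:
        total = self.R_alive + self.R_step + self.R_target
        if abs(self.J - total) > 1e-9:
            raise ValueError(
                f"decomposition violated: J={self.J} != {total}")


def total_reward(
    R_alive: float,
    R_step: float,
    R_target: float,
    r_trace: np.ndarray | None = None,
    footsteps: list[FootstepRecord] | None = None,
    n_steps: int = 0,
    targets_reached: int = 0,
) -> EpisodeResult:
    """Assemble an :class:`EpisodeResult` enforcing J = sum of components."""
    return EpisodeResult(
        J=R_alive + R_step + R_target,
        R_alive=R_alive, R_step=R_step, R_target=R_target,
        r_trace=np.zeros(0) if r_trace is None else np.asarray(r_trace, float),
        footsteps=footsteps or [],
        n_steps=n_steps, targets_reached=targets_reached,
    )


class TaskScorer:
    """Incremental scorer driving the ledger/target machinery step by step.

    Feed it one simulation step at a time (pelvis velocity and ground-plane
    position, per-foot contact flags, activations); it maintains the
    footstep ledger, the target dwell clocks, and the per-step reward trace.
    The env module and the offline trajectory scorer both run on this class.
    """

    def __init__(
        self,
        config: RewardConfig,
        targets: list[TargetSpec] | None = None,
        rng: np.random.Generator | None = None,
        speed: float = 1.4,
        annulus: tuple[float, float] = (2.0, 6.0),
        along_x: bool = False,
    ):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.speed = speed
        self.annulus = annulus
        self.along_x = along_x
        self.ledger = FootstepLedger()
        self.targets_fixed = targets is not None
        self._pending_targets = list(targets) if targets else []
        self.current_target: TargetSpec | None = None
        self.n_alive = 0
        self.R_step = 0.0
        self.R_target = 0.0
        self.r_trace: list[float] = []
        self.targets_reached = 0
        self._prev_contact = np.array([True, True])
        self.n_steps = 0

    def start(self, pelvis_xy: np.ndarray) -> None:
        self._next_target(pelvis_xy)

    def _next_target(self, pelvis_xy) -> None:
        idx = self.targets_reached + 1
        if idx > self.config.n_targets:
            self.current_target = None
            return
        if self.targets_fixed:
            self.current_target = (
                self._pending_targets.pop(0) if self._pending_targets else None)
        else:
            self.current_target = sample_target(
                self.rng, pelvis_xy, idx, self.config,
                annulus=self.annulus, along_x=self.along_x)

    @property
    def R_alive(self) -> float:
        # product form avoids accumulating 2500 tiny float additions
        return self.n_alive * self.config.b_alive

    @property
    def field(self) -> VelocityField:
        tgt = (self.current_target.location
               if self.current_target is not None else np.zeros(2))
        return VelocityField(target=tgt, speed=self.speed,
                             proximity_radius=self.config.proximity_radius)

    def v_tgt0(self, pelvis_xy) -> np.ndarray:
        if self.current_target is None:
            return np.zeros(2)
        return self.field.velocity_at(pelvis_xy)

    def step(
        self,
        pelvis_xy: np.ndarray,
        v_pel: np.ndarray,
        foot_contact: np.ndarray,
        activations: np.ndarray,
        alive: bool = True,
    ) -> float:
        """Score one simulation step; returns this step's reward."""
        cfg = self.config
        if self.current_target is None and self.n_steps == 0 \
                and self.targets_reached == 0:
            self.start(pelvis_xy)
        r = 0.0
        if alive:
            r += alive_increment(cfg)
            self.n_alive += 1

        event = detect_footstep_event(
            self.ledger, self._prev_contact, foot_contact, cfg.dt, cfg)
        v0 = self.v_tgt0(pelvis_xy)
        accumulate_step(self.ledger, v_pel, v0, activations, cfg.dt)
        if event == "new_step":
            step_r, _ = close_footstep(self.ledger, cfg)
            r += step_r
            self.R_step += step_r
        self._prev_contact = np.asarray(foot_contact, bool).copy()

        if self.current_target is not None:
            bonus, _, advance = update_target(
                self.current_target, pelvis_xy, cfg.dt, cfg)
            if bonus > 0.0:
                r += bonus
                self.R_target += bonus
                self.targets_reached += 1
            if advance:
                self._next_target(pelvis_xy)

        self.n_steps += 1
        self.r_trace.append(r)
        return r

    def finish(self) -> EpisodeResult:
        """Close the trailing partial footstep (if scored) and total up."""
        cfg = self.config
        trace = np.asarray(self.r_trace, float)
        if cfg.score_trailing_partial and self.ledger.open_duration > 0.0:
            step_r, _ = close_footstep(self.ledger, cfg)
            self.R_step += step_r
            if len(trace):
                trace[-1] += step_r
        return total_reward(
            self.R_alive, self.R_step, self.R_target,
            r_trace=trace, footsteps=list(self.ledger.records),
            n_steps=self.n_steps, targets_reached=self.targets_reached,
        )
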