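"""Fixture generation, trajectory file I/O, and offline scoring.

The fixture generator writes synthetic trajectory logs whose rewards are
known in closed form: pelvis velocity, contact-flag sequences, activation
traces, and target-reach scenarios are constructed analytically, and the
expected J with its full decomposition is computed by a direct literal
transcription of the reward definition over the piecewise-constant
segments — deliberately independent of the incremental ledger machinery in
``planargait.task``, so the two paths check each other.

Trajectory logs are plain CSV (12 significant digits) with a comment header
carrying the schema version, seed, and model-config hash. The same schema is
written by the environment's episode logger and read by the offline
``score_trajectory`` path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .muscle import MUSCLES_PER_LEG
from .task import (EpisodeResult, FootstepRecord, RewardConfig, TargetSpec,
                   TaskScorer, total_reward)

SCHEMA = "planargait-traj-v1"
ACT_COLUMNS = tuple(
    f"act_{m}_{s}" for s in ("R", "L") for m in MUSCLES_PER_LEG)
Q_COLUMNS = ("pelvis_x", "pelvis_y", "pitch", "hip_r", "knee_r", "ankle_r",
             "hip_l", "knee_l", "ankle_l")
QDOT_COLUMNS = ("vx", "vy", "pitch_rate", "hip_r_rate", "knee_r_rate",
                "ankle_r_rate", "hip_l_rate", "knee_l_rate", "ankle_l_rate")
COLUMNS = (
    ("time",) + Q_COLUMNS + QDOT_COLUMNS
    + ("gp_y", "v_gp_x", "v_gp_y", "contact_r", "contact_l", "alive")
    + ACT_COLUMNS
    + ("target_x", "target_y", "target_index", "required_dwell")
)


class TrajectoryValidationError(ValueError):
    """A trajectory file violates the documented schema."""


@dataclass
class TrajectoryLog:
    """A per-control-step trajectory table plus provenance metadata."""

    frame: pd.DataFrame
    seed: int = 0
    config_hash: str = "none"
    schema: str = SCHEMA

    def __post_init__(self) -> None:
        validate_frame(self.frame)

    def __eq__(self, other) -> bool:
        return (isinstance(other, TrajectoryLog)
                and self.seed == other.seed
                and self.config_hash == other.config_hash
                and self.schema == other.schema
                and self.frame.equals(other.frame))


def validate_frame(df: pd.DataFrame, dt: float = 0.01,
                   max_rows: int = 2500) -> None:
    if len(df) == 0:
        raise TrajectoryValidationError("empty trajectory: no data rows")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        n_act = sum(c.startswith("act_") for c in missing)
        detail = (f" ({n_act} of {len(ACT_COLUMNS)} activation columns "
                  f"missing)" if n_act else "")
        raise TrajectoryValidationError(
            f"missing columns: {missing}{detail}")
    if len(df) > max_rows:
        raise TrajectoryValidationError(
            f"{len(df)} rows exceed the {max_rows}-step episode cap")
    t = df["time"].to_numpy(float)
    if len(t) > 1 and not np.allclose(np.diff(t), dt, atol=1e-9):
        raise TrajectoryValidationError(
            "time column is not monotone at 0.01 s increments")


def write_trajectory(log: TrajectoryLog, path: str | Path) -> None:
    """Write a trajectory log as commented-header CSV."""
    buf = io.StringIO()
    buf.write(f"# schema: {log.schema}\n")
    buf.write(f"# seed: {log.seed}\n")
    buf.write(f"# config: {log.config_hash}\n")
    log.frame.to_csv(buf, index=False, float_format="%.12g",
                     columns=list(COLUMNS))
    Path(path).write_text(buf.getvalue())


def read_trajectory(path: str | Path) -> TrajectoryLog:
    """Read and validate a trajectory log; raises named schema errors."""
    text = Path(path).read_text()
    if not text.strip():
        raise TrajectoryValidationError(f"empty input file: {path}")
    meta = {"schema": SCHEMA, "seed": 0, "config": "none"}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, val = line.lstrip("# ").partition(":")
        if key.strip() in meta:
            meta[key.strip()] = val.strip()
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise TrajectoryValidationError(f"no data rows in {path}")
    df = pd.read_csv(io.StringIO(body))
    validate_frame(df)
    return TrajectoryLog(frame=df, seed=int(meta["seed"]),
                         config_hash=meta["config"], schema=meta["schema"])


def env_trajectory_log(env) -> TrajectoryLog:
    """Convert an environment's episode buffer into a TrajectoryLog."""
    rows = []
    names = env.muscle_names
    for r in env.trajectory:
        row = {"time": r["time"]}
        row.update(dict(zip(Q_COLUMNS, r["q"])))
        row.update(dict(zip(QDOT_COLUMNS, r["qdot"])))
        row["gp_y"] = 0.0
        row["v_gp_x"] = r["qdot"][0]
        row["v_gp_y"] = 0.0
        row["contact_r"] = int(r["contact"][:3].any())
        row["contact_l"] = int(r["contact"][3:].any())
        row["alive"] = int(r["q"][1] >= env.config.fall_threshold)
        acts = dict.fromkeys(ACT_COLUMNS, 0.0)
        for n, a in zip(names, r["activations"]):
            acts[f"act_{n}"] = a
        row.update(acts)
        row["target_x"] = r["target_x"]
        row["target_y"] = r["target_y"]
        row["target_index"] = r["target_index"]
        row["required_dwell"] = r["required_dwell"]
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    from .config import config_hash
    return TrajectoryLog(frame=df, seed=env.config.seed,
                         config_hash=config_hash(env.model_config))


# --------------------------------------------------------------------------
# Offline scoring
# --------------------------------------------------------------------------

def score_trajectory(
    log: TrajectoryLog,
    config: RewardConfig | None = None,
    speed: float = 1.4,
) -> EpisodeResult:
    """Score a logged trajectory with the incremental task machinery.

    Targets are reconstructed from the per-row target columns (location and
    required dwell at first appearance of each target index) and replayed as
    a fixed sequence, so scoring is a pure function of the file.
    """
    cfg = config or RewardConfig()
    df = log.frame
    targets = []
    seen = set()
    for _, row in df.iterrows():
        idx = int(row["target_index"])
        if idx >= 1 and idx not in seen:
            seen.add(idx)
            targets.append(TargetSpec(
                index=idx,
                location=np.array([row["target_x"], row["target_y"]]),
                required_dwell=float(row["required_dwell"]),
            ))
    scorer = TaskScorer(cfg, targets=targets, speed=speed)
    first = df.iloc[0]
    scorer.start(np.array([first["pelvis_x"], first["gp_y"]]))
    for _, row in df.iterrows():
        scorer.step(
            pelvis_xy=np.array([row["pelvis_x"], row["gp_y"]]),
            v_pel=np.array([row["v_gp_x"], row["v_gp_y"]]),
            foot_contact=np.array([bool(row["contact_r"]),
                                   bool(row["contact_l"])]),
            activations=row[list(ACT_COLUMNS)].to_numpy(float),
            alive=bool(row["alive"]),
        )
    return scorer.finish()


# --------------------------------------------------------------------------
# Fixture generation
# --------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Analytic description of a synthetic episode.

    ``footsteps`` lists scheduled footstep durations (s); they are realized
    by lifting alternate feet for a short swing before each boundary so the
    segmentation rules reproduce the schedule exactly. ``None`` means both
    feet stay planted (standing: only forced closures fire).

    With ``target_course`` (list of (distance, dwell) pairs) the pelvis
    follows the commanded velocity field exactly — full speed toward the
    target, exponential taper inside the proximity radius, standstill after
    the last award — so the velocity cost is identically zero; ``v_err`` and
    ``v_fluct`` must then be zero. Without a course, the commanded velocity
    is a constant ``speed`` toward a far target and the pelvis velocity is
    commanded + per-footstep constant error ``v_err`` + an alternating
    zero-mean fluctuation of amplitude ``v_fluct``.
    """

    n_steps: int = 2500
    footsteps: list[float] | None = None
    speed: float = 1.4
    v_err: tuple[float, float] | list[tuple[float, float]] = (0.0, 0.0)
    v_fluct: float = 0.0
    activations: np.ndarray | float = 0.0
    target_course: list[tuple[float, float]] | None = None
    config: RewardConfig = field(default_factory=RewardConfig)

    def __post_init__(self) -> None:
        cfg = self.config
        if not (1 <= self.n_steps <= cfg.max_sim_steps):
            raise ValueError("n_steps out of range")
        if self.footsteps is not None:
            if any(d < 0.2 or d > cfg.forced_closure for d in self.footsteps):
                raise ValueError(
                    "footstep durations must lie in [0.2 s, forced-closure)")
            if sum(self.footsteps) > self.n_steps * cfg.dt + 1e-9:
                raise ValueError("footsteps exceed the episode duration")
        if self.target_course is not None:
            err = np.atleast_2d(np.asarray(self.v_err, float))
            if self.v_fluct != 0.0 or np.any(err != 0.0):
                raise ValueError(
                    "target_course fixtures require zero velocity error")


def _boundary_rows(spec: FixtureSpec) -> list[int]:
    dt = spec.config.dt
    rows, cum = [], 0
    for d in spec.footsteps or []:
        cum += int(round(d / dt))
        rows.append(cum - 1)
    return [r for r in rows if r < spec.n_steps]


def _per_step_err(spec: FixtureSpec, n_foot: int) -> np.ndarray:
    err = np.asarray(spec.v_err, float)
    if err.ndim == 1:
        return np.tile(err, (max(n_foot, 1), 1))
    if len(err) != n_foot:
        raise ValueError("v_err list must match the footstep schedule")
    return err


def generate_fixture(
    spec: FixtureSpec, rng: np.random.Generator | int = 0
) -> tuple[TrajectoryLog, EpisodeResult]:
    """Build the trajectory log and its closed-form expected result.

    The expected rewards come from a literal evaluation of

        J = sum b_alive + sum_steps (w_s b_s - w_v c_v - w_e c_e)
            + sum_targets b_target

    over the analytic segments of the spec, never from the task module.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cfg = spec.config
    dt = cfg.dt
    n = spec.n_steps
    boundaries = set(_boundary_rows(spec))
    swing_rows = 6  # 0.06 s airborne, above the 0.05 s chatter filter

    acts = np.asarray(spec.activations, float)
    if acts.ndim == 0:
        acts = np.full(len(ACT_COLUMNS), float(acts))
    if acts.shape != (len(ACT_COLUMNS),):
        raise ValueError("activations must be scalar or a 22-vector")
    effort_rate = float(np.sum(acts**2))  # per second

    # contact flags: alternate the swinging foot per scheduled boundary
    contact = np.ones((n, 2), dtype=int)
    for j, b in enumerate(sorted(boundaries)):
        foot = j % 2
        lo = max(0, b - swing_rows)
        contact[lo:b, foot] = 0

    # pelvis motion and targets
    pos = np.zeros((n, 2))
    vel = np.zeros((n, 2))
    tgt_x = np.full(n, np.nan)
    tgt_y = np.full(n, np.nan)
    tgt_idx = np.zeros(n, dtype=int)
    tgt_dwell = np.full(n, np.nan)
    award_rows: list[int] = []

    if spec.target_course is not None:
        course = list(spec.target_course)
        p = np.zeros(2)
        k_t = 0
        target = np.array([course[0][0], 0.0])
        dwell_req = float(course[0][1])
        if not (cfg.dwell_range[0] <= dwell_req <= cfg.dwell_range[1]):
            raise ValueError("course dwell outside the dwell range")
        accrued = 0.0
        for i in range(n):
            if k_t < len(course):
                d = target - p
                dist = float(np.linalg.norm(d))
                if dist > 1e-12:
                    mag = spec.speed * min(1.0, dist / cfg.proximity_radius)
                    v = (mag / dist) * d
                else:
                    v = np.zeros(2)
            else:
                v = np.zeros(2)
            pos[i] = p
            vel[i] = v
            if k_t < len(course):
                tgt_x[i], tgt_y[i] = target
                tgt_idx[i] = k_t + 1
                tgt_dwell[i] = dwell_req
                if float(np.linalg.norm(p - target)) <= cfg.proximity_radius:
                    accrued += dt
                else:
                    accrued = 0.0
                if accrued >= dwell_req:
                    award_rows.append(i)
                    k_t += 1
                    accrued = 0.0
                    if k_t < len(course):
                        target = p + np.array([course[k_t][0], 0.0])
                        dwell_req = float(course[k_t][1])
            p = p + v * dt
    else:
        # constant command toward a far target on +x
        far = 1000.0
        err = _per_step_err(spec, len(spec.footsteps or []))
        bsorted = sorted(boundaries)
        seg = 0
        p = np.zeros(2)
        sign = 1.0
        tgt = np.array([far, 0.0])
        for i in range(n):
            e = err[min(seg, len(err) - 1)] if len(err) else np.zeros(2)
            fluct = np.array([sign * spec.v_fluct, 0.0])
            sign = -sign
            # commanded vector via the same field law the scorer applies, so
            # the per-row deviation is exactly err + fluct
            d = tgt - p
            v_cmd = spec.speed * d / np.linalg.norm(d)
            v = v_cmd + e + fluct
            pos[i] = p
            vel[i] = v
            tgt_x[i], tgt_y[i] = far, 0.0
            tgt_idx[i] = 1
            tgt_dwell[i] = cfg.dwell_range[0]
            if i in boundaries:
                seg += 1
            p = p + v * dt

    frame = pd.DataFrame({"time": np.arange(n) * dt})
    for c in Q_COLUMNS + QDOT_COLUMNS:
        frame[c] = 0.0
    frame["pelvis_x"] = pos[:, 0]
    frame["pelvis_y"] = 0.95  # standing height placeholder, above any fall
    frame["vx"] = vel[:, 0]
    frame["gp_y"] = pos[:, 1]
    frame["v_gp_x"] = vel[:, 0]
    frame["v_gp_y"] = vel[:, 1]
    frame["contact_r"] = contact[:, 0]
    frame["contact_l"] = contact[:, 1]
    frame["alive"] = 1
    for c, a in zip(ACT_COLUMNS, acts):
        frame[c] = a
    frame["target_x"] = tgt_x
    frame["target_y"] = tgt_y
    frame["target_index"] = tgt_idx
    frame["required_dwell"] = tgt_dwell
    frame = frame[list(COLUMNS)]

    expected = _closed_form_expected(spec, n, boundaries, award_rows,
                                     effort_rate)
    seed_val = int(rng.integers(0, 2**31 - 1))
    return TrajectoryLog(frame=frame, seed=seed_val,
                         config_hash="fixture"), expected


def _closed_form_expected(
    spec: FixtureSpec, n: int, boundaries: set[int], award_rows: list[int],
    effort_rate: float,
) -> EpisodeResult:
    """Literal transcription of the reward sum over analytic segments."""
    cfg = spec.config
    dt = cfg.dt
    R_alive = n * cfg.b_alive

    # footstep segmentation: scheduled boundaries, then forced closures in
    # any stretch longer than the forced-closure horizon, trailing partial
    segments: list[int] = []       # rows per closed footstep
    last = -1
    for b in sorted(boundaries):
        segments.append(b - last)
        last = b
    trailing = n - 1 - last
    forced_rows = int(round(cfg.forced_closure / dt)) + 1
    while trailing >= forced_rows:
        segments.append(forced_rows)
        trailing -= forced_rows
    if trailing > 0 and cfg.score_trailing_partial:
        segments.append(trailing)

    err = _per_step_err(spec, len(spec.footsteps or []))
    records = []
    R_step = 0.0
    start = 0
    for j, rows in enumerate(segments):
        b_s = rows * dt
        if spec.target_course is not None or not len(err):
            c_v = 0.0
        else:
            e = err[min(j, len(err) - 1)]
            integral = e * rows * dt
            # alternating +/- fluctuation: cancels exactly over even row
            # counts; odd counts leave one +/-A dt residue whose sign is the
            # parity of the segment's first row
            if rows % 2 == 1 and spec.v_fluct:
                s = 1.0 if start % 2 == 0 else -1.0
                integral = integral + np.array([s * spec.v_fluct * dt, 0.0])
            c_v = float(np.linalg.norm(integral))
        start += rows
        c_e = effort_rate * rows * dt
        r = cfg.w_s * b_s - cfg.w_v * c_v - cfg.w_e * c_e
        records.append(FootstepRecord(b_s, c_v, c_e, r))
        R_step += r

    R_target = cfg.b_target * len(award_rows)
    return total_reward(R_alive, R_step, R_target, footsteps=records,
                        n_steps=n, targets_reached=len(award_rows))


# --------------------------------------------------------------------------
# Canonical fixtures and reports
# --------------------------------------------------------------------------

def max_reward_fixture(rng: np.random.Generator | int = 0
                       ) -> tuple[TrajectoryLog, EpisodeResult]:
    """Full-length, zero-cost, continuously stepping episode reaching and
    holding both targets: the hypothetical maximum J = 1500."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    dwells = rng.uniform(2.0, 4.0, size=2).round(2)
    spec = FixtureSpec(
        n_steps=2500,
        footsteps=[0.5] * 50,
        target_course=[(4.0, float(dwells[0])), (5.0, float(dwells[1]))],
    )
    return generate_fixture(spec, rng)


def report_text(result: EpisodeResult) -> str:
    """Human-readable scoring report with the exact decomposition."""
    lines = [
        "episode score report",
        f"  J        = {result.J:.9g}",
        f"  R_alive  = {result.R_alive:.9g}",
        f"  R_step   = {result.R_step:.9g}",
        f"  R_target = {result.R_target:.9g}",
        f"  steps simulated: {result.n_steps}, "
        f"targets reached: {result.targets_reached}",
        "  footsteps (b_s [s], c_v [m], c_e [a^2 s], reward):",
    ]
    for i, f in enumerate(result.footsteps, 1):
        lines.append(f"    {i:3d}  {f.duration:8.4f}  {f.velocity_cost:10.6f}"
                     f"  {f.effort_cost:10.6f}  {f.reward:10.6f}")
    return "\n".join(lines) + "\n"
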