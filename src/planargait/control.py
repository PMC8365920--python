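"""Non-learned baseline controllers for the planar walking environment.

Two baselines demonstrate the environment end to end without any RL:

* :func:`stand_policy` — constant low-level co-activation holding quiet
  standing.
* :func:`reflex_policy` — a reflex-style lower-layer controller: each leg
  runs a stance/swing finite-state machine keyed on its ground-reaction
  force, and muscle excitations are clamped sums of constant offsets and
  simple feedback terms (positive force feedback on the extensors during
  stance, trunk-pitch balance feedback at the hip, length feedback driving
  swing flexion). The feedback laws read only observation entries — the
  controller has no access to hidden simulator state.

:func:`search_params` tunes the reflex gain vector with a seeded
(mu, lambda) evolution strategy (rank-based selection, geometric step-size
decay) against any user objective, e.g. episode return or footstep count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .env import ACTION_DIM, MUSCLES_PER_LEG, Observation, PLANAR_MUSCLES

# (name, lower, upper, default) of the reflex parameter vector; gains are
# shared between the two legs.
PARAM_SPEC: tuple[tuple[str, float, float, float], ...] = (
    ("contact_thresh", 0.02, 0.30, 0.10),   # normalized GRF_y stance gate
    ("pitch_setpoint", -0.20, 0.20, 0.04),  # rad forward trunk lean target
    # stance
    ("sol_offset", 0.0, 0.4, 0.05),
    ("sol_gain", 0.0, 3.0, 1.1),            # + force feedback F_SOL
    ("gas_offset", 0.0, 0.4, 0.03),
    ("gas_gain", 0.0, 3.0, 0.8),
    ("vas_offset", 0.0, 0.6, 0.12),
    ("vas_gain", 0.0, 3.0, 0.7),
    ("glu_offset", 0.0, 0.6, 0.08),
    ("glu_pitch_gain", 0.0, 4.0, 1.2),      # trunk balance: pitch error
    ("glu_dpitch_gain", 0.0, 2.0, 0.4),     # trunk balance: pitch rate
    ("ham_pitch_gain", 0.0, 4.0, 0.8),      # contact-gated HAM share
    ("hfl_pitch_gain", 0.0, 4.0, 1.0),      # backward-lean counter (stance)
    ("ta_offset", 0.0, 0.5, 0.10),
    ("ta_sol_gain", 0.0, 3.0, 0.9),         # SOL force inhibits TA
    # swing
    ("hfl_offset_sw", 0.0, 1.0, 0.45),
    ("hfl_length_gain", 0.0, 4.0, 0.6),     # HAM stretch drives HFL
    ("ham_sw_gain", 0.0, 4.0, 0.4),         # leg retraction, late swing
    ("glu_offset_sw", 0.0, 0.6, 0.05),
    ("bfsh_offset_sw", 0.0, 1.0, 0.25),     # early-swing knee flexion
    ("ta_offset_sw", 0.0, 1.0, 0.45),
    ("swing_time_knee", 0.05, 0.60, 0.25),  # s: BFSH on before, off after
    ("init_swing_time", 0.0, 0.5, 0.20),    # s: left leg starts in swing
)

PARAM_NAMES = tuple(s[0] for s in PARAM_SPEC)
PARAM_BOUNDS = np.array([[s[1], s[2]] for s in PARAM_SPEC])
PARAM_DEFAULTS = np.array([s[3] for s in PARAM_SPEC])


@dataclass
class ReflexParams:
    """Flat, bounded parameter vector of the reflex controller."""

    values: np.ndarray = field(default_factory=lambda: PARAM_DEFAULTS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(PARAM_SPEC),):
            raise ValueError(f"expected {len(PARAM_SPEC)} parameters")
        lo, hi = PARAM_BOUNDS[:, 0], PARAM_BOUNDS[:, 1]
        if np.any(self.values < lo - 1e-12) or np.any(self.values > hi + 1e-12):
            raise ValueError("reflex parameters outside declared bounds")

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"schema": "planargait-reflex-v1",
                        "params": self.as_dict()}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReflexParams":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != "planargait-reflex-v1":
            raise ValueError("unrecognized reflex parameter file")
        return cls(np.array([doc["params"][n] for n in PARAM_NAMES]))


def shipped_reflex_params() -> ReflexParams:
    """The tuned walking parameter set shipped with the package.

    Produced by this repository's own evolution-strategy run (see
    examples/tune_reflex_gait.py); it sustains alternating stepping in
    planar-18 mode. It is a stability baseline, not a human-likeness claim.
    """
    from importlib import resources

    ref = resources.files("planargait").joinpath("data/reflex_walker.json")
    doc = json.loads(ref.read_text())
    return ReflexParams(np.array([doc["params"][n] for n in PARAM_NAMES]))


@dataclass
class ReflexState:
    """Controller memory: per-leg FSM phase and time in phase."""

    stance: np.ndarray = field(
        default_factory=lambda: np.array([True, True]))
    phase_time: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t: float = 0.0


class _ObsView:
    """Named access into the documented body-observation layouts."""

    def __init__(self, obs: Observation, mode: str):
        b = obs.body
        self.mode = mode
        if mode == "compat-22":
            self.pitch, self.pitch_rate = b[1], b[6]
            self.per_leg, self.leg0 = 44, 9
            self.grf_y = (b[9 + 1], b[9 + 44 + 1])
            self.n_mus, self.mus0 = 11, 11
            self.ang0, self.rate0 = 4, 8   # skip the zero abduction slots
        elif mode == "planar-18":
            self.pitch, self.pitch_rate = b[1], b[4]
            self.per_leg, self.leg0 = 38, 5
            self.grf_y = (b[5 + 1], b[5 + 38 + 1])
            self.n_mus, self.mus0 = 9, 11
            self.ang0, self.rate0 = 5, 8
        else:
            raise ValueError(f"unknown mode {mode!r}")
        # pitch is the CCW trunk angle: forward lean is negative pitch
        self.forward_lean = -self.pitch
        self.forward_lean_rate = -self.pitch_rate
        self._b = b
        names = MUSCLES_PER_LEG if mode == "compat-22" else PLANAR_MUSCLES
        self._midx = {n: i for i, n in enumerate(names)}

    def muscle(self, leg: int, name: str) -> tuple[float, float, float]:
        """(normalized force, normalized length, normalized velocity)."""
        k = self.leg0 + leg * self.per_leg + self.mus0 + 3 * self._midx[name]
        return self._b[k], self._b[k + 1], self._b[k + 2]

    def angles(self, leg: int) -> np.ndarray:
        k = self.leg0 + leg * self.per_leg + self.ang0
        return self._b[k:k + 3]

    def rates(self, leg: int) -> np.ndarray:
        k = self.leg0 + leg * self.per_leg + self.rate0
        return self._b[k:k + 3]


def stand_policy(obs: Observation, mode: str = "compat-22",
                 level: float = 0.07) -> np.ndarray:
    """Constant low co-activation that holds quiet standing.

    Extensors (VAS, SOL, GLU) get the base level plus a small trunk-pitch
    correction so the pose is statically robust; everything else stays
    nearly silent. Deterministic function of the observation.
    """
    v = _ObsView(obs, mode)
    names = MUSCLES_PER_LEG if mode == "compat-22" else PLANAR_MUSCLES
    act = {m: 0.01 for m in names}
    lean = v.forward_lean + 0.82 * v.forward_lean_rate
    # ankle strategy: forward sway dorsiflexes the ankles -> plantarflexors
    sway = 0.5 * (v.angles(0)[2] + v.angles(1)[2])
    act["VAS"] = level
    act["GLU"] = 0.104 + np.clip(3.0 * lean, 0.0, 0.6)
    act["HFL"] = 0.110 + np.clip(-3.0 * lean, 0.0, 0.6)
    act["HAM"] = np.clip(1.5 * lean, 0.0, 0.3)
    act["SOL"] = 0.006 + np.clip(8.1 * sway, 0.0, 0.85)
    act["TA"] = 0.066 + np.clip(-8.1 * sway, 0.0, 0.85)
    per_leg = [act[m] for m in names]
    return np.clip(np.array(per_leg * 2, float), 0.0, 1.0)


def reflex_policy(
    obs: Observation,
    params: ReflexParams,
    state: ReflexState | None = None,
    mode: str = "planar-18",
    dt: float = 0.01,
) -> tuple[np.ndarray, ReflexState]:
    """Reflex-style excitations from the current observation.

    Pure function of (observation, params, controller state): returns the
    action and the updated state. Per-leg FSM: a leg is in *stance* while
    its normalized vertical GRF exceeds ``contact_thresh`` and in *swing*
    otherwise.
    """
    p = params
    v = _ObsView(obs, mode)
    st = state or ReflexState()
    new_stance = np.array([v.grf_y[0] > p["contact_thresh"],
                           v.grf_y[1] > p["contact_thresh"]])
    # gait initiation: hold the left leg in swing for a short lead-in so the
    # symmetric standing start breaks into alternating stepping
    if st.t < p["init_swing_time"]:
        new_stance[1] = False
    phase_time = np.where(new_stance == st.stance,
                          st.phase_time + dt, 0.0)
    # forward trunk lean error relative to the commanded lean setpoint
    lean = (v.forward_lean - p["pitch_setpoint"]) \
        + 0.25 * v.forward_lean_rate

    names = MUSCLES_PER_LEG if mode == "compat-22" else PLANAR_MUSCLES
    action = np.zeros(ACTION_DIM[mode])
    n = len(names)
    for leg in range(2):
        e = {m: 0.01 for m in names}
        f_sol = v.muscle(leg, "SOL")[0]
        f_gas = v.muscle(leg, "GAS")[0]
        f_vas = v.muscle(leg, "VAS")[0]
        l_ham = v.muscle(leg, "HAM")[1]
        if new_stance[leg]:
            e["SOL"] = p["sol_offset"] + p["sol_gain"] * f_sol
            e["GAS"] = p["gas_offset"] + p["gas_gain"] * f_gas
            e["VAS"] = p["vas_offset"] + p["vas_gain"] * f_vas
            e["GLU"] = (p["glu_offset"]
                        + max(0.0, p["glu_pitch_gain"] * lean
                              + p["glu_dpitch_gain"] * v.forward_lean_rate))
            e["HAM"] = max(0.0, p["ham_pitch_gain"] * lean)
            e["HFL"] = 0.01 + max(0.0, -p["hfl_pitch_gain"] * lean)
            e["TA"] = max(
                0.01, p["ta_offset"] - p["ta_sol_gain"] * f_sol)
        else:
            t = phase_time[leg]
            e["HFL"] = (p["hfl_offset_sw"]
                        + p["hfl_length_gain"] * max(0.0, l_ham - 1.0))
            e["HAM"] = p["ham_sw_gain"] * max(0.0, l_ham - 1.0)
            e["GLU"] = p["glu_offset_sw"]
            e["BFSH"] = (p["bfsh_offset_sw"]
                         if t < p["swing_time_knee"] else 0.01)
            e["TA"] = p["ta_offset_sw"]
        action[leg * n:(leg + 1) * n] = [e[m] for m in names]

    new = ReflexState(stance=new_stance, phase_time=phase_time,
                      t=st.t + dt)
    return np.clip(action, 0.0, 1.0), new


def search_params(
    objective,
    bounds: np.ndarray = PARAM_BOUNDS,
    budget: int = 400,
    rng: np.random.Generator | int = 0,
    population: int = 16,
    x0: np.ndarray | None = None,
    sigma0: float = 0.25,
    sigma_decay: float = 0.95,
) -> tuple[np.ndarray, dict]:
    """Maximize ``objective(x)`` with a seeded (mu, lambda) ES.

    Rank-based: each generation draws ``population`` candidates around the
    current mean, keeps the top quarter, and recenters; the per-coordinate
    step size decays geometrically. Candidates are clipped to ``bounds``.
    Non-finite objective values are treated as worst fitness. Returns the
    best-ever vector and a log with the monotone best-so-far trace.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    bounds = np.asarray(bounds, float)
    if budget < population or population < 4:
        raise ValueError("budget must cover at least one population of >= 4")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    mean = (np.clip(np.asarray(x0, float), lo, hi) if x0 is not None
            else 0.5 * (lo + hi))
    sigma = sigma0 * span
    mu = max(2, population // 4)

    best_x, best_f = mean.copy(), -np.inf
    trace = []
    evals = 0
    while evals + population <= budget:
        cand = rng.normal(mean, sigma, size=(population, len(lo)))
        cand = np.clip(cand, lo, hi)
        fit = np.empty(population)
        for i in range(population):
            f = objective(cand[i])
            fit[i] = f if np.isfinite(f) else -np.inf
        evals += population
        order = np.argsort(fit)[::-1]
        if fit[order[0]] > best_f:
            best_f = float(fit[order[0]])
            best_x = cand[order[0]].copy()
        mean = cand[order[:mu]].mean(axis=0)
        sigma = sigma * sigma_decay
        trace.append(best_f)
    return best_x, {"best_f": best_f, "trace": trace, "evals": evals}
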