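"""Planar articulated rigid-body dynamics of the 7-segment walker.

The skeleton is a sagittal-plane kinematic tree: a head-arms-trunk-pelvis
(HAT) segment floating in the plane, with two legs of thigh, shank, and foot.
Generalized coordinates (9):

    q = [x_pelvis, y_pelvis, pitch, hip_R, knee_R, ankle_R,
                                    hip_L, knee_L, ankle_L]

Angle conventions: every angle is a counter-clockwise rotation in the x-up
plane (+x forward, +y up). Trunk pitch is the CCW trunk angle, so a
*forward* lean is negative pitch; hip flexion (thigh forward) +; knee
flexion - (0 = straight); ankle dorsiflexion + (0 = foot flat). Both hip
joints coincide with the pelvis origin (no pelvis width in the sagittal
plane).

Dynamics are assembled from body Jacobians. For a planar kinematic tree,
the velocity of any material point p is

    v_p = (x', y') + sum_a  q'_a  R90 (p - c_a)

over the angle dofs a in the chain above p, where c_a is the joint center of
dof a and R90 the +90 deg rotation. The columns R90 (p - c_a) are the point
Jacobian; the mass matrix is M = sum_b J_b^T diag(m, m, I) J_b and the
velocity-product (bias) acceleration of a com follows from differentiating
the same expression. Ground contact uses a Hunt-Crossley style nonlinear
spring-damper on three spheres per foot with smoothed Coulomb friction.

Time stepping is semi-implicit Euler (velocity first), sub-stepped below the
0.01 s control step for stability with stiff contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NQ = 9                      # generalized coordinates
ANGLE_DOFS = range(2, 9)    # pitch + 6 leg joints
JOINT_NAMES = ("hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")
_R90 = np.array([[0.0, -1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class ContactParams:
    stiffness: float = 1.2e6
    exponent: float = 1.5
    damping: float = 1.2
    friction_mu: float = 0.8
    friction_vel: float = 0.05
    # sphere offsets in the foot frame (x forward from ankle, y up) + radius
    spheres: tuple[tuple[float, float, float], ...] = (
        (-0.05, -0.05, 0.025),
        (0.08, -0.05, 0.025),
        (0.20, -0.05, 0.025),
    )


@dataclass(frozen=True)
class SkeletonParams:
    """Inertial and geometric parameters of the 7-segment planar walker."""

    masses: dict[str, float]        # trunk, thigh, shank, foot
    lengths: dict[str, float]
    com_offsets: dict[str, float]
    inertias: dict[str, float]
    joint_limits: dict[str, tuple[float, float]]  # hip, knee, ankle
    joint_limit_stiffness: float = 300.0
    joint_limit_damping: float = 3.0
    joint_damping: float = 0.3
    gravity: float = 9.81
    contact: ContactParams = field(default_factory=ContactParams)

    def __post_init__(self) -> None:
        for group in (self.masses, self.lengths, self.com_offsets, self.inertias):
            if set(group) != {"trunk", "thigh", "shank", "foot"}:
                raise ValueError("expect trunk/thigh/shank/foot parameters")
            if any(v <= 0 for v in group.values()):
                raise ValueError("masses, lengths, inertias must be positive")
        if len(self.contact.spheres) != 3:
            raise ValueError("exactly 3 contact spheres per foot")

    @property
    def total_mass(self) -> float:
        m = self.masses
        return m["trunk"] + 2 * (m["thigh"] + m["shank"] + m["foot"])

    @property
    def standing_pelvis_height(self) -> float:
        sx, sy, r = self.contact.spheres[0]
        return self.lengths["thigh"] + self.lengths["shank"] + (-sy) + r

    @classmethod
    def from_config(cls, cfg: dict) -> "SkeletonParams":
        seg = cfg["segments"]
        con = cfg["contact"]
        return cls(
            masses={k: float(v["mass"]) for k, v in seg.items()},
            lengths={k: float(v["length"]) for k, v in seg.items()},
            com_offsets={k: float(v["com_offset"]) for k, v in seg.items()},
            inertias={k: float(v["inertia"]) for k, v in seg.items()},
            joint_limits={k: tuple(v["limits"]) for k, v in cfg["joints"].items()},
            joint_limit_stiffness=float(cfg["joint_limit_stiffness"]),
            joint_limit_damping=float(cfg["joint_limit_damping"]),
            joint_damping=float(cfg["joint_damping"]),
            gravity=float(cfg["gravity"]),
            contact=ContactParams(
                stiffness=float(con["stiffness"]),
                exponent=float(con["exponent"]),
                damping=float(con["damping"]),
                friction_mu=float(con["friction_mu"]),
                friction_vel=float(con["friction_vel"]),
                spheres=tuple(
                    (float(s["x"]), float(s["y"]), float(s["r"]))
                    for s in con["spheres"]
                ),
            ),
        )


@dataclass
class BodyState:
    """Minimal-coordinate state of the walker plus contact bookkeeping."""

    q: np.ndarray                  # (9,)
    qdot: np.ndarray               # (9,)
    time: float = 0.0
    v_pel: np.ndarray = field(default_factory=lambda: np.zeros(2))
    contact_flags: np.ndarray = field(default_factory=lambda: np.zeros(6, bool))
    contact_forces: np.ndarray = field(default_factory=lambda: np.zeros((6, 2)))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (NQ,) or self.qdot.shape != (NQ,):
            raise ValueError(f"q and qdot must have length {NQ}")

    def copy(self) -> "BodyState":
        return BodyState(
            q=self.q.copy(), qdot=self.qdot.copy(), time=self.time,
            v_pel=self.v_pel.copy(), contact_flags=self.contact_flags.copy(),
            contact_forces=self.contact_forces.copy(),
        )

    @property
    def pelvis_height(self) -> float:
        return float(self.q[1])


def standing_state(params: SkeletonParams) -> BodyState:
    """Static standing pose: straight legs, feet flat, zero velocity."""
    q = np.zeros(NQ)
    q[1] = params.standing_pelvis_height
    return BodyState(q=q, qdot=np.zeros(NQ))


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

# incidence: which angle dofs (columns, q-index 2..8) move each body (rows:
# trunk, thigh_R, shank_R, foot_R, thigh_L, shank_L, foot_L)
_INCIDENCE = np.array(
    [
        [1, 0, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0],
        [1, 1, 1, 1, 0, 0, 0],
        [1, 0, 0, 0, 1, 0, 0],
        [1, 0, 0, 0, 1, 1, 0],
        [1, 0, 0, 0, 1, 1, 1],
    ],
    dtype=float,
)
_BODY_SEG = ("trunk", "thigh", "shank", "foot", "thigh", "shank", "foot")


class Kinematics:
    """Forward-kinematics snapshot of the walker at (q, qdot)."""

    def __init__(self, params: SkeletonParams, q: np.ndarray, qdot: np.ndarray):
        p = params
        x, y = q[0], q[1]
        vx, vy = qdot[0], qdot[1]
        pitch = q[2]
        pelvis = np.array([x, y])
        v_pelvis = np.array([vx, vy])

        # absolute segment angles: legs measured from straight-down, foot
        # direction from +x (flat)
        th_r = pitch + q[3]
        sh_r = th_r + q[4]
        ft_r = sh_r + q[5]
        th_l = pitch + q[6]
        sh_l = th_l + q[7]
        ft_l = sh_l + q[8]

        def down(a):
            return np.array([np.sin(a), -np.cos(a)])

        def fwd(a):
            return np.array([np.cos(a), np.sin(a)])

        L, C = p.lengths, p.com_offsets
        knee_r = pelvis + L["thigh"] * down(th_r)
        ankle_r = knee_r + L["shank"] * down(sh_r)
        knee_l = pelvis + L["thigh"] * down(th_l)
        ankle_l = knee_l + L["shank"] * down(sh_l)

        # trunk com above pelvis along the trunk axis (CCW pitch)
        up = np.array([-np.sin(pitch), np.cos(pitch)])
        coms = np.array(
            [
                pelvis + C["trunk"] * up,
                pelvis + C["thigh"] * down(th_r),
                knee_r + C["shank"] * down(sh_r),
                ankle_r + C["foot"] * fwd(ft_r),
                pelvis + C["thigh"] * down(th_l),
                knee_l + C["shank"] * down(sh_l),
                ankle_l + C["foot"] * fwd(ft_l),
            ]
        )
        # joint centers of the 7 angle dofs (pitch, hipR, kneeR, ankleR, ...)
        cent = np.array([pelvis, pelvis, knee_r, ankle_r, pelvis, knee_l, ankle_l])

        self.params = p
        self.q = q
        self.qdot = qdot
        self.pelvis = pelvis
        self.coms = coms                     # (7,2)
        self.cent = cent                     # (7,2)
        self.incidence = _INCIDENCE
        self.joints = {
            "pelvis": pelvis, "knee_r": knee_r, "ankle_r": ankle_r,
            "knee_l": knee_l, "ankle_l": ankle_l,
        }
        self.seg_angles = np.array([pitch, th_r, sh_r, ft_r, th_l, sh_l, ft_l])

        # contact sphere positions: spheres live on the foot bodies (3, 6)
        self.sphere_pos = np.zeros((6, 2))
        self.sphere_body = np.array([3, 3, 3, 6, 6, 6])
        for i, (ankle, ang) in enumerate(((ankle_r, ft_r), (ankle_l, ft_l))):
            f, n = fwd(ang), _R90 @ fwd(ang)
            for j, (sx, sy, r) in enumerate(p.contact.spheres):
                self.sphere_pos[3 * i + j] = ankle + sx * f + sy * n

        # velocities via the Jacobian identity (point and centers)
        adot = qdot[2:9]
        self.v_cent = self._point_vel(cent, _INCIDENCE_CENTERS, adot, v_pelvis)
        self.v_coms = self._point_vel(coms, _INCIDENCE, adot, v_pelvis)
        sph_inc = _INCIDENCE[self.sphere_body]
        self.v_spheres = self._point_vel(self.sphere_pos, sph_inc, adot, v_pelvis)

    def _point_vel(self, pts, inc, adot, v_base):
        # v = v_base + sum_a adot_a * R90 (p - c_a) over incident dofs
        d = pts[:, None, :] - self.cent[None, :, :]          # (n,7,2)
        rot = np.stack([-d[..., 1], d[..., 0]], axis=-1)      # R90 applied
        return v_base + np.einsum("a,naj,na->nj", adot, rot, inc)

    def point_jacobian(self, pt: np.ndarray, body: int) -> np.ndarray:
        """2 x 9 Jacobian of a material point attached to ``body``."""
        J = np.zeros((2, NQ))
        J[0, 0] = J[1, 1] = 1.0
        inc = _INCIDENCE[body]
        d = pt[None, :] - self.cent                           # (7,2)
        J[0, 2:] = -d[:, 1] * inc
        J[1, 2:] = d[:, 0] * inc
        return J

    def sphere_radii(self) -> np.ndarray:
        r = np.array([s[2] for s in self.params.contact.spheres])
        return np.concatenate([r, r])


# incidence of the 7 joint-center points on the angle dofs: the center of dof
# a moves with all dofs strictly above it in the tree
_INCIDENCE_CENTERS = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],   # pelvis (pitch center)
        [0, 0, 0, 0, 0, 0, 0],   # hip R center = pelvis
        [1, 1, 0, 0, 0, 0, 0],   # knee R
        [1, 1, 1, 0, 0, 0, 0],   # ankle R
        [0, 0, 0, 0, 0, 0, 0],   # hip L center = pelvis
        [1, 0, 0, 0, 1, 0, 0],   # knee L
        [1, 0, 0, 0, 1, 1, 0],   # ankle L
    ],
    dtype=float,
)


# --------------------------------------------------------------------------
# Generic planar assembly (shared with the serial test chains)
# --------------------------------------------------------------------------

def assemble_mass_matrix(
    masses: np.ndarray, inertias: np.ndarray, coms: np.ndarray,
    cent: np.ndarray, incidence: np.ndarray, nq: int,
) -> np.ndarray:
    """M = sum_b J_b^T diag(m, m, I) J_b for planar tree bodies."""
    nb = len(masses)
    n_ang = incidence.shape[1]
    J = np.zeros((nb, 3, nq))
    if nq > n_ang:  # leading translation dofs (floating base)
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
    d = coms[:, None, :] - cent[None, :, :]
    J[:, 0, nq - n_ang:] = -d[..., 1] * incidence
    J[:, 1, nq - n_ang:] = d[..., 0] * incidence
    J[:, 2, nq - n_ang:] = incidence
    w = np.stack([masses, masses, inertias], axis=1)          # (nb,3)
    return np.einsum("bi,bij,bik->jk", w, J, J)


def bias_forces(
    masses: np.ndarray, coms: np.ndarray, v_coms: np.ndarray,
    cent: np.ndarray, v_cent: np.ndarray, incidence: np.ndarray,
    adot: np.ndarray, nq: int,
) -> np.ndarray:
    """Generalized velocity-product forces: -sum_b J_b^T m_b a_bias(b).

    a_bias(b) = sum_a adot_a R90 (v_com(b) - v_cent(a)) over incident dofs
    (the com acceleration at zero generalized acceleration).
    """
    nb = len(masses)
    n_ang = incidence.shape[1]
    dv = v_coms[:, None, :] - v_cent[None, :, :]
    rot = np.stack([-dv[..., 1], dv[..., 0]], axis=-1)
    a_bias = np.einsum("a,naj,na->nj", adot, rot, incidence)  # (nb,2)
    Q = np.zeros(nq)
    if nq > n_ang:
        Q[0] = -np.sum(masses * a_bias[:, 0])
        Q[1] = -np.sum(masses * a_bias[:, 1])
    d = coms[:, None, :] - cent[None, :, :]
    Jx = -d[..., 1] * incidence
    Jy = d[..., 0] * incidence
    Q[nq - n_ang:] = -(
        np.einsum("b,ba->a", masses * a_bias[:, 0], Jx)
        + np.einsum("b,ba->a", masses * a_bias[:, 1], Jy)
    )
    return Q


def solve_accelerations(M: np.ndarray, Q: np.ndarray,
                        free: np.ndarray | None = None) -> np.ndarray:
    """Solve M qddot = Q, optionally restricted to a free-dof mask."""
    if free is None:
        return np.linalg.solve(M, Q)
    idx = np.flatnonzero(free)
    qddot = np.zeros(len(Q))
    qddot[idx] = np.linalg.solve(M[np.ix_(idx, idx)], Q[idx])
    return qddot


# --------------------------------------------------------------------------
# Contact
# --------------------------------------------------------------------------

def contact_forces(
    sphere_pos: np.ndarray, sphere_vel: np.ndarray, radii: np.ndarray,
    params: ContactParams,
) -> np.ndarray:
    """Per-sphere ground forces (n, 2): nonlinear spring-damper + friction.

    Normal: F_n = k d^e (1 + c * ddot), clamped at zero (no adhesion), with
    penetration d and penetration rate ddot. Tangential: smoothed Coulomb,
    F_t = -mu F_n tanh(v_x / v_s), which opposes slip and saturates at mu F_n.
    """
    d = radii - sphere_pos[:, 1]
    pen = d > 0
    F = np.zeros_like(sphere_pos)
    if not np.any(pen):
        return F
    dd = np.clip(d[pen], 0, None)
    ddot = -sphere_vel[pen, 1]
    fn = params.stiffness * dd**params.exponent * (1.0 + params.damping * ddot)
    fn = np.clip(fn, 0.0, None)
    ft = -params.friction_mu * fn * np.tanh(
        sphere_vel[pen, 0] / params.friction_vel
    )
    F[pen, 0] = ft
    F[pen, 1] = fn
    return F


# --------------------------------------------------------------------------
# Muscle geometry (affine path model)
# --------------------------------------------------------------------------

class MusclePaths:
    """Affine MTU path model: constant moment arms, neutral-pose calibration.

    L_m(q) = L_m(0) - sum_j r_mj q_j  and  v_m = -sum_j r_mj qdot_j, where
    r_mj is the (constant) moment arm of muscle m at joint j and the neutral
    pose q = 0 is straight-leg standing. The joint torque contributed by a
    muscle with tension F is tau_j = r_mj F (virtual work). Biarticular
    muscles (HAM, RF, GAS) carry two nonzero arms.
    """

    def __init__(self, muscle_params: list, joint_index: dict[str, int],
                 neutral_lengths: np.ndarray, moment_arms: np.ndarray):
        self.muscle_params = muscle_params
        self.joint_index = joint_index
        self.neutral_lengths = np.asarray(neutral_lengths, float)
        self.moment_arms = np.asarray(moment_arms, float)  # (n_muscles, 9)

    @classmethod
    def from_config(cls, cfg: dict, muscle_params: list) -> "MusclePaths":
        jmap = {name: 3 + i for i, name in enumerate(JOINT_NAMES)}
        n = len(muscle_params)
        arms = np.zeros((n, NQ))
        neutral = np.zeros(n)
        for i, mp in enumerate(muscle_params):
            base, side = mp.name.rsplit("_", 1)
            mc = cfg["muscles"][base]
            neutral[i] = mp.l_opt + mp.l_slack
            for joint, r in mc.get("moment_arms", {}).items():
                arms[i, jmap[f"{joint}_{side.lower()}"]] = float(r)
        return cls(muscle_params, jmap, neutral, arms)

    def muscle_geometry(
        self, q: np.ndarray, qdot: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mtu_lengths, mtu_velocities, moment_arms) at configuration q."""
        q = np.asarray(q, float)
        lengths = self.neutral_lengths - self.moment_arms @ q
        if qdot is None:
            vels = np.zeros_like(lengths)
        else:
            vels = -self.moment_arms @ np.asarray(qdot, float)
        return lengths, vels, self.moment_arms

    def joint_moments(self, forces: np.ndarray) -> np.ndarray:
        """Generalized torques (9,) from muscle tensions (n,)."""
        return self.moment_arms.T @ np.asarray(forces, float)


# --------------------------------------------------------------------------
# Walker dynamics
# --------------------------------------------------------------------------

class WalkerDynamics:
    """Forward dynamics and time stepping of the planar walker.

    Owns the skeleton parameters and the muscle path model; muscle params and
    states are passed through so the env module can manage them.
    """

    def __init__(self, params: SkeletonParams, paths: MusclePaths,
                 muscle_params: list, elastic_tendon: bool = False):
        self.params = params
        self.paths = paths
        self.muscle_params = muscle_params
        self.elastic_tendon = elastic_tendon
        self._masses = np.array([params.masses[s] for s in _BODY_SEG])
        self._inertias = np.array([params.inertias[s] for s in _BODY_SEG])
        # stacked muscle parameter arrays for the vectorized stepping path
        mp = muscle_params
        self._f_max = np.array([m.f_max for m in mp])
        self._l_opt = np.array([m.l_opt for m in mp])
        self._l_slack = np.array([m.l_slack for m in mp])
        self._v_scale = np.array([m.v_max * m.l_opt for m in mp])
        self._tau_act = np.array([m.tau_act for m in mp])
        self._tau_deact = np.array([m.tau_deact for m in mp])
        self._fl_w = np.array([m.fl_width for m in mp])
        self._fv_k = np.array([m.fv_shape for m in mp])
        self._fv_n = np.array([m.fv_ecc_plateau for m in mp])
        self._pe_e0 = np.array([m.pe_engage for m in mp])
        self._pe_w = np.array([m.pe_stretch for m in mp])

    def _muscle_forces_vec(self, a, lengths, vels):
        """Vectorized Hill forces; mirrors muscle.mtu_force (rigid tendon)."""
        l_ce = lengths - self._l_slack
        degen = l_ce <= 0.0
        x = np.where(degen, 0.01, l_ce / self._l_opt)
        v = vels / self._v_scale
        xc = np.clip(x, 0.0, 10.0)  # avoid overflow in diverged states
        fl = np.exp(-(((xc - 1.0) / self._fl_w) ** 2) * 4.0 * np.log(2.0))
        con = np.clip((1.0 + v) / (1.0 - v / self._fv_k), 0.0, None)
        g = (1.0 + 1.0 / self._fv_k) / (self._fv_n - 1.0)
        ecc = self._fv_n - (self._fv_n - 1.0) / (1.0 + v * g)
        fv = np.where(v <= 0.0, con, ecc)
        s = np.clip((x - self._pe_e0) / self._pe_w, 0.0, None)
        fp = np.where(s <= 1.0, s**2, 1.0 + 2.0 * (s - 1.0))
        F = self._f_max * (a * fl * fv + fp)
        F = np.where(degen, 0.0, np.clip(F, 0.0, None))
        return F, x, degen

    # -- spec surface -----------------------------------------------------
    def muscle_geometry(self, q, qdot=None):
        return self.paths.muscle_geometry(q, qdot)

    def contact_forces(self, state: BodyState) -> np.ndarray:
        kin = Kinematics(self.params, state.q, state.qdot)
        return contact_forces(kin.sphere_pos, kin.v_spheres,
                              kin.sphere_radii(), self.params.contact)

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        kin = Kinematics(self.params, np.asarray(q, float), np.zeros(NQ))
        return assemble_mass_matrix(self._masses, self._inertias, kin.coms,
                                    kin.cent, kin.incidence, NQ)

    def forward_dynamics(
        self, state: BodyState, joint_moments: np.ndarray,
        external: list[tuple[np.ndarray, int, np.ndarray]] | None = None,
        gravity: float | None = None,
    ) -> np.ndarray:
        """qddot for given joint torques and external point forces.

        ``external`` is a list of (force_2d, body_index, world_point).
        """
        kin = Kinematics(self.params, state.q, state.qdot)
        return self._qddot(kin, state.qdot, np.asarray(joint_moments, float),
                           external or [], gravity)

    # -- internals --------------------------------------------------------
    def _qddot(self, kin, qdot, tau, external, gravity=None):
        g = self.params.gravity if gravity is None else gravity
        M = assemble_mass_matrix(self._masses, self._inertias, kin.coms,
                                 kin.cent, kin.incidence, NQ)
        if not np.all(np.isfinite(M)):
            raise FloatingPointError("non-finite mass matrix")
        Q = bias_forces(self._masses, kin.coms, kin.v_coms, kin.cent,
                        kin.v_cent, kin.incidence, qdot[2:], NQ)
        Q[1] -= g * self._masses.sum()
        # gravity torque on angle dofs: sum_b m_b g * d/dq (−y_com)
        d = kin.coms[:, None, :] - kin.cent[None, :, :]
        Jy = d[..., 0] * kin.incidence
        Q[2:] -= g * np.einsum("b,ba->a", self._masses, Jy)
        Q += tau
        for force, body, point in external:
            J = kin.point_jacobian(np.asarray(point, float), body)
            Q += J.T @ np.asarray(force, float)
        try:
            return np.linalg.solve(M, Q)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"singular mass matrix: {exc}") from exc

    def _passive_joint_torques(self, q, qdot):
        p = self.params
        tau = np.zeros(NQ)
        lim = [p.joint_limits[j.split("_")[0]] for j in JOINT_NAMES]
        for k, (lo, hi) in enumerate(lim):
            i = 3 + k
            tau[i] -= p.joint_damping * qdot[i]
            if q[i] > hi:
                tau[i] -= p.joint_limit_stiffness * (q[i] - hi)
                tau[i] -= p.joint_limit_damping * max(0.0, qdot[i])
            elif q[i] < lo:
                tau[i] -= p.joint_limit_stiffness * (q[i] - lo)
                tau[i] -= p.joint_limit_damping * min(0.0, qdot[i])
        return tau

    def integrate_step(
        self,
        state: BodyState,
        muscle_states: list,
        excitations: np.ndarray,
        dt: float = 0.01,
        substeps: int = 10,
    ) -> tuple[BodyState, list, dict]:
        """Advance the walker by one control step of ``dt`` seconds.

        Activation dynamics, muscle forces, contact, and skeleton dynamics
        are advanced together on ``substeps`` semi-implicit Euler substeps.
        Returns the new body state, new muscle states, and an info dict with
        clamp/degeneracy flags. Deterministic for identical inputs.
        """
        from . import muscle as mus

        if substeps < 1:
            raise ValueError("substeps must be >= 1")
        exc = np.asarray(excitations, float)
        if exc.shape != (len(self.muscle_params),):
            raise ValueError("excitation vector has wrong length")
        if not np.all(np.isfinite(exc)):
            bad = int(np.flatnonzero(~np.isfinite(exc))[0])
            raise ValueError(f"non-finite excitation at index {bad}")

        h = dt / substeps
        q = state.q.copy()
        qdot = state.qdot.copy()
        info = {"clamped": bool(np.any((exc < 0) | (exc > 1))),
                "degenerate": False}
        e = np.clip(exc, 0.0, 1.0)
        a = np.clip(np.array([s.activation for s in muscle_states]), 0, 1)

        if self.elastic_tendon:
            states = [s.copy() for s in muscle_states]
        l_norm = None
        forces = np.zeros(len(a))
        for _ in range(substeps):
            lengths, vels, _ = self.paths.muscle_geometry(q, qdot)
            tau_m = np.where(e > a, self._tau_act, self._tau_deact)
            a = e + (a - e) * np.exp(-h / tau_m)
            if self.elastic_tendon:
                for m, (mp, ms) in enumerate(zip(self.muscle_params, states)):
                    ms.activation = a[m]
                    f, s_new = mus.mtu_force(ms, lengths[m], vels[m], mp,
                                             elastic_tendon=True)
                    states[m] = s_new
                    forces[m] = f
                l_norm = np.array([s.l_ce_norm for s in states])
            else:
                forces, l_norm, degen = self._muscle_forces_vec(
                    a, lengths, vels)
                info["degenerate"] |= bool(np.any(degen))
            tau = self.paths.joint_moments(forces)
            tau += self._passive_joint_torques(q, qdot)

            kin = Kinematics(self.params, q, qdot)
            F = contact_forces(kin.sphere_pos, kin.v_spheres,
                               kin.sphere_radii(), self.params.contact)
            external = [
                (F[i], int(kin.sphere_body[i]), kin.sphere_pos[i])
                for i in range(6) if F[i, 1] > 0.0
            ]
            qddot = self._qddot(kin, qdot, tau, external)
            qdot = qdot + h * qddot
            q = q + h * qdot

        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qdot))):
            raise FloatingPointError(
                "non-finite state after integration step; the dynamics went "
                "unstable — consider more substeps")

        if not self.elastic_tendon:
            states = [
                mus.MuscleState(activation=float(a[m]),
                                l_ce_norm=float(l_norm[m]),
                                force=float(forces[m]))
                for m in range(len(a))
            ]
        kin = Kinematics(self.params, q, qdot)
        F = contact_forces(kin.sphere_pos, kin.v_spheres, kin.sphere_radii(),
                           self.params.contact)
        new = BodyState(
            q=q, qdot=qdot, time=state.time + dt,
            v_pel=np.array([qdot[0], 0.0]),
            contact_flags=F[:, 1] > 0.0,
            contact_forces=F,
        )
        return new, states, info


# --------------------------------------------------------------------------
# Serial chain (pendulum fixtures sharing the same assembly and stepping)
# --------------------------------------------------------------------------

class SerialChain:
    """n-link serial pendulum pinned at the origin.

    Uses the same mass-matrix / bias-force assembly as the walker; exists so
    the dynamics core can be validated against closed-form pendulum and
    energy-conservation oracles.
    """

    def __init__(self, masses, lengths, com_offsets, inertias, gravity=9.81):
        self.m = np.asarray(masses, float)
        self.l = np.asarray(lengths, float)
        self.c = np.asarray(com_offsets, float)
        self.inertia = np.asarray(inertias, float)
        self.g = gravity
        self.n = len(self.m)

    def _kin(self, q, qdot):
        # link k hangs below; absolute angle of link k = sum(q[:k+1]),
        # measured from straight down
        ang = np.cumsum(q)
        u = np.stack([np.sin(ang), -np.cos(ang)], axis=1)
        joints = np.zeros((self.n + 1, 2))
        for k in range(self.n):
            joints[k + 1] = joints[k] + self.l[k] * u[k]
        coms = joints[:-1] + self.c[:, None] * u
        inc = np.tril(np.ones((self.n, self.n)))
        cent = joints[:-1]
        # velocities by the same R90 identity
        adot = qdot
        d = coms[:, None, :] - cent[None, :, :]
        rot = np.stack([-d[..., 1], d[..., 0]], axis=-1)
        v_coms = np.einsum("a,naj,na->nj", adot, rot, inc)
        dc = cent[:, None, :] - cent[None, :, :]
        rotc = np.stack([-dc[..., 1], dc[..., 0]], axis=-1)
        inc_c = np.tril(np.ones((self.n, self.n)), k=-1)
        v_cent = np.einsum("a,naj,na->nj", adot, rotc, inc_c)
        return coms, v_coms, cent, v_cent, inc

    def accelerations(self, q, qdot):
        coms, v_coms, cent, v_cent, inc = self._kin(q, qdot)
        nq = self.n
        # no translation dofs: reuse assembly with nq = n angle dofs
        M = assemble_mass_matrix(self.m, self.inertia, coms, cent, inc, nq)
        Q = bias_forces(self.m, coms, v_coms, cent, v_cent, inc, qdot, nq)
        d = coms[:, None, :] - cent[None, :, :]
        Jy = d[..., 0] * inc
        Q -= self.g * np.einsum("b,ba->a", self.m, Jy)
        return solve_accelerations(M, Q)

    def step(self, q, qdot, h):
        """One semi-implicit Euler substep."""
        qdot = qdot + h * self.accelerations(q, qdot)
        return q + h * qdot, qdot

    def energy(self, q, qdot):
        coms, v_coms, _, _, inc = self._kin(q, qdot)
        omega = inc @ qdot
        ke = 0.5 * np.sum(self.m * np.sum(v_coms**2, axis=1)) \
            + 0.5 * np.sum(self.inertia * omega**2)
        pe = self.g * np.sum(self.m * coms[:, 1])
        return ke + pe
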