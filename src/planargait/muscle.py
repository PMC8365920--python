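"""Hill-type muscle-tendon units.

Each muscle-tendon unit (MTU) is modelled with a contractile element (CE)
whose active force scales with activation, a force-length curve and a
force-velocity curve, plus a parallel elastic element (PE) that engages as a
nonlinear spring above the optimal CE length. The series elastic element (SE,
tendon) is rigid by default: the CE length is the MTU path length minus the
tendon slack length. An elastic-tendon mode solving the CE/SE force
equilibrium per step is available but off by default.

Excitation (the neural command, in [0, 1]) drives activation through a
first-order ODE with separate activation and deactivation time constants;
activation is the low-pass state that scales active force.

The effort cost used by the locomotion task is the time integral of summed
squared activations, a standard proxy for muscle fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

# Canonical per-leg muscle order used everywhere in the package.
MUSCLES_PER_LEG = (
    "HAB", "HAD", "HFL", "GLU", "HAM", "RF", "VAS", "BFSH", "GAS", "SOL", "TA",
)
# Full names, for reports.
MUSCLE_LONG_NAMES = {
    "HAB": "hip abductor",
    "HAD": "hip adductor",
    "HFL": "hip flexor",
    "GLU": "glutei (hip extensor)",
    "HAM": "hamstring (biarticular hip extensor / knee flexor)",
    "RF": "rectus femoris (biarticular hip flexor / knee extensor)",
    "VAS": "vastii (knee extensor)",
    "BFSH": "biceps femoris short head (knee flexor)",
    "GAS": "gastrocnemius (biarticular knee flexor / ankle extensor)",
    "SOL": "soleus (ankle extensor)",
    "TA": "tibialis anterior (ankle flexor)",
}


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one Hill-type MTU.

    Attributes
    ----------
    name : str
        One of HAB/HAD/HFL/GLU/HAM/RF/VAS/BFSH/GAS/SOL/TA with a ``_R`` or
        ``_L`` side suffix.
    f_max : float
        Maximum isometric force (N).
    l_opt : float
        Optimal CE length (m); active force-length peaks here.
    v_max : float
        Maximum shortening velocity in optimal lengths per second (l_opt/s).
    l_slack : float
        Series-element slack length (m).
    tau_act, tau_deact : float
        Activation / deactivation time constants (s).
    fv_ecc_plateau : float
        Eccentric (lengthening) force plateau, dimensionless, >= 1.
    """

    name: str
    f_max: float
    l_opt: float
    v_max: float = 10.0
    l_slack: float = 0.2
    tau_act: float = 0.015
    tau_deact: float = 0.05
    fv_ecc_plateau: float = 1.5
    fl_width: float = 0.45        # Gaussian force-length width (dimensionless)
    fv_shape: float = 0.25        # concentric hyperbola curvature
    pe_engage: float = 1.0        # normalized CE length where PE engages
    pe_stretch: float = 0.5       # normalized stretch giving PE force = f_max

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValueError(f"{self.name}: f_max, l_opt, v_max must be positive")
        if not (0 < self.tau_act <= self.tau_deact):
            raise ValueError(f"{self.name}: need 0 < tau_act <= tau_deact")
        if self.fv_ecc_plateau < 1.0:
            raise ValueError(f"{self.name}: eccentric plateau must be >= 1")


@dataclass
class MuscleState:
    """Dynamic state of one MTU: activation, normalized CE length, force."""

    activation: float = 0.0
    l_ce_norm: float = 1.0
    force: float = 0.0
    degenerate: bool = False  # set when geometry yields non-positive CE length

    def copy(self) -> "MuscleState":
        return replace(self)


def activation_step(
    excitation: float, activation: float, dt: float, params: MuscleParams
) -> tuple[float, bool]:
    """Advance activation toward excitation by one first-order ODE step.

    da/dt = (e - a) / tau, with tau = tau_act when e > a and tau_deact
    otherwise. Integrated exactly over dt (exponential update), so the result
    is unconditionally stable and monotone for any step size.

    Returns ``(new_activation, clamped)`` where ``clamped`` flags an
    out-of-range excitation that was clipped into [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    clamped = not (0.0 <= excitation <= 1.0)
    e = min(1.0, max(0.0, float(excitation)))
    a = min(1.0, max(0.0, float(activation)))
    tau = params.tau_act if e > a else params.tau_deact
    a_new = e + (a - e) * np.exp(-dt / tau)
    return float(min(1.0, max(0.0, a_new))), clamped


def force_length_active(l_ce_norm: float, params: MuscleParams | None = None) -> float:
    """Active force-length factor: Gaussian bell, maximum 1 at l_ce_norm = 1."""
    w = params.fl_width if params is not None else 0.45
    x = np.asarray(l_ce_norm, dtype=float)
    return np.exp(-(((x - 1.0) / w) ** 2) * 4.0 * np.log(2.0))


def force_velocity(v_ce_norm: float, params: MuscleParams | None = None) -> float:
    """Force-velocity factor.

    ``v_ce_norm`` is CE velocity over v_max, shortening negative. The
    concentric branch is the classic rectangular hyperbola: 1 at v=0, 0 at
    v=-1. The eccentric branch rises toward ``fv_ecc_plateau`` and is
    continuous (value and slope) at v=0.
    """
    k = params.fv_shape if params is not None else 0.25
    n = params.fv_ecc_plateau if params is not None else 1.5
    v = np.asarray(v_ce_norm, dtype=float)
    # concentric: (1 + v) / (1 - v / k); clamp below max shortening speed
    con = np.clip((1.0 + v) / (1.0 - v / k), 0.0, None)
    # eccentric: n - (n - 1) * (1 + v * g), slope-matched at 0 with slope
    # of the concentric branch (1 + 1/k)
    slope0 = 1.0 + 1.0 / k
    g = slope0 / (n - 1.0) if n > 1.0 else 0.0
    ecc = n - (n - 1.0) / (1.0 + v * g)
    out = np.where(v <= 0.0, con, ecc)
    return float(out) if np.isscalar(v_ce_norm) else out


def force_passive(l_ce_norm: float, params: MuscleParams | None = None) -> float:
    """Passive (PE) force factor: zero at/below engagement, quadratic above.

    Normalized so the factor reaches 1 (i.e. a force of f_max) at a stretch
    of ``pe_stretch`` beyond the engagement length. Beyond that point the
    curve continues linearly with matched slope, keeping the passive joint
    stiffness bounded for numerical robustness under extreme stretches.
    """
    e0 = params.pe_engage if params is not None else 1.0
    w = params.pe_stretch if params is not None else 0.5
    x = np.asarray(l_ce_norm, dtype=float)
    s = np.clip((x - e0) / w, 0.0, None)
    out = np.where(s <= 1.0, s**2, 1.0 + 2.0 * (s - 1.0))
    return float(out) if np.isscalar(l_ce_norm) else out


def mtu_force(
    state: MuscleState,
    mtu_length: float,
    mtu_velocity: float,
    params: MuscleParams,
    elastic_tendon: bool = False,
) -> tuple[float, MuscleState]:
    """Total MTU force and updated muscle state.

    Rigid-tendon default: CE length = mtu_length - l_slack, CE velocity =
    mtu_velocity, and

        force = f_max * (a * fl(l) * fv(v) + fp(l))

    With ``elastic_tendon=True`` the CE length is found by root-finding the
    CE/SE force balance (tendon modelled as a stiff quadratic spring).

    Non-positive CE length marks the state degenerate and returns the
    passive-only floor (zero force at the clamped minimal length).
    """
    if mtu_length <= 0:
        raise ValueError("mtu_length must be positive")
    a = min(1.0, max(0.0, state.activation))
    if elastic_tendon:
        l_ce, f = _equilibrium_ce_length(a, mtu_length, mtu_velocity, params)
        new = MuscleState(activation=a, l_ce_norm=l_ce / params.l_opt,
                          force=f, degenerate=False)
        return f, new

    l_ce = mtu_length - params.l_slack
    degenerate = l_ce <= 0
    if degenerate:
        l_ce_norm = 0.01
        f = 0.0
    else:
        l_ce_norm = l_ce / params.l_opt
        v_ce_norm = mtu_velocity / (params.v_max * params.l_opt)
        f = params.f_max * (
            a * force_length_active(l_ce_norm, params)
            * force_velocity(v_ce_norm, params)
            + force_passive(l_ce_norm, params)
        )
    f = max(0.0, float(f))
    new = MuscleState(activation=a, l_ce_norm=float(l_ce_norm), force=f,
                      degenerate=degenerate)
    return f, new


def _tendon_force(l_se: float, params: MuscleParams) -> float:
    """SE force: stiff quadratic spring above slack, zero below."""
    strain = (l_se - params.l_slack) / params.l_slack
    if strain <= 0:
        return 0.0
    # reaches f_max at 4% strain — conventional tendon stiffness scale
    return params.f_max * (strain / 0.04) ** 2


def _equilibrium_ce_length(
    a: float, mtu_length: float, mtu_velocity: float, params: MuscleParams
) -> tuple[float, float]:
    """Solve f_ce(l_ce) = f_se(l_mtu - l_ce) for the elastic-tendon mode.

    The CE is evaluated quasi-statically (v distributed to the CE), which is
    adequate at the 1 ms substeps used by the integrator.
    """

    def residual(l_ce: float) -> float:
        l_ce_norm = l_ce / params.l_opt
        v_ce_norm = mtu_velocity / (params.v_max * params.l_opt)
        f_ce = params.f_max * (
            a * force_length_active(l_ce_norm, params)
            * force_velocity(v_ce_norm, params)
            + force_passive(l_ce_norm, params)
        )
        return f_ce - _tendon_force(mtu_length - l_ce, params)

    lo = 0.01 * params.l_opt
    hi = max(mtu_length - 1e-6, lo + 1e-6)
    try:
        if residual(lo) * residual(hi) > 0:
            l_ce = max(lo, min(hi, mtu_length - params.l_slack))
        else:
            l_ce = brentq(residual, lo, hi, xtol=1e-10)
    except ValueError:
        l_ce = max(lo, min(hi, mtu_length - params.l_slack))
    f = max(0.0, _tendon_force(mtu_length - l_ce, params))
    return l_ce, f


def effort_increment(activations: np.ndarray, dt: float) -> float:
    """One time-step increment of the effort cost: dt * sum_m A_m**2."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(activations, dtype=float)
    return float(dt * np.sum(a * a))
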