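"""Single-leg control.

Each leg is driven by two alternative procedures selected by the motivation
layer: a swing net that lifts the leg and moves it to the touchdown target,
and a stance net that lets the leg propel the body.  Additional elements are
the height controller (a saturating "soft spring" acting through the beta
joint), the standing integral controller with adaptive reference, the
levator avoidance reflex, analog load/contact handling, and the computation
of the effective PEP from the default PEP, the local load and the
coordination-rule shifts.

Travel frame: all PEP/AEP logic works on the coordinate ``u = s * x`` where
``s = +1`` for forward and ``-1`` for backward walking.  During stance ``u``
decreases; a leg lifts off when ``u`` falls below its effective PEP and
targets a point ``u_aep = u_pep + 0.3`` ahead.  This makes backward walking
a pure sign/role inversion, as selected by the motivation network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ControllerConfig
from .geometry import (
    JointAngles,
    JointVelocities,
    LegGeometry,
    LegID,
    forward_kinematics,
    jacobian,
)

__all__ = [
    "GatingError",
    "InconsistentStateError",
    "LegControllerState",
    "begin_swing",
    "swing_command",
    "apply_levator_reflex",
    "stance_command",
    "height_correction",
    "standing_joint_step",
    "update_load_and_contact",
    "effective_pep",
]


class GatingError(RuntimeError):
    """A procedure was invoked while its motivation unit is not the winner."""


class InconsistentStateError(RuntimeError):
    """Controller state contradicts the requested operation."""


@dataclass
class LegControllerState:
    """Mutable per-leg controller state (one instance per leg per run)."""

    leg: LegID
    geom: LegGeometry
    q: JointAngles
    qdot: JointVelocities = JointVelocities(0.0, 0.0, 0.0)
    # motivation outputs mirrored here for gating checks
    swing_mu: float = 0.0
    stance_mu: float = 1.0
    phase: str = "stance"  # "swing" | "stance"
    # swing-net internal states
    hpf_state: float = 0.0  # swing-net 3 high-pass rebound (rad/s)
    reb_a: float = 0.0  # swing-net 2 two-stage rebound
    reb_b: float = 0.0
    swing_target: Optional[JointAngles] = None
    swing_target_xy: Optional[Tuple[float, float]] = None  # body-frame x, y
    # standing integral controller (Sigma 1 per joint) and adaptive
    # reference (Sigma 2 per joint)
    integ1: List[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    stand_ref: List[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    stand_q0: List[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    # load and contact
    load: float = 0.0
    load_filt: float = 0.0  # low-passed combined load
    ground_load: float = 0.0  # local weight share, before rule-5 sharing
    ground_load_filt: float = 0.0  # low-passed own share; drives the PEP shift
    shared_load_in: float = 0.0
    contact: bool = True
    descending: bool = False
    # step geometry in the travel frame (u = s * x)
    u: float = 0.0  # current tarsus coordinate in the travel frame
    pep_u_default: float = 0.0
    aep_u_default: float = 0.3
    pep_u_effective: float = 0.0
    # bookkeeping
    stance_onset_t: float = 0.0
    swing_onset_t: float = 0.0
    stance_onset_u: float = 0.3
    reflex_timer: float = 0.0
    tarsus: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # body frame
    prev_tarsus_z: float = 0.0

    @property
    def in_swing(self) -> bool:
        return self.phase == "swing"


def begin_swing(state: LegControllerState, cfg: ControllerConfig, t: float) -> None:
    """Bookkeeping at the stance->swing transition: seed the rebound element
    that produces the tarsus lift and record the onset time."""
    state.phase = "swing"
    state.swing_onset_t = t
    state.reflex_timer = 0.0
    # The rebound impulse fights the simultaneous negative-feedback pull of
    # the beta servo toward the (below-ground) target, giving a rise-then-
    # fall profile that is near critically damped: peak beta excursion of an
    # impulse h0*exp(-t/tau) against a servo pole k is ~ h0/(k*e).  Size h0
    # so the tarsus peaks at about swing_lift_amplitude through the femur
    # lever arm (~ len_femur / 2 near walking poses).
    h0 = (
        cfg.swing_lift_amplitude
        * cfg.k_beta
        * math.e
        / (0.5 * state.geom.len_femur)
    )
    if cfg.swing_net_version == 3:
        state.hpf_state = h0
    elif cfg.swing_net_version == 2:
        state.reb_a = math.e * h0  # two-stage cascade peaks at h0/e
        state.reb_b = 0.0
    else:
        state.hpf_state = 0.0


def begin_stance(state: LegControllerState, t: float, u: float) -> None:
    state.phase = "stance"
    state.stance_onset_t = t
    state.stance_onset_u = u
    state.hpf_state = 0.0
    state.reb_a = 0.0
    state.reb_b = 0.0
    state.reflex_timer = 0.0


def _clip(v: float, bound: float) -> float:
    return min(max(v, -bound), bound)


def swing_command(
    state: LegControllerState,
    target: JointAngles,
    cfg: ControllerConfig,
    dt: float,
) -> JointVelocities:
    """Joint-velocity command of the swing net.

    Alpha and gamma are negative-feedback servos toward the target angles.
    The beta channel adds a rebound term that lifts the tarsus before it is
    lowered again: a high-pass-filtered impulse (version 3), a two-stage
    smooth rebound standing in for the antagonistic circuit (version 2), or
    crosstalk from the alpha channel (version 1, forward walking only).
    Mutates the rebound filter states.
    """
    if state.stance_mu > state.swing_mu:
        raise GatingError(
            f"swing_command on {state.leg} while stance motivation wins"
        )
    ea = target.alpha - state.q.alpha
    eb = target.beta - state.q.beta
    eg = target.gamma - state.q.gamma
    a_dot = _clip(cfg.k_alpha * ea, cfg.max_joint_speed)
    g_dot = _clip(cfg.k_gamma * eg, cfg.max_joint_speed)
    version = cfg.swing_net_version
    if version == 3:
        lift = state.hpf_state
        state.hpf_state *= math.exp(-dt / cfg.hpf_tau)
    elif version == 2:
        # cascade of two low-passes of the onset impulse: smooth rise, fall
        lift = state.reb_b
        decay = math.exp(-dt / cfg.hpf_tau)
        state.reb_b += (dt / cfg.hpf_tau) * (state.reb_a - state.reb_b)
        state.reb_a *= decay
    else:
        lift = cfg.crosstalk_gain * abs(a_dot)
    b_dot = _clip(cfg.k_beta * eb + lift, cfg.max_joint_speed)
    return JointVelocities(a_dot, b_dot, g_dot)


def apply_levator_reflex(
    state: LegControllerState,
    stimulus_site: Optional[str],
    cfg: ControllerConfig,
    dt: float,
    dir_sign: float = 1.0,
) -> Optional[JointVelocities]:
    """Avoidance reflex to a tactile stimulus at the front of the leg.

    During swing, a front-side stimulus makes the leg briefly retract
    (opposite to the travel direction) and lift; the swing then resumes.
    During stance the reflex is gated off entirely and ``None`` is returned
    (the nominal command stands).  Returns the overriding joint-velocity
    command while the reflex is running, else ``None``.
    """
    if not state.in_swing:
        return None
    if stimulus_site == "front" and state.reflex_timer <= 0.0:
        state.reflex_timer = cfg.reflex_duration
    if state.reflex_timer <= 0.0:
        return None
    state.reflex_timer -= dt
    v_task = np.array(
        [
            -dir_sign * cfg.reflex_retract / cfg.reflex_duration,
            0.0,
            cfg.reflex_lift / cfg.reflex_duration,
        ]
    )
    J = jacobian(state.geom, state.q)
    try:
        q_dot = np.linalg.solve(J, v_task)
    except np.linalg.LinAlgError:  # singular pose: lift only via beta
        q_dot = np.array([0.0, cfg.reflex_lift / cfg.reflex_duration, 0.0])
    q_dot = np.clip(q_dot, -cfg.max_joint_speed, cfg.max_joint_speed)
    return JointVelocities(*q_dot)


def stance_command(
    state: LegControllerState,
    v_commanded: float,
    dir_sign: float,
    clearance_error: float,
    cfg: ControllerConfig,
    dt: float,
    pep_pose: Optional[JointAngles] = None,
) -> JointVelocities:
    """Joint-velocity command of the stance net.

    ``pos_vel_feedback`` mode: alpha and gamma amplify their own measured
    velocities (the mechanical coupling through body and ground does the
    coordination); beta comes from the height controller only.
    ``neg_feedback`` mode: alpha and gamma servo toward the PEP-pose angles
    at a rate set by the commanded body velocity.
    """
    if not state.contact:
        raise InconsistentStateError(
            f"stance_command on {state.leg} without ground contact"
        )
    b_dot = height_correction(clearance_error, cfg)
    if cfg.stance_mode == "pos_vel_feedback":
        a_dot = _clip(cfg.pos_vel_gain * state.qdot.alpha_dot, cfg.max_joint_speed)
        g_dot = _clip(cfg.pos_vel_gain * state.qdot.gamma_dot, cfg.max_joint_speed)
        return JointVelocities(a_dot, b_dot, g_dot)
    if pep_pose is None:
        raise InconsistentStateError("neg_feedback stance mode needs the PEP pose")
    # time to reach the PEP at the commanded speed
    u = dir_sign * state.tarsus[0]
    t_left = max((u - state.pep_u_effective) / max(abs(v_commanded), 1e-6), dt)
    a_dot = _clip((pep_pose.alpha - state.q.alpha) / t_left, cfg.max_joint_speed)
    g_dot = _clip((pep_pose.gamma - state.q.gamma) / t_left, cfg.max_joint_speed)
    return JointVelocities(a_dot, b_dot, g_dot)


def height_correction(clearance_error: float, cfg: ControllerConfig) -> float:
    """Nonlinear soft-spring restoring command (beta channel / body height).

    ``clearance_error`` is reference minus actual clearance (m); the output
    is monotone in the error, saturates smoothly at large errors, and is
    exactly zero at the reference.
    """
    return cfg.height_gain * cfg.height_sat * math.tanh(
        clearance_error / cfg.height_sat
    )


def standing_joint_step(
    state: LegControllerState,
    joint: int,
    substrate_stiffness: float,
    disturbance: float,
    cfg: ControllerConfig,
    dt: float,
) -> float:
    """One tick of the standing controller for joint ``joint`` (0..2).

    The command is ``kp * e + I1`` where ``I1`` integrates the error
    (Sigma 1, with a slow leak bounding it), and the reference itself adapts
    toward the measured angle (Sigma 2).  ``disturbance`` is an external
    torque-like drive on the joint; the substrate is a spring of the given
    stiffness pulling the joint back to its initial angle.  On a compliant
    substrate the integral action nulls the position error; on a stiff
    substrate the joint cannot move, the reference converges to the actual
    value and the command decays -- the controller "gives up" integrating.

    Returns the motor command; mutates ``q``, ``integ1`` and ``stand_ref``.
    """
    qj = state.q[joint]
    e = state.stand_ref[joint] - qj
    i1 = state.integ1[joint] + (
        cfg.standing_ki * e - cfg.standing_leak * state.integ1[joint]
    ) * dt
    lim = cfg.standing_integ_limit
    state.integ1[joint] = min(max(i1, -lim), lim)
    u = cfg.standing_kp * e + state.integ1[joint]
    # Sigma 2: the reference drifts toward the measured value
    state.stand_ref[joint] += cfg.standing_adapt * (qj - state.stand_ref[joint]) * dt
    # joint-on-substrate kinetics
    q_dot = cfg.standing_mobility * (u + disturbance) - substrate_stiffness * (
        qj - state.stand_q0[joint]
    )
    q = list(state.q)
    q[joint] = qj + q_dot * dt
    state.q = JointAngles(*q)
    return u


def update_load_and_contact(
    state: LegControllerState,
    tarsus_z: float,
    terrain_z: float,
    weight_share: float,
    shared_load_in: float,
    cfg: ControllerConfig,
    dt: float = 0.0,
) -> None:
    """Set the analog load and the contact flag for this tick.

    Contact: tarsus at or below the terrain within the contact tolerance.
    Load: the leg's geometric share of the body weight while in contact,
    plus whatever the neighbours contribute through rule 5, clipped to
    [0, 1].  A low-passed copy (``load_filt``, mimicking the sluggishness
    of load afference) drives the PEP shift; the raw value drives the
    touchdown trigger.  Also tracks whether the tarsus is descending,
    which qualifies a fresh contact as a touchdown.
    """
    state.descending = tarsus_z < state.prev_tarsus_z - 1e-12
    state.prev_tarsus_z = tarsus_z
    state.contact = tarsus_z <= terrain_z + cfg.contact_tolerance
    state.ground_load = weight_share if state.contact else 0.0
    state.shared_load_in = shared_load_in
    state.load = min(max(state.ground_load + shared_load_in, 0.0), 1.0)
    if dt > 0:
        k = dt / cfg.load_filter_tau
        state.load_filt += k * (state.load - state.load_filt)
        state.ground_load_filt += k * (state.ground_load - state.ground_load_filt)
    else:
        state.load_filt = state.load
        state.ground_load_filt = state.ground_load


def effective_pep(
    state: LegControllerState,
    shifts: Sequence,
    cfg: ControllerConfig,
) -> float:
    """Effective PEP in the travel frame: the default PEP, shifted rearward
    in proportion to the local load, plus the superposition of all active
    coordination-rule shifts (rearward negative, forward positive)."""
    pep = state.pep_u_default - cfg.pep_load_shift_gain * state.load_filt
    for sh in shifts:
        pep += sh.delta_pep
    state.pep_u_effective = pep
    return pep
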