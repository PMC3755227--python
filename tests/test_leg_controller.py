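"""Single-leg control: swing trajectory shape and accuracy, the levator
reflex and its stance gating, stance command modes, the soft-spring height
controller, the standing integral controller, and effective-PEP
superposition."""

import math

import numpy as np
import pytest

import hexawalk.leg_controller as lc
from hexawalk.config import ControllerConfig
from hexawalk.coordination import CoordinationShift
from hexawalk.geometry import (
    JointAngles,
    JointVelocities,
    LegID,
    forward_kinematics,
    inverse_kinematics,
)

HEIGHT = 0.25  # body clearance used by the single-leg harness
STANCE_Y = 0.30


def make_state(geom, u=-0.15, phase="stance"):
    q = inverse_kinematics(geom, (u, STANCE_Y, -HEIGHT))
    st = lc.LegControllerState(leg=LegID("L", 2), geom=geom, q=q)
    st.phase = phase
    if phase == "swing":
        st.swing_mu, st.stance_mu = 1.0, 0.0
    return st


def ground_target(geom, cfg, u=0.15):
    """Swing target: the on-ground AEP pose with the beta channel pushed
    below ground by the configured depth (as the simulator builds it)."""
    pose = inverse_kinematics(geom, (u, STANCE_Y, -HEIGHT))
    dbeta = cfg.swing_target_depth / (0.5 * geom.len_femur)
    return JointAngles(pose.alpha, pose.beta - dbeta, pose.gamma)


def integrate_swing(geom, cfg, state, target, max_t=2.0, stimulus_at=None):
    """Closed-loop swing harness; returns (t_contact, tarsus, peak_lift,
    z trace)."""
    dt = 0.005
    zs = []
    prev_z = -HEIGHT
    for i in range(int(max_t / dt)):
        t = i * dt
        stim = "front" if stimulus_at is not None and abs(t - stimulus_at) < dt / 2 else None
        override = lc.apply_levator_reflex(state, stim, cfg, dt)
        cmd = override if override is not None else lc.swing_command(state, target, cfg, dt)
        state.q = geom.clip_to_limits(
            JointAngles(*(a + v * dt for a, v in zip(state.q, cmd)))
        )
        p = forward_kinematics(geom, state.q)
        zs.append(p[2])
        if i > 3 and p[2] <= -HEIGHT + 1e-3 and p[2] < prev_z:
            return t, p, max(zs) + HEIGHT, zs
        prev_z = p[2]
    return None, forward_kinematics(geom, state.q), max(zs) + HEIGHT, zs


def test_swing_command_zero_at_target(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="swing")
    st.hpf_state = 0.0
    cmd = lc.swing_command(st, st.q, ctrl, 0.005)
    assert all(abs(v) < 1e-9 for v in cmd)


def test_swing_command_gated_by_motivation(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="stance")
    st.swing_mu, st.stance_mu = 0.0, 1.0
    with pytest.raises(lc.GatingError):
        lc.swing_command(st, st.q, ctrl, 0.005)


@pytest.mark.parametrize("version", [1, 2, 3])
def test_swing_lifts_before_lowering(left_middle_geom, version):
    cfg = ControllerConfig(swing_net_version=version)
    st = make_state(left_middle_geom, phase="swing")
    lc.begin_swing(st, cfg, 0.0)
    target = ground_target(left_middle_geom, cfg)
    t_c, p, lift, zs = integrate_swing(left_middle_geom, cfg, st, target)
    assert t_c is not None, "swing must terminate in bounded time"
    peak_i = int(np.argmax(zs))
    assert lift > 0.015, "tarsus must lift visibly"
    assert 0 < peak_i < len(zs) - 1, "height rises before it falls"


def test_swing_terminal_position_accuracy(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="swing")
    lc.begin_swing(st, ctrl, 0.0)
    target = ground_target(left_middle_geom, ctrl)
    t_c, p, _, _ = integrate_swing(left_middle_geom, ctrl, st, target)
    aep = (0.15, STANCE_Y, -HEIGHT)
    assert t_c is not None
    assert math.dist(p, aep) < 5e-3


def test_levator_reflex_noop_during_stance(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="stance")
    assert lc.apply_levator_reflex(st, "front", ctrl, 0.005) is None
    assert st.reflex_timer == 0.0


def test_levator_reflex_retracts_and_lifts(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="swing")
    lc.begin_swing(st, ctrl, 0.0)
    # let the swing get airborne first
    target = ground_target(left_middle_geom, ctrl)
    dt = 0.005
    for _ in range(20):
        cmd = lc.swing_command(st, target, ctrl, dt)
        st.q = JointAngles(*(a + v * dt for a, v in zip(st.q, cmd)))
    p0 = forward_kinematics(left_middle_geom, st.q)
    n_reflex = int(ctrl.reflex_duration / dt)
    for i in range(n_reflex):
        cmd = lc.apply_levator_reflex(st, "front" if i == 0 else None, ctrl, dt)
        assert cmd is not None
        st.q = JointAngles(*(a + v * dt for a, v in zip(st.q, cmd)))
    p1 = forward_kinematics(left_middle_geom, st.q)
    assert p1[0] < p0[0] - 0.5 * ctrl.reflex_retract  # retracted (-x)
    assert p1[2] > p0[2] + 0.5 * ctrl.reflex_lift  # lifted (+z)


def test_swing_resumes_after_reflex_and_still_reaches_target(left_middle_geom, ctrl):
    st = make_state(left_middle_geom, phase="swing")
    lc.begin_swing(st, ctrl, 0.0)
    target = ground_target(left_middle_geom, ctrl)
    t_c, p, _, _ = integrate_swing(
        left_middle_geom, ctrl, st, target, stimulus_at=0.1
    )
    assert t_c is not None
    assert math.dist(p, (0.15, STANCE_Y, -HEIGHT)) < 5e-3


def test_stance_command_zero_at_rest(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    st.contact = True
    st.qdot = JointVelocities(0.0, 0.0, 0.0)
    cmd = lc.stance_command(st, 0.25, 1.0, 0.0, ctrl, 0.005)
    assert all(abs(v) < 1e-12 for v in cmd)


def test_stance_command_requires_contact(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    st.contact = False
    with pytest.raises(lc.InconsistentStateError):
        lc.stance_command(st, 0.25, 1.0, 0.0, ctrl, 0.005)


def test_stance_command_amplifies_measured_velocity(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    st.contact = True
    st.qdot = JointVelocities(-0.4, 0.0, 0.2)
    cmd = lc.stance_command(st, 0.25, 1.0, 0.0, ctrl, 0.005)
    assert cmd.alpha_dot == pytest.approx(ctrl.pos_vel_gain * -0.4)
    assert cmd.gamma_dot == pytest.approx(ctrl.pos_vel_gain * 0.2)


def test_stance_command_neg_feedback_mode(left_middle_geom):
    cfg = ControllerConfig(stance_mode="neg_feedback")
    st = make_state(left_middle_geom, u=0.1)
    st.contact = True
    st.u = 0.1
    st.pep_u_effective = -0.15
    pep_pose = inverse_kinematics(left_middle_geom, (-0.15, STANCE_Y, -HEIGHT))
    cmd = lc.stance_command(st, 0.25, 1.0, 0.0, cfg, 0.005, pep_pose=pep_pose)
    # command points from the current pose toward the PEP pose
    assert cmd.alpha_dot * (pep_pose.alpha - st.q.alpha) > 0


def test_height_correction_zero_at_reference_and_monotone(ctrl):
    assert lc.height_correction(0.0, ctrl) == 0.0
    small = lc.height_correction(0.01, ctrl)
    large = lc.height_correction(0.02, ctrl)
    assert 0 < small < large
    # saturates: doubling a large error less than doubles the command
    e1 = lc.height_correction(0.1, ctrl)
    e2 = lc.height_correction(0.2, ctrl)
    assert e2 < 2 * e1
    assert lc.height_correction(-0.02, ctrl) == -lc.height_correction(0.02, ctrl)


def test_standing_zero_error_is_quiescent(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    st.stand_ref = list(st.q)
    st.stand_q0 = list(st.q)
    u = lc.standing_joint_step(st, 0, 0.0, 0.0, ctrl, 0.005)
    assert abs(u) < 1e-12
    assert st.integ1[0] == 0.0


def test_standing_compliant_substrate_integral_action(left_middle_geom, ctrl):
    """On a compliant substrate a sustained external push is integrated
    away: the position error returns to (near) zero."""
    st = make_state(left_middle_geom)
    st.stand_ref = list(st.q)
    st.stand_q0 = list(st.q)
    dt = 0.005
    disturbance = 0.5
    for _ in range(int(40.0 / dt)):
        lc.standing_joint_step(st, 0, 0.0, disturbance, ctrl, dt)
    err = st.stand_ref[0] - st.q[0]
    assert abs(err) < 0.02
    assert abs(st.integ1[0]) < ctrl.standing_integ_limit


def test_standing_stiff_substrate_reference_adapts_and_command_decays(
    left_middle_geom, ctrl
):
    """On a stiff substrate the joint cannot move; the reference converges
    to the actual angle and the motor command gives up (decays)."""
    st = make_state(left_middle_geom)
    q0 = st.q[0]
    st.stand_ref = [st.q[0] + 0.3, st.q[1], st.q[2]]  # sustained error
    st.stand_q0 = list(st.q)
    dt = 0.005
    stiffness = 200.0
    cmds = []
    for _ in range(int(40.0 / dt)):
        cmds.append(lc.standing_joint_step(st, 0, stiffness, 0.0, ctrl, dt))
    assert abs(st.q[0] - q0) < 0.02  # joint barely moved
    assert abs(st.stand_ref[0] - st.q[0]) < 0.01  # reference -> actual
    assert abs(cmds[-1]) < 0.3 * max(abs(c) for c in cmds)  # command decays
    assert abs(st.integ1[0]) < ctrl.standing_integ_limit


def test_load_contact_flags(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    lc.update_load_and_contact(st, 0.01, 0.0, 0.3, 0.0, ctrl)
    assert not st.contact and st.ground_load == 0.0 and st.load == 0.0
    lc.update_load_and_contact(st, 0.0, 0.0, 0.3, 0.2, ctrl)
    assert st.contact and st.load == pytest.approx(0.5)
    lc.update_load_and_contact(st, 0.0, 0.0, 0.9, 0.5, ctrl)
    assert st.load == 1.0  # clipped


def test_effective_pep_defaults_and_load_shift(left_middle_geom, ctrl):
    st = make_state(left_middle_geom)
    st.pep_u_default = -0.15
    st.aep_u_default = 0.15
    assert st.aep_u_default - st.pep_u_default == pytest.approx(0.3)
    st.load_filt = 0.0
    assert lc.effective_pep(st, [], ctrl) == pytest.approx(-0.15)
    st.load_filt = 0.5
    assert lc.effective_pep(st, [], ctrl) < -0.15  # rearward under load


def test_effective_pep_superposition_matches_sum_oracle(left_middle_geom, ctrl, rng):
    st = make_state(left_middle_geom)
    st.pep_u_default = -0.15
    sender, receiver = LegID("L", 3), LegID("L", 2)
    for _ in range(200):
        n = int(rng.integers(0, 6))
        shifts = []
        for _ in range(n):
            rule = int(rng.choice([1, 2, 3]))
            mag = float(rng.uniform(0.005, 0.05))
            delta = -mag if rule == 1 else mag
            shifts.append(CoordinationShift(rule, sender, receiver, delta))
        st.load_filt = float(rng.uniform(0, 1))
        expected = (
            -0.15
            - ctrl.pep_load_shift_gain * st.load_filt
            + sum(s.delta_pep for s in shifts)
        )
        assert lc.effective_pep(st, shifts, ctrl) == pytest.approx(expected)
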