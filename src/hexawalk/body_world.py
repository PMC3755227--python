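"""Kinematic body/environment simulation: the "loop through the world".

The body is a rigid frame advancing at the commanded velocity along its
(fixed) heading; legs whose controllers are in stance keep their tarsi
pinned to the ground in world coordinates, so their joint angles follow by
inverse-kinematic consistency -- the kinematic expression of all stance
legs adopting the same velocity through the shared mechanics.  Swing legs
integrate the joint-velocity commands of their swing nets.  Body clearance
is regulated by the soft-spring height controller.  A run is deterministic
given its configuration and seed.

Stability bookkeeping: the centre of mass (the body origin's ground
projection) must stay inside the support polygon of the stance tarsi;
leaving it for more than 50 ms raises the fall flag and truncates the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import coordination as coord
from . import leg_controller as lc
from . import motivation as mot
from .config import ControllerConfig, SimConfig
from .gait_analysis import StepEvent
from .geometry import (
    ALL_LEGS,
    JointAngles,
    JointVelocities,
    LegID,
    OutOfWorkspaceError,
    forward_kinematics,
    inverse_kinematics,
)

__all__ = [
    "Terrain",
    "BodyState",
    "ShiftInterval",
    "SimTrace",
    "simulate",
    "integrate_step",
    "support_margin",
    "point_in_support",
]

#: ticks of anticipation on the PEP trigger, compensating the finite
#: switching latency of the swing/stance WTA pair (the pair needs a couple
#: of network updates to flip, during which the leg would otherwise keep
#: travelling past its PEP)
PEP_TRIGGER_LEAD_TICKS = 2.0

FALL_GRACE = 0.05  # s the CoM may leave the support polygon

#: Initial lift phases (fraction of the step period) for reduced leg sets,
#: from an offline search maximizing the minimum static-support margin over
#: a step cycle (with the adaptive step-range shifts applied and ipsilateral
#: neighbours never swinging together).  Same-side double amputations and
#: non-diagonal contralateral doubles have no statically feasible schedule
#: for a fixed-CoM kinematic walker and are not supported.
AMPUTEE_PHASES: Dict[frozenset, Dict[str, float]] = {
    frozenset({"L1"}): {"L2": 0.0, "L3": 11 / 14, "R1": 9 / 14, "R2": 6 / 14, "R3": 0.0},
    frozenset({"L2"}): {"L1": 0.0, "L3": 11 / 14, "R1": 9 / 14, "R2": 5 / 14, "R3": 2 / 14},
    frozenset({"L3"}): {"L1": 0.0, "L2": 11 / 14, "R1": 8 / 14, "R2": 5 / 14, "R3": 2 / 14},
    frozenset({"R1"}): {"R2": 0.0, "R3": 11 / 14, "L1": 9 / 14, "L2": 6 / 14, "L3": 0.0},
    frozenset({"R2"}): {"R1": 0.0, "R3": 11 / 14, "L1": 9 / 14, "L2": 5 / 14, "L3": 2 / 14},
    frozenset({"R3"}): {"R1": 0.0, "R2": 11 / 14, "L1": 8 / 14, "L2": 5 / 14, "L3": 2 / 14},
    frozenset({"L1", "R3"}): {"L2": 0.0, "L3": 11 / 14, "R1": 7 / 14, "R2": 4 / 14},
    frozenset({"L2", "R2"}): {"L1": 0.0, "L3": 11 / 14, "R1": 7 / 14, "R3": 4 / 14},
    frozenset({"L3", "R1"}): {"L1": 0.0, "L2": 11 / 14, "R2": 7 / 14, "R3": 4 / 14},
}


@dataclass
class Terrain:
    """Piecewise-flat ground: height 0, then ``height`` from each ``x_from``
    onward (later steps override earlier ones)."""

    steps: Tuple[Tuple[float, float], ...] = ()

    def height(self, x: float, y: float = 0.0) -> float:
        z = 0.0
        for x_from, h in self.steps:
            if x >= x_from:
                z = h
        return z


@dataclass
class BodyState:
    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0
    height: float = 0.25
    v_commanded: float = 0.0
    direction: str = "fw"


@dataclass(frozen=True)
class ShiftInterval:
    """One logged activation interval of a coordination-rule channel."""

    rule: int
    sender: LegID
    receiver: LegID
    t_on: float
    t_off: float
    delta_pep: float


@dataclass
class SimTrace:
    """Per-tick record of a run plus the digitized step events."""

    dt: float
    legs: Tuple[LegID, ...]
    t: np.ndarray
    body_x: np.ndarray
    height: np.ndarray
    stance_count: np.ndarray
    supported: np.ndarray
    phase: np.ndarray  # [n_legs, T] 1 = swing
    tarsus_x: np.ndarray  # body frame
    tarsus_z: np.ndarray  # world frame
    pep_eff: np.ndarray  # travel frame
    load: np.ndarray
    q: np.ndarray  # [n_legs, 3, T]
    events: List[StepEvent]
    shift_log: List[ShiftInterval]
    fall_time: Optional[float] = None
    config: Optional[SimConfig] = None

    @property
    def n_ticks(self) -> int:
        return len(self.t)

    @property
    def fell(self) -> bool:
        return self.fall_time is not None

    def leg_index(self, leg: LegID) -> int:
        return self.legs.index(leg)


def distribute_load(
    points: List[Tuple[float, float]], com: Tuple[float, float]
) -> List[float]:
    """Static weight distribution over the contact points.

    Minimum-norm nonnegative forces satisfying force balance (sum = 1 body
    weight) and moment balance about the centre of mass -- the quasi-static
    share each support actually carries.  When the CoM lies outside the
    support polygon no balancing solution exists; the remaining weight is
    then spread in proportion to the unconstrained solution's positive
    part (the walker is tipping anyway).
    """
    n = len(points)
    if n == 0:
        return []
    if n == 1:
        return [1.0]
    xs = [p[0] - com[0] for p in points]
    ys = [p[1] - com[1] for p in points]
    active = [True] * n
    f = [0.0] * n

    def solve_minnorm() -> bool:
        # min ||f|| s.t. sum f = 1, sum f x = 0, sum f y = 0 on the active
        # set: f = A^T (A A^T)^{-1} b with A = [1; x; y], b = (1, 0, 0)
        s0 = sx = sy = sxx = sxy = syy = 0.0
        for i in range(n):
            if not active[i]:
                continue
            x, y = xs[i], ys[i]
            s0 += 1.0
            sx += x
            sy += y
            sxx += x * x
            sxy += x * y
            syy += y * y
        # G = A A^T (symmetric 3x3); solve G m = b
        a11, a12, a13 = s0, sx, sy
        a22, a23, a33 = sxx, sxy, syy
        det = (
            a11 * (a22 * a33 - a23 * a23)
            - a12 * (a12 * a33 - a23 * a13)
            + a13 * (a12 * a23 - a22 * a13)
        )
        if abs(det) < 1e-12:
            return False
        m0 = (a22 * a33 - a23 * a23) / det
        m1 = -(a12 * a33 - a13 * a23) / det
        m2 = (a12 * a23 - a13 * a22) / det
        for i in range(n):
            f[i] = (m0 + m1 * xs[i] + m2 * ys[i]) if active[i] else 0.0
        return True

    for _ in range(n):
        if not solve_minnorm():
            break
        neg = [i for i in range(n) if active[i] and f[i] < -1e-12]
        if not neg:
            break
        for i in neg:
            active[i] = False
        if not any(active):
            break
    f = [max(v, 0.0) for v in f]
    # verify the balance; the greedy active set can drop a support the
    # exact solution needs -- fall back to a nonnegative least-squares fit
    res = (
        abs(sum(f) - 1.0)
        + abs(sum(fi * x for fi, x in zip(f, xs)))
        + abs(sum(fi * y for fi, y in zip(f, ys)))
    )
    if res > 1e-9:
        from scipy.optimize import nnls

        A = np.vstack([np.ones(n), xs, ys])
        f, _ = nnls(A, np.array([1.0, 0.0, 0.0]))
        f = list(f)
    tot = sum(f)
    return [v / tot for v in f] if tot > 1e-12 else [1.0 / n] * n


def _convex_hull(points: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Andrew's monotone chain; returns hull in counter-clockwise order."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
    lower: List[Tuple[float, float]] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: List[Tuple[float, float]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def point_in_support(
    point: Tuple[float, float], supports: List[Tuple[float, float]]
) -> bool:
    """True iff ``point`` lies inside (or on) the convex hull of the
    support points.  Fewer than three supports cannot enclose a point."""
    if len(supports) < 3:
        return False
    hull = _convex_hull(supports)
    if len(hull) < 3:
        return False
    px, py = point
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        if (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1) < -1e-12:
            return False
    return True


def support_margin(
    point: Tuple[float, float], supports: List[Tuple[float, float]]
) -> float:
    """Signed distance of ``point`` to the support-polygon boundary
    (positive inside)."""
    if len(supports) < 3:
        return -math.inf
    hull = _convex_hull(supports)
    if len(hull) < 3:
        return -math.inf
    px, py = point
    margin = math.inf
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        ex, ey = x2 - x1, y2 - y1
        norm = math.hypot(ex, ey)
        if norm < 1e-12:
            continue
        margin = min(margin, (ex * (py - y1) - ey * (px - x1)) / norm)
    return margin


class _Run:
    """Internal mutable state of one simulation run."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.morph = cfg.morphology
        self.ctrl = cfg.controller
        self.rules = cfg.rules
        self.terrain = Terrain(cfg.terrain_steps)
        amput = cfg.amputated_legs
        self.legs = tuple(l for l in ALL_LEGS if l not in amput)
        self.geoms = {l: self.morph.leg_geometry(l) for l in self.legs}
        self.graph = coord.build_coordination_graph(amput)
        self.net = mot.MotivationNetwork(cfg.motivation, legs=self.legs)
        self.body = BodyState(
            height=self.morph.height_reference, v_commanded=cfg.v_commanded,
            direction=cfg.direction,
        )
        self.rng = np.random.default_rng(cfg.seed)
        self.states: Dict[LegID, lc.LegControllerState] = {}
        self.anchors: Dict[LegID, Tuple[float, float, float]] = {}
        self._init_pose()

    # -- setup ------------------------------------------------------------
    def _travel_sign(self) -> float:
        return 1.0 if self.body.direction == "fw" else -1.0

    def _step_range_x(self, leg: LegID) -> Tuple[float, float]:
        """Default (pep_x, aep_x) of a leg, adapted for amputations: a leg
        neighbouring a lost leg shifts its whole step range (keeping the
        0.3 m step length, hence the common step period) toward the gap so
        the body stays straddled by supports on that side."""
        morph = self.morph
        ax = morph.attach_x[leg.index]
        amp = self.cfg.amputated_legs
        reach = morph.amputation_reach
        front, mid, hind = (LegID(leg.side, i) for i in (1, 2, 3))
        shift = 0.0
        if leg.index == 2:
            if front in amp:
                shift += reach
            if hind in amp:
                shift -= reach
        elif leg.index == 1 and mid in amp:
            shift -= 0.5 * reach
        elif leg.index == 3 and mid in amp:
            shift += 0.5 * reach
        return ax + morph.pep_offset + shift, ax + morph.aep_offset + shift

    def _set_step_frame(self, state: lc.LegControllerState) -> None:
        pep_x, aep_x = self._step_range_x(state.leg)
        if self.body.direction == "fw":
            state.pep_u_default = pep_x
            state.aep_u_default = aep_x
        else:
            state.pep_u_default = -aep_x
            state.aep_u_default = -pep_x

    def _amputee_order(self) -> List[LegID]:
        """Lift ordering for a reduced leg set: per-side back-to-front
        chains, with the depleted side's legs stepping consecutively while
        the stronger side's chain straddles them.  This keeps the single
        remaining support of the weak side near the body whenever its
        partner swings -- the only phasing whose support polygon stays
        feasible for a strictly statically stable kinematic walker."""
        chains = {
            side: [l for l in (LegID(side, 3), LegID(side, 2), LegID(side, 1))
                   if l in self.legs]
            for side in ("L", "R")
        }
        weak, strong = ("L", "R") if len(chains["L"]) <= len(chains["R"]) else ("R", "L")
        w, s = chains[weak], chains[strong]
        order: List[LegID] = []
        if s:
            order.append(s[0])
        order.extend(w)
        order.extend(s[1:])
        return order

    def _amputee_fracs(self) -> Dict[Tuple[str, int], float]:
        """Initial stance fractions for a reduced leg set.

        For supported amputation sets the lift phases come from the
        precomputed static-support schedule table; unsupported sets fall
        back to an even spread over the :meth:`_amputee_order` sequence.
        Phases (fractions of the step period) are converted to stance
        fractions at the commanded velocity.
        """
        v = max(abs(self.cfg.v_commanded), 1e-3)
        period = 0.3 / v + 0.5  # stance + nominal swing duration
        key = frozenset(l.name for l in self.cfg.amputated_legs)
        phases = AMPUTEE_PHASES.get(key)
        if phases is None:
            order = self._amputee_order()
            phases = {
                l.name: k / len(order) for k, l in enumerate(order)
            }
        return {
            (LegID.parse(name).side, LegID.parse(name).index): min(
                max(pf * period * v / 0.3, 0.02), 0.99
            )
            for name, pf in phases.items()
        }

    def _init_pose(self) -> None:
        # stance fractions (distance from PEP, as fraction of the step);
        # staggered so one tripod group is about to lift while the other
        # has just touched down (a valid start for any commanded velocity)
        default_frac = {
            ("L", 3): 0.05, ("R", 2): 0.10, ("L", 1): 0.15,
            ("R", 3): 0.90, ("L", 2): 0.95, ("R", 1): 0.99,
        }
        if len(self.legs) < 6:
            default_frac = self._amputee_fracs()
        h = self.body.height
        if self.cfg.initial_pose == "random":
            # arbitrary configuration = random ordering of step phases with
            # jitter; a uniform iid draw can start several legs at their PEP
            # simultaneously, which no walking animal exhibits
            spread = np.linspace(0.08, 0.92, len(self.legs))
            self.rng.shuffle(spread)
            random_frac = {
                leg: float(np.clip(f + self.rng.uniform(-0.04, 0.04), 0.02, 0.98))
                for leg, f in zip(self.legs, spread)
            }
        for leg in self.legs:
            if self.cfg.initial_pose == "random":
                frac = random_frac[leg]
            else:
                # functional index: the leading leg pair swaps in backward
                # walking, making the start the exact mirror of forward
                idx = leg.index if self.body.direction == "fw" else 4 - leg.index
                frac = default_frac[(leg.side, idx)]
            geom = self.geoms[leg]
            state = lc.LegControllerState(leg=leg, geom=geom, q=JointAngles(0, 0, -1))
            self._set_step_frame(state)
            u = state.pep_u_default + frac * (
                state.aep_u_default - state.pep_u_default
            )
            x = self._travel_sign() * u
            y = self.morph.tarsus_y(leg)
            z_world = self.terrain.height(self.body.x + x, y)
            q = inverse_kinematics(geom, (x, y, z_world - h))
            state.q = q
            state.tarsus = (x, y, z_world - h)
            state.prev_tarsus_z = z_world
            state.u = u
            state.stance_onset_u = u
            state.pep_u_effective = state.pep_u_default
            state.stand_ref = list(q)
            state.stand_q0 = list(q)
            self.states[leg] = state
            self.anchors[leg] = (self.body.x + x, y, z_world)
        initial_cmd = "walk_fw" if self.cfg.direction == "fw" else "walk_bw"
        mot.select_behavior(self.net, initial_cmd)
        if self.cfg.direction == "bw":
            # start on the backward attractor rather than flipping to it
            for pre, post in (("fw", "bw"), ("tfw", "tbw")):
                for name in self.net.names:
                    if name == pre or name.startswith(pre + "_"):
                        self.net.acts[self.net.idx[name]] = 0.0
                    elif name == post or name.startswith(post + "_"):
                        self.net.acts[self.net.idx[name]] = 1.0
        # settle the network on the commanded coalition before t = 0
        for _ in range(100):
            mot.network_step(self.net, None, self.cfg.dt)

    # -- helpers ----------------------------------------------------------
    def _with_depth(self, geom, pose: JointAngles) -> JointAngles:
        """Push only the beta target below the ground-contact pose.

        Alpha and gamma then converge to the exact touchdown pose (so the
        tarsus lands on target in the horizontal plane) while the beta
        overshoot provides a decisive final descent through the ground.
        """
        dbeta = self.ctrl.swing_target_depth / (0.5 * geom.len_femur)
        return JointAngles(pose.alpha, pose.beta - dbeta, pose.gamma)

    def _swing_target(self, leg: LegID, t: float) -> JointAngles:
        """Touchdown target at swing onset: the anterior leg's position via
        the targeting rule when available, else the default AEP."""
        state = self.states[leg]
        s = self._travel_sign()
        geom = self.geoms[leg]
        y = self.morph.tarsus_y(leg)
        x_default = s * state.aep_u_default
        state.swing_target_xy = (x_default, y)
        z_ground = self.terrain.height(self.body.x + x_default, y)
        default_pose = self._ik_or_clip(
            geom, (x_default, y, z_ground - self.body.height)
        )
        if not self.cfg.rules_enabled.get(4, True):
            return self._with_depth(geom, default_pose)
        gate = self.net.target_gate(leg, self.body.direction)
        if gate <= 0.5:
            return self._with_depth(geom, default_pose)
        sender = None
        for e in self.graph.active_edges(4, self.body.direction):
            if e.receiver == leg and e.sender in self.states:
                sender = self.states[e.sender]
                break
        if sender is None or sender.in_swing:
            return self._with_depth(geom, default_pose)
        # clamp the transmitted sender position so that, after the
        # clearance margin, the touchdown stays in a band around the
        # default AEP: targeting fine-tunes the foothold but may not
        # relocate it far enough to break the support pattern
        margin = self.rules.rule4_margin
        u_s = s * sender.tarsus[0]
        u_lo = state.aep_u_default - 0.06 + margin
        u_hi = state.aep_u_default + 0.06 + margin
        u_sender = min(max(u_s, u_lo), u_hi)
        x_sender = s * u_sender
        x = s * (u_sender - margin)
        state.swing_target_xy = (x, y)
        z_ground = self.terrain.height(self.body.x + x, y)
        pose = coord.rule4_target(
            (x_sender, y, z_ground - self.body.height), geom, gate,
            default_pose, self.rules, dir_sign=s,
            target_z=z_ground - self.body.height,
        )
        return self._with_depth(geom, pose)

    def _ik_or_clip(
        self, geom, point: Tuple[float, float, float]
    ) -> JointAngles:
        try:
            return inverse_kinematics(geom, point)
        except OutOfWorkspaceError as err:
            try:
                return inverse_kinematics(geom, err.nearest)
            except OutOfWorkspaceError:
                return geom.clip_to_limits(inverse_kinematics(geom, err.nearest, check_limits=False))


def integrate_step(run: _Run, t: float, swing_cmds: Dict[LegID, JointVelocities], dt: float) -> None:
    """Advance body and legs by one tick.

    The body moves ``v*dt`` along its heading (sign per direction) while it
    is walking; stance tarsi stay pinned at their world anchors and the
    joint angles follow by IK; swing legs integrate their commanded joint
    velocities.  A stance leg dragged out of its workspace is released into
    an emergency swing.
    """
    cfg, body = run.cfg, run.body
    s = run._travel_sign()
    walking = run.net.walking()
    if walking:
        body.x += s * body.v_commanded * dt
    # body clearance regulation (soft spring through the beta channels)
    clearance = body.height - run.terrain.height(body.x, body.y)
    err = run.morph.height_reference - clearance
    body.height += lc.height_correction(err, run.ctrl) * dt

    for leg in run.legs:
        state = run.states[leg]
        geom = run.geoms[leg]
        q_old = state.q
        if state.in_swing:
            cmd = swing_cmds.get(leg)
            if cmd is not None:
                q = JointAngles(
                    q_old.alpha + cmd.alpha_dot * dt,
                    q_old.beta + cmd.beta_dot * dt,
                    q_old.gamma + cmd.gamma_dot * dt,
                )
                state.q = geom.clip_to_limits(q)
        else:
            ax_w, ay_w, az_w = run.anchors[leg]
            local = (ax_w - body.x, ay_w, az_w - body.height)
            try:
                state.q = inverse_kinematics(geom, local)
            except OutOfWorkspaceError:
                _force_swing(run, leg, t)
        state.qdot = JointVelocities(
            *((a - b) / dt for a, b in zip(state.q, q_old))
        )


def _force_swing(run: _Run, leg: LegID, t: float) -> None:
    """Emergency lift: a stance leg left its workspace (dragged too far)."""
    net = run.net
    net.acts[net.idx[f"swing_{leg.name}"]] = 1.0
    net.acts[net.idx[f"stance_{leg.name}"]] = 0.0
    state = run.states[leg]
    lc.begin_swing(state, run.ctrl, t)
    state.swing_target = run._swing_target(leg, t)
    run._events.append(StepEvent(leg=leg, kind="swing_onset", t=t))


def simulate(cfg: SimConfig) -> SimTrace:
    """Run the full controller loop for ``cfg.duration`` seconds.

    Deterministic given (config, seed).  A fall truncates the trace and is
    recorded as ``fall_time`` rather than raised.
    """
    run = _Run(cfg)
    dt = cfg.dt
    n = int(round(cfg.duration / dt))
    legs = run.legs
    n_legs = len(legs)
    leg_ix = {l: i for i, l in enumerate(legs)}

    t_arr = np.arange(n) * dt
    body_x = np.zeros(n)
    height = np.zeros(n)
    stance_count = np.zeros(n, dtype=np.int8)
    supported = np.zeros(n, dtype=bool)
    phase = np.zeros((n_legs, n), dtype=np.int8)
    tarsus_x = np.zeros((n_legs, n))
    tarsus_z = np.zeros((n_legs, n))
    pep_eff = np.zeros((n_legs, n))
    load_arr = np.zeros((n_legs, n))
    q_arr = np.zeros((n_legs, 3, n))
    events: List[StepEvent] = []
    run._events = events
    shift_log: List[ShiftInterval] = []
    open_shifts: Dict[Tuple[int, LegID, LegID], Tuple[float, float]] = {}

    gain = cfg.motivation.sensory_gain
    ctrl = run.ctrl
    schedule = sorted(cfg.command_schedule)
    cmd_i = 0
    dist_events = sorted(cfg.disturbances, key=lambda d: d.time)
    fired_displace: set = set()
    fall_timer = 0.0
    fall_time: Optional[float] = None
    prev_loads = {l: run.states[l].ground_load for l in legs}
    lead = PEP_TRIGGER_LEAD_TICKS * dt
    end = n

    for i in range(n):
        t = i * dt
        # -- external commands ------------------------------------------
        while cmd_i < len(schedule) and t >= schedule[cmd_i][0]:
            mot.select_behavior(run.net, schedule[cmd_i][1])
            cmd_i += 1
        new_dir = run.net.direction()
        if new_dir != run.body.direction:
            run.body.direction = new_dir
            for leg in legs:
                st = run.states[leg]
                run._set_step_frame(st)
                st.stance_onset_u = run._travel_sign() * st.tarsus[0]
        s = run._travel_sign()
        walking = run.net.walking()
        if cfg.v_ramp is not None:
            v0, ramp_t = cfg.v_ramp
            frac_r = min(t / ramp_t, 1.0) if ramp_t > 0 else 1.0
            v = v0 + (cfg.v_commanded - v0) * frac_r
        else:
            v = cfg.v_commanded
        run.body.v_commanded = v

        # -- sensors ------------------------------------------------------
        contact_pts = []
        for leg in legs:
            st = run.states[leg]
            p = forward_kinematics(run.geoms[leg], st.q)
            st.tarsus = p
            st.u = s * p[0]
        # quasi-static weight distribution over the contact legs (moment-
        # balanced shares; a rear support opposite a swinging partner thus
        # carries more, which via the load-dependent PEP shift keeps it in
        # stance until the partner lands)
        contact_pts: List[Tuple[float, float]] = []
        contact_who: List[LegID] = []
        for leg in legs:
            st = run.states[leg]
            z_world = st.tarsus[2] + run.body.height
            terr = run.terrain.height(run.body.x + st.tarsus[0], st.tarsus[1])
            if z_world <= terr + ctrl.contact_tolerance:
                contact_pts.append((st.tarsus[0], st.tarsus[1]))
                contact_who.append(leg)
        shares = distribute_load(contact_pts, (0.0, 0.0))
        weights: Dict[LegID, float] = dict(zip(contact_who, shares))
        rule5_on = cfg.rules_enabled.get(5, True)
        gates = run.net.rule_gates()
        shared = (
            coord.rule5_load_share(prev_loads, run.graph, run.rules)
            if rule5_on and gates.get(5, 0.0) > 0.0
            else {l: 0.0 for l in legs}
        )
        for leg in legs:
            st = run.states[leg]
            z_world = st.tarsus[2] + run.body.height
            terr = run.terrain.height(run.body.x + st.tarsus[0], st.tarsus[1])
            share = weights.get(leg, 0.0)
            lc.update_load_and_contact(
                st, z_world, terr, share, shared[leg] * gates.get(5, 1.0),
                ctrl, dt,
            )

        # -- disturbances: load pulses and contact stimuli ---------------
        stimuli: Dict[LegID, str] = {}
        holds: Dict[LegID, bool] = {}
        for ev in dist_events:
            if ev.kind == "load_pulse" and ev.time <= t < ev.time + ev.duration:
                st = run.states[LegID.parse(ev.leg)]
                st.load = min(1.0, st.load + ev.magnitude)
            elif ev.kind == "front_contact_stimulus" and ev.time <= t < ev.time + dt:
                stimuli[LegID.parse(ev.leg)] = "front"
            elif ev.kind == "hold_swing" and ev.time <= t < ev.time + ev.duration:
                holds[LegID.parse(ev.leg)] = True
            elif (
                ev.kind == "displace_stance"
                and t >= ev.time
                and id(ev) not in fired_displace
                and ev.magnitude != 0.0
            ):
                fired_displace.add(id(ev))
                leg = LegID.parse(ev.leg)
                if not run.states[leg].in_swing:
                    ax_w, ay_w, az_w = run.anchors[leg]
                    dx, dy = {
                        "front": (ev.magnitude, 0.0),
                        "back": (-ev.magnitude, 0.0),
                        "out": (0.0, math.copysign(ev.magnitude, ay_w)),
                        "in": (0.0, -math.copysign(ev.magnitude, ay_w)),
                    }[ev.direction]
                    run.anchors[leg] = (ax_w + dx, ay_w + dy, az_w)

        # -- coordination shifts ------------------------------------------
        shifts = coord.active_shifts(
            run.states, run.graph, t, v, run.rules, gates,
            cfg.rules_enabled, run.body.direction,
        )
        now_active: Dict[Tuple[int, LegID, LegID], float] = {}
        for leg in legs:
            for sh in shifts[leg]:
                now_active[(sh.rule, sh.sender, sh.receiver)] = sh.delta_pep
            lc.effective_pep(run.states[leg], shifts[leg], ctrl)
        for key, delta in now_active.items():
            if key not in open_shifts:
                open_shifts[key] = (t, delta)
        for key in list(open_shifts):
            if key not in now_active:
                t_on, delta = open_shifts.pop(key)
                shift_log.append(
                    ShiftInterval(key[0], key[1], key[2], t_on, t, delta)
                )

        # -- motivation layer ---------------------------------------------
        sens: Dict[str, float] = {}
        if walking:
            for leg in legs:
                st = run.states[leg]
                if not st.in_swing and st.u <= st.pep_u_effective + lead * v:
                    # PEP reached: trigger the swing unit
                    sens[f"swing_{leg.name}"] = gain
                elif st.in_swing and not st.contact:
                    # no ground contact: proprioceptive support keeps the
                    # swing unit the winner until touchdown
                    sens[f"swing_{leg.name}"] = gain
                if (
                    st.in_swing
                    and st.descending
                    and st.contact
                    and st.load >= ctrl.contact_load_threshold
                ):
                    sens[f"stance_{leg.name}"] = gain
                elif st.in_swing and st.contact and not st.descending:
                    # mechanical contact at the front of the leg while it
                    # moves forward (e.g. brushing a terrain step): the
                    # levator avoidance pathway, not a touchdown
                    stimuli.setdefault(leg, "front")
        mot.network_step(run.net, sens, dt)

        # -- phase transitions --------------------------------------------
        for leg in legs:
            st = run.states[leg]
            winner = run.net.phase_winner(leg) if walking else "stance"
            st.swing_mu = run.net.output(f"swing_{leg.name}")
            st.stance_mu = run.net.output(f"stance_{leg.name}")
            if winner == "swing" and not st.in_swing:
                lc.begin_swing(st, ctrl, t)
                st.swing_target = run._swing_target(leg, t)
                events.append(StepEvent(leg=leg, kind="swing_onset", t=t))
            elif winner == "stance" and st.in_swing:
                # touchdown: project the tarsus onto the ground and anchor it
                x, y, _ = st.tarsus
                terr = run.terrain.height(run.body.x + x, y)
                try:
                    st.q = inverse_kinematics(
                        run.geoms[leg], (x, y, terr - run.body.height)
                    )
                except OutOfWorkspaceError:
                    pass
                p = forward_kinematics(run.geoms[leg], st.q)
                st.tarsus = p
                st.u = s * p[0]
                lc.begin_stance(st, t, st.u)
                run.anchors[leg] = (run.body.x + p[0], p[1], p[2] + run.body.height)
                events.append(StepEvent(leg=leg, kind="stance_onset", t=t))

        # -- leg commands ---------------------------------------------------
        swing_cmds: Dict[LegID, JointVelocities] = {}
        for leg in legs:
            st = run.states[leg]
            if not walking:
                for j in range(3):
                    lc.standing_joint_step(st, j, 1e3, 0.0, ctrl, dt)
                continue
            if st.in_swing:
                if holds.get(leg):
                    swing_cmds[leg] = JointVelocities(0.0, 0.0, 0.0)
                    continue
                if st.swing_target_xy is not None:
                    # track the target AEP against the current body height
                    # and terrain (the body may rise while the leg swings)
                    tx, ty = st.swing_target_xy
                    terr_t = run.terrain.height(run.body.x + tx, ty)
                    try:
                        st.swing_target = run._with_depth(
                            run.geoms[leg],
                            inverse_kinematics(
                                run.geoms[leg],
                                (tx, ty, terr_t - run.body.height),
                            ),
                        )
                    except OutOfWorkspaceError:
                        pass
                override = lc.apply_levator_reflex(
                    st, stimuli.get(leg), ctrl, dt, dir_sign=s
                )
                if override is not None:
                    swing_cmds[leg] = override
                else:
                    swing_cmds[leg] = lc.swing_command(
                        st, st.swing_target, ctrl, dt
                    )

        # -- world update ---------------------------------------------------
        integrate_step(run, t, swing_cmds, dt)
        # rule 5 shares only the locally sensed ground loads (sharing the
        # already-shared total would let load echo between neighbours)
        prev_loads = {l: run.states[l].ground_load for l in legs}

        # -- record ---------------------------------------------------------
        body_x[i] = run.body.x
        height[i] = run.body.height
        sc = 0
        supports = []
        for k, leg in enumerate(legs):
            st = run.states[leg]
            swing = st.in_swing
            phase[k, i] = 1 if swing else 0
            tarsus_x[k, i] = st.tarsus[0]
            tarsus_z[k, i] = st.tarsus[2] + run.body.height
            pep_eff[k, i] = st.pep_u_effective
            load_arr[k, i] = st.load
            q_arr[k, :, i] = st.q
            if not swing:
                sc += 1
                supports.append((run.body.x + st.tarsus[0], st.tarsus[1]))
        stance_count[i] = sc
        ok = point_in_support((run.body.x, run.body.y), supports)
        supported[i] = ok
        if walking and not ok:
            fall_timer += dt
            if fall_timer > FALL_GRACE:
                fall_time = t
                end = i + 1
                break
        else:
            fall_timer = 0.0

    for key, (t_on, delta) in open_shifts.items():
        shift_log.append(ShiftInterval(key[0], key[1], key[2], t_on, end * dt, delta))

    return SimTrace(
        dt=dt,
        legs=legs,
        t=t_arr[:end],
        body_x=body_x[:end],
        height=height[:end],
        stance_count=stance_count[:end],
        supported=supported[:end],
        phase=phase[:, :end],
        tarsus_x=tarsus_x[:, :end],
        tarsus_z=tarsus_z[:, :end],
        pep_eff=pep_eff[:, :end],
        load=load_arr[:, :end],
        q=q_arr[:, :, :end],
        events=events,
        shift_log=sorted(shift_log, key=lambda s: s.t_on),
        fall_time=fall_time,
        config=cfg,
    )
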