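"""Inter-leg coordination rules 1-5.

Rules 1-3 shift the receiver's PEP (rearward = inhibitory, forward =
excitatory) inside time or position windows determined by the sender's
step phase; rule 4 transmits the sender's tarsus position as the
receiver's swing target (AEP); rule 5 shares supra-threshold load signals
between neighbouring legs.

Topology (no amputations):

* rule 1: ipsilateral, back to front (3->2, 2->1)
* rule 2: ipsilateral back to front, and contralateral (both ways)
* rule 3: ipsilateral front to back (1->2, 2->3), and contralateral both ways
* rule 4: ipsilateral front to back (targeting)
* rule 5: between neighbours (ipsilateral adjacent and contralateral pairs)

Losing a middle leg inserts new ipsilateral hind->front edges carrying
rules 1-3 so that the remaining ipsilateral pair stays coordinated.  In
backward walking the functional front/back axis reverses, so directed
ipsilateral edges swap sender and receiver (the sign inversion of the PEP
shifts is already handled by working in the travel frame u = s*x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .config import RuleParams
from .geometry import (
    ALL_LEGS,
    JointAngles,
    LegGeometry,
    LegID,
    OutOfWorkspaceError,
    inverse_kinematics,
)

__all__ = [
    "CoordinationShift",
    "Edge",
    "CoordinationGraph",
    "build_coordination_graph",
    "rule1_shift",
    "rule2_shift",
    "rule3_shift",
    "rule4_target",
    "rule5_load_share",
    "active_shifts",
]


@dataclass(frozen=True)
class CoordinationShift:
    """A rule-generated PEP displacement at the receiver (travel frame;
    negative = rearward/inhibitory, positive = forward/excitatory)."""

    rule: int
    sender: LegID
    receiver: LegID
    delta_pep: float

    def __post_init__(self) -> None:
        if self.rule == 1 and self.delta_pep > 0:
            raise ValueError("rule 1 shifts must be rearward (negative)")
        if self.rule in (2, 3) and self.delta_pep < 0:
            raise ValueError(f"rule {self.rule} shifts must be forward (positive)")


@dataclass(frozen=True)
class Edge:
    sender: LegID
    receiver: LegID
    rule: int
    kind: str  # "ipsi" | "contra"


def _ipsi_pairs(legs: Set[LegID], side: str) -> List[Tuple[LegID, LegID]]:
    """Adjacent (front, back) pairs on one side, present legs only."""
    present = sorted(
        (l for l in legs if l.side == side), key=lambda l: l.index
    )
    return [(a, b) for a, b in zip(present, present[1:])]


@dataclass
class CoordinationGraph:
    """Edge list of the coordination network, with per-edge enable flags."""

    edges: List[Edge]
    amputations: FrozenSet[LegID]
    enabled: Dict[Edge, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            self.enabled.setdefault(e, True)

    def active_edges(self, rule: int, direction: str = "fw") -> List[Edge]:
        """Edges carrying ``rule``, with ipsilateral directed edges reversed
        for backward walking (functional front/back inversion)."""
        out = []
        for e in self.edges:
            if e.rule != rule or not self.enabled[e]:
                continue
            if direction == "bw" and e.kind == "ipsi" and rule in (1, 2, 3, 4):
                out.append(Edge(e.receiver, e.sender, e.rule, e.kind))
            else:
                out.append(e)
        return out

    def neighbours(self, leg: LegID) -> List[LegID]:
        """Rule-5 neighbourhood of ``leg``."""
        out = set()
        for e in self.edges:
            if e.rule != 5 or not self.enabled[e]:
                continue
            if e.sender == leg:
                out.add(e.receiver)
            elif e.receiver == leg:
                out.add(e.sender)
        return sorted(out)


def build_coordination_graph(
    amputations: Iterable[LegID] = (),
) -> CoordinationGraph:
    """Default coordination topology minus edges incident to amputated legs,
    plus the hind->front bridge (rules 1-3) when a middle leg is lost."""
    amp = frozenset(amputations)
    if len(amp) > 2:
        raise ValueError("unsupported configuration: more than two amputations")
    legs = set(ALL_LEGS) - amp
    edges: List[Edge] = []

    for side in ("L", "R"):
        # anatomically adjacent ipsilateral pairs among the *full* layout
        full_pairs = [
            (LegID(side, 1), LegID(side, 2)),
            (LegID(side, 2), LegID(side, 3)),
        ]
        for front, back in full_pairs:
            if front in legs and back in legs:
                edges.append(Edge(back, front, 1, "ipsi"))
                edges.append(Edge(back, front, 2, "ipsi"))
                edges.append(Edge(front, back, 3, "ipsi"))
                edges.append(Edge(front, back, 4, "ipsi"))
                edges.append(Edge(front, back, 5, "ipsi"))
        # middle-leg loss: bridge hind and front
        mid, front_leg, hind = LegID(side, 2), LegID(side, 1), LegID(side, 3)
        if mid in amp and front_leg in legs and hind in legs:
            for rule in (1, 2, 3):
                edges.append(Edge(hind, front_leg, rule, "ipsi"))

    for idx in (1, 2, 3):
        left, right = LegID("L", idx), LegID("R", idx)
        if left in legs and right in legs:
            for a, b in ((left, right), (right, left)):
                edges.append(Edge(a, b, 2, "contra"))
                edges.append(Edge(a, b, 3, "contra"))
            edges.append(Edge(left, right, 5, "contra"))

    return CoordinationGraph(edges=edges, amputations=amp)


def rule1_shift(
    sender_state,
    t: float,
    v: float,
    params: RuleParams,
    edge: Edge,
) -> Optional[CoordinationShift]:
    """Rearward shift at the receiver while the sender swings, prolonged by
    the velocity-dependent delay_1b after the sender's touchdown."""
    active = sender_state.in_swing or (
        t - sender_state.stance_onset_t < params.delay_1b(v)
    )
    if not active:
        return None
    return CoordinationShift(1, edge.sender, edge.receiver, params.rule1_shift)


def rule2_shift(
    sender_stance_onset: float,
    t: float,
    params: RuleParams,
    edge: Edge,
) -> Optional[CoordinationShift]:
    """Forward shift in the fixed time window [onset + 270 ms, + 50 ms)."""
    dt_on = t - sender_stance_onset
    # small epsilon so grid-aligned boundary ticks are classified stably
    eps = 1e-9
    if not (
        params.rule2_delay - eps
        <= dt_on
        < params.rule2_delay + params.rule2_window - eps
    ):
        return None
    mag = params.rule2_shift_ipsi if edge.kind == "ipsi" else params.rule2_shift_contra
    return CoordinationShift(2, edge.sender, edge.receiver, mag)


def rule3_shift(
    sender_state,
    v: float,
    params: RuleParams,
    edge: Edge,
    direction: str = "fw",
) -> Optional[CoordinationShift]:
    """Forward shift while the sender, in stance, sits inside a velocity-
    dependent position window measured as distance travelled rearward from
    its touchdown position.  The displacement table is keyed by the
    receiver's functional position, which reverses in backward walking
    (the anatomical hind leg then plays the leading role)."""
    if sender_state.in_swing:
        return None
    travelled = sender_state.stance_onset_u - sender_state.u
    thr = params.thr(v, edge.kind)
    if not (thr <= travelled < thr + params.rule3_window):
        return None
    func_index = edge.receiver.index if direction == "fw" else 4 - edge.receiver.index
    mag = params.rule3_shift[edge.kind][func_index]
    return CoordinationShift(3, edge.sender, edge.receiver, mag)


def rule4_target(
    sender_tarsus: Tuple[float, float, float],
    receiver_geom: LegGeometry,
    gating: float,
    default_aep: JointAngles,
    params: RuleParams,
    dir_sign: float = 1.0,
    target_z: Optional[float] = None,
) -> JointAngles:
    """Swing target from the anterior leg's current position (targeting).

    The sender's tarsus position, offset rearward (against the travel
    direction) by a clearance margin, is converted to receiver joint angles;
    if the targeting channel is gated off or the point is unreachable the
    default AEP pose is returned.
    """
    if gating <= 0.0:
        return default_aep
    x = sender_tarsus[0] - dir_sign * params.rule4_margin
    y = sender_tarsus[1]
    z = sender_tarsus[2] if target_z is None else target_z
    try:
        return inverse_kinematics(receiver_geom, (x, y, z))
    except OutOfWorkspaceError:
        return default_aep


def rule5_load_share(
    loads: Dict[LegID, float],
    graph: CoordinationGraph,
    params: RuleParams,
) -> Dict[LegID, float]:
    """Supra-threshold load of each leg, summed into its neighbours."""
    out = {leg: 0.0 for leg in loads}
    for leg in loads:
        for nb in graph.neighbours(leg):
            if nb in loads and loads[nb] > params.rule5_threshold:
                out[leg] += loads[nb]
    return out


def active_shifts(
    states: Dict[LegID, object],
    graph: CoordinationGraph,
    t: float,
    v: float,
    params: RuleParams,
    gates: Dict[int, float],
    rules_enabled: Dict[int, bool],
    direction: str = "fw",
) -> Dict[LegID, List[CoordinationShift]]:
    """All PEP shifts (rules 1-3) active this tick, grouped by receiver.

    Gate outputs from the motivation layer multiply the shift magnitudes
    (multiplicative gating), so a channel whose motivation unit is silent
    contributes exactly nothing.
    """
    shifts: Dict[LegID, List[CoordinationShift]] = {leg: [] for leg in states}
    for rule in (1, 2, 3):
        if not rules_enabled.get(rule, True):
            continue
        gate = gates.get(rule, 1.0)
        if gate <= 0.0:
            continue
        for e in graph.active_edges(rule, direction):
            if e.sender not in states or e.receiver not in states:
                continue
            sender = states[e.sender]
            if rule == 1:
                sh = rule1_shift(sender, t, v, params, e)
            elif rule == 2:
                if sender.in_swing:
                    sh = None
                else:
                    sh = rule2_shift(sender.stance_onset_t, t, params, e)
            else:
                sh = rule3_shift(sender, v, params, e, direction)
            if sh is not None and gate < 1.0:
                sh = CoordinationShift(
                    sh.rule, sh.sender, sh.receiver, sh.delta_pep * gate
                )
            if sh is not None:
                shifts[e.receiver].append(sh)
    return shifts
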