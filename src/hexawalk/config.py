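"""Configuration: morphology, controller, coordination-rule and simulation
defaults, plus YAML load/save.

All distances are in m, times in s, angles in rad.  The two numbers the
behavioural literature fixes directly are the default AEP-PEP distance
(0.3 m) and the rule-2 timing (270 ms delay, 50 ms window); everything else
(segment lengths, gains, rule displacement magnitudes, velocity-dependence
coefficients) is a calibrated default of this package, chosen so that a
stick-insect-like workspace results and the emergent gait continuum spans
wave to tripod over the supported velocity range.  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .geometry import ALL_LEGS, LegGeometry, LegID

__all__ = [
    "MorphologyConfig",
    "ControllerConfig",
    "RuleParams",
    "MotivationConfig",
    "Disturbance",
    "SimConfig",
    "default_config",
    "load_config",
    "save_config",
]

#: Distance between default AEP and default PEP (m).
STEP_LENGTH = 0.3

#: Supported commanded-velocity range (m/s) for steady walking.
V_MIN, V_MAX = 0.03, 0.42


@dataclass
class MorphologyConfig:
    """Symmetric six-leg layout.  Attachment x per leg index, common lateral
    attachment offset, segment lengths and joint limits shared by all legs,
    and the default stance geometry (lateral tarsus distance, AEP/PEP
    offsets from the attachment, body clearance)."""

    attach_x: Dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.0, 3: -0.25}
    )
    attach_y: float = 0.05
    attach_z: float = 0.0
    phi: float = 0.0
    psi: float = 0.0
    len_coxa: float = 0.1
    len_femur: float = 0.3
    len_tibia: float = 0.3
    alpha_limits: Tuple[float, float] = (-1.45, 1.45)
    beta_limits: Tuple[float, float] = (-1.2, 1.5)
    gamma_limits: Tuple[float, float] = (-3.0, -0.02)
    #: lateral distance of the tarsus from the body midline during stance
    stance_y: float = 0.30
    #: AEP / PEP x offsets from the leg's attachment point; their difference
    #: is the default step length of 0.3 m.
    aep_offset: float = 0.15
    pep_offset: float = -0.15
    #: default body clearance above the ground
    height_reference: float = 0.25
    #: how far a neighbour extends its step range toward the workspace of an
    #: amputated leg (front loss: ipsi middle reaches forward; hind loss:
    #: ipsi middle holds rearward; middle loss: front and hind close the
    #: gap by half this amount each)
    amputation_reach: float = 0.1

    def leg_geometry(self, leg: LegID) -> LegGeometry:
        return LegGeometry(
            side=leg.side,
            attach=(
                self.attach_x[leg.index],
                self.attach_y * (1 if leg.side == "L" else -1),
                self.attach_z,
            ),
            phi=self.phi,
            psi=self.psi,
            len_coxa=self.len_coxa,
            len_femur=self.len_femur,
            len_tibia=self.len_tibia,
            alpha_limits=tuple(self.alpha_limits),
            beta_limits=tuple(self.beta_limits),
            gamma_limits=tuple(self.gamma_limits),
        )

    def aep_x(self, leg: LegID) -> float:
        return self.attach_x[leg.index] + self.aep_offset

    def pep_x(self, leg: LegID) -> float:
        return self.attach_x[leg.index] + self.pep_offset

    def tarsus_y(self, leg: LegID) -> float:
        return self.stance_y * (1 if leg.side == "L" else -1)


@dataclass
class ControllerConfig:
    """Single-leg controller parameters (swing, stance, height, standing,
    load handling, reflex)."""

    swing_net_version: int = 3  # 1, 2 or 3
    stance_mode: str = "pos_vel_feedback"  # or "neg_feedback"
    # swing servo gains (1/s) and speed bound (rad/s)
    k_alpha: float = 15.0
    k_beta: float = 8.0
    k_gamma: float = 15.0
    max_joint_speed: float = 10.0
    # swing-net 3: high-pass rebound element in the beta channel
    swing_lift_amplitude: float = 0.05  # m of tarsus lift
    hpf_tau: float = 0.15  # s
    # swing-net 1: beta crosstalk from the alpha channel
    crosstalk_gain: float = 0.5
    # swing targeting: aim this far below the ground so touchdown is decisive
    swing_target_depth: float = 0.02
    # stance
    pos_vel_gain: float = 1.0
    # height controller: soft spring, saturating
    height_gain: float = 2.5  # 1/s
    height_sat: float = 0.06  # m, saturation scale of the soft spring
    # load / contact
    contact_tolerance: float = 1e-3  # m
    contact_load_threshold: float = 0.05
    pep_load_shift_gain: float = 0.02  # m of rearward PEP shift per unit load
    load_filter_tau: float = 0.1  # s, low-pass on the load driving the shift
    # levator reflex
    reflex_duration: float = 0.1  # s
    reflex_retract: float = 0.03  # m
    reflex_lift: float = 0.02  # m
    # standing integral controller (per joint)
    standing_kp: float = 2.0
    standing_ki: float = 4.0  # 1/s, error integrator (Sigma 1)
    standing_adapt: float = 0.5  # 1/s, reference adaptation rate (Sigma 2)
    standing_leak: float = 0.1  # 1/s, slow leak bounding the Sigma 1 integrator
    standing_integ_limit: float = 5.0
    standing_mobility: float = 1.0


@dataclass
class RuleParams:
    """Coordination-rule parameters.

    ``delay_1b(v) = max(0, delay1b_a - delay1b_b * v)`` is the
    velocity-dependent prolongation of rule 1 past the sender's touchdown.
    ``thr(v) = max(0, thr_a - thr_b * v)`` is the stance distance the rule-3
    sender must have travelled (from its touchdown position) before the
    influence becomes active; ipsilateral and contralateral channels have
    separate coefficient sets.  Displacements are signed PEP shifts in the
    travel frame: negative = rearward (inhibitory), positive = forward
    (excitatory).
    """

    # rule 1
    delay1b_a: float = 0.25  # s
    delay1b_b: float = 0.4  # s per m/s
    # large enough to block the receiver's lift-off for the whole sender
    # swing even at the top commanded velocity (0.42 m/s x ~0.45 s swing)
    rule1_shift: float = -0.18  # m, rearward
    # rule 2
    rule2_delay: float = 0.270  # s
    rule2_window: float = 0.050  # s
    rule2_shift_ipsi: float = 0.02  # m, forward
    rule2_shift_contra: float = 0.03
    # rule 3
    thr_a_ipsi: float = 0.22  # m
    thr_b_ipsi: float = 0.15  # m per m/s
    thr_a_contra: float = 0.25
    thr_b_contra: float = 0.15
    rule3_window: float = 0.05  # m, position window width
    # displacement table keyed by (edge kind, receiver index)
    rule3_shift: Dict[str, Dict[int, float]] = field(
        default_factory=lambda: {
            "ipsi": {1: 0.02, 2: 0.025, 3: 0.03},
            "contra": {1: 0.01, 2: 0.015, 3: 0.05},
        }
    )
    # rule 4 (targeting): rearward clearance margin behind the sender tarsus
    rule4_margin: float = 0.03  # m
    # rule 5 (load sharing)
    rule5_threshold: float = 0.1

    def delay_1b(self, v: float) -> float:
        return max(0.0, self.delay1b_a - self.delay1b_b * abs(v))

    def thr(self, v: float, kind: str) -> float:
        if kind == "ipsi":
            return max(0.0, self.thr_a_ipsi - self.thr_b_ipsi * abs(v))
        return max(0.0, self.thr_a_contra - self.thr_b_contra * abs(v))


@dataclass
class MotivationConfig:
    """Motivation-unit network parameters.  WTA pairs use mutual inhibition
    with self-excitation; units are discrete first-order low-passes with
    piecewise-linear (clamped) activation."""

    tau: float = 0.05  # s, default unit time constant
    tau_phase: float = 0.015  # s, swing/stance pairs switch faster
    wta_inhibition: float = -2.0
    self_excitation: float = 1.1
    sensory_gain: float = 3.0


@dataclass
class Disturbance:
    """One scheduled disturbance event."""

    time: float
    leg: str  # e.g. "L2"
    kind: str  # hold_swing | displace_stance | load_pulse | front_contact_stimulus
    magnitude: float = 0.0
    duration: float = 0.0
    direction: str = "back"  # for displace_stance: front|back|in|out


@dataclass
class SimConfig:
    """Complete, reproducible description of one simulation run."""

    dt: float = 0.005
    duration: float = 30.0
    v_commanded: float = 0.25
    #: optional soft start: (initial velocity, ramp seconds) -- the commanded
    #: velocity rises linearly from the initial value to v_commanded
    v_ramp: Optional[Tuple[float, float]] = None
    direction: str = "fw"  # or "bw"
    seed: int = 0
    initial_pose: str = "default"  # or "random"
    amputations: Tuple[str, ...] = ()
    disturbances: Tuple[Disturbance, ...] = ()
    #: terrain steps: list of (x_from, height); ground is 0 before the first
    terrain_steps: Tuple[Tuple[float, float], ...] = ()
    rules_enabled: Dict[int, bool] = field(
        default_factory=lambda: {1: True, 2: True, 3: True, 4: True, 5: True}
    )
    #: command switches: list of (time, command) applied mid-run
    command_schedule: Tuple[Tuple[float, str], ...] = ()
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    rules: RuleParams = field(default_factory=RuleParams)
    motivation: MotivationConfig = field(default_factory=MotivationConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 0.01):
            raise ValueError("dt must be in (0, 0.01] s")
        if self.direction not in ("fw", "bw"):
            raise ValueError("direction must be 'fw' or 'bw'")
        if len(self.amputations) > 2:
            raise ValueError("at most two legs may be amputated")
        amp = {LegID.parse(a) for a in self.amputations}
        for d in self.disturbances:
            if LegID.parse(d.leg) in amp:
                raise ValueError(f"disturbance on amputated leg {d.leg}")

    @property
    def amputated_legs(self) -> frozenset:
        return frozenset(LegID.parse(a) for a in self.amputations)


def default_config(**overrides) -> SimConfig:
    """A fresh default configuration, optionally with top-level overrides."""
    return SimConfig(**overrides)


def _to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["schema_version"] = 1
    return d


def save_config(cfg: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d.pop("schema_version", None)
    for key, cls in (
        ("morphology", MorphologyConfig),
        ("controller", ControllerConfig),
        ("rules", RuleParams),
        ("motivation", MotivationConfig),
    ):
        if key in d and isinstance(d[key], dict):
            sub = d[key]
            f_types = {f.name for f in dataclasses.fields(cls)}
            d[key] = cls(**{k: v for k, v in sub.items() if k in f_types})
    if "disturbances" in d:
        d["disturbances"] = tuple(
            Disturbance(**ev) if isinstance(ev, dict) else ev
            for ev in d["disturbances"]
        )
    if "terrain_steps" in d:
        d["terrain_steps"] = tuple(tuple(t) for t in d["terrain_steps"])
    if "amputations" in d:
        d["amputations"] = tuple(d["amputations"])
    if "command_schedule" in d:
        d["command_schedule"] = tuple(tuple(c) for c in d["command_schedule"])
    if "rules_enabled" in d:
        d["rules_enabled"] = {int(k): bool(v) for k, v in d["rules_enabled"].items()}
    morph = d.get("morphology")
    if isinstance(morph, MorphologyConfig) and isinstance(
        next(iter(morph.attach_x)), str
    ):
        morph.attach_x = {int(k): v for k, v in morph.attach_x.items()}
    return SimConfig(**d)
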