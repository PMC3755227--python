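"""Motivation-unit network for behaviour selection.

Units are discrete first-order low-pass elements with piecewise-linear
(threshold/saturation) activation, coupled into a recurrent heterarchical
network: per-leg swing/stance pairs and forward/backward target-net pairs
under local winner-take-all (WTA) coupling, per-leg "leg" units, the global
walk/stand and fw/bw pairs, and one gating unit per coordination-rule
channel.  Excitatory links build coalitions (walk + all leg units + one of
fw/bw); WTA pairs use mutual inhibition with self-excitation, so the
current winner is held hysteretically until sensory input flips the pair.

Procedure outputs are gated multiplicatively by their unit's output, so a
behaviour whose motivation is silent contributes exactly nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import MotivationConfig
from .geometry import ALL_LEGS, LegID

__all__ = [
    "MotivationUnit",
    "unit_step",
    "MotivationNetwork",
    "network_step",
    "select_behavior",
]

COMMANDS = ("stand", "walk_fw", "walk_bw")


@dataclass
class MotivationUnit:
    """A single low-pass, piecewise-linear unit."""

    name: str
    activation: float = 0.0
    time_constant: float = 0.05
    bias: float = 0.0

    @property
    def output(self) -> float:
        return min(max(self.activation, 0.0), 1.0)


def unit_step(u: MotivationUnit, net_input: float, dt: float) -> MotivationUnit:
    """Discrete first-order low-pass toward clamp(net_input + bias).

    The closed-form step response is
    ``a[k] = x + (a[0] - x) * (1 - dt/tau)^k`` with ``x`` the clamped drive.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt >= u.time_constant:
        warnings.warn(
            f"dt={dt} >= time constant {u.time_constant}; unit update may be "
            "unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    x = min(max(net_input + u.bias, 0.0), 1.0)
    a = u.activation + (dt / u.time_constant) * (x - u.activation)
    return MotivationUnit(u.name, min(max(a, 0.0), 1.0), u.time_constant, u.bias)


class MotivationNetwork:
    """The full selection network for one walker.

    Unit names: ``swing_<leg>``, ``stance_<leg>``, ``leg_<leg>``,
    ``tfw_<leg>``, ``tbw_<leg>`` for each of the six legs, the global
    ``walk``, ``stand``, ``fw``, ``bw``, and rule gates ``r1`` .. ``r5``.
    """

    def __init__(
        self,
        cfg: Optional[MotivationConfig] = None,
        legs: Tuple[LegID, ...] = ALL_LEGS,
    ):
        self.cfg = cfg or MotivationConfig()
        self.legs = tuple(legs)
        names: List[str] = []
        for leg in self.legs:
            names += [f"swing_{leg.name}", f"stance_{leg.name}", f"leg_{leg.name}"]
            names += [f"tfw_{leg.name}", f"tbw_{leg.name}"]
        names += ["walk", "stand", "fw", "bw"]
        names += [f"r{k}" for k in range(1, 6)]
        self.names = names
        self.idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        self.acts = np.zeros(n)
        self.tau = np.full(n, self.cfg.tau)
        self.bias = np.zeros(n)
        self.drive = np.zeros(n)  # external command drive
        self.W = np.zeros((n, n))
        self._build()

    # -- wiring -----------------------------------------------------------
    def _wta(self, a: str, b: str) -> None:
        ia, ib = self.idx[a], self.idx[b]
        self.W[ia, ib] = self.cfg.wta_inhibition
        self.W[ib, ia] = self.cfg.wta_inhibition
        self.W[ia, ia] = self.cfg.self_excitation
        self.W[ib, ib] = self.cfg.self_excitation

    def _build(self) -> None:
        cfg = self.cfg
        iw, ist = self.idx["walk"], self.idx["stand"]
        ifw, ibw = self.idx["fw"], self.idx["bw"]
        self._wta("walk", "stand")
        self._wta("fw", "bw")
        # deterministic tie-breaks: stance over swing, fw over bw
        self.bias[ifw] = 0.02
        for leg in self.legs:
            s, t = self.idx[f"swing_{leg.name}"], self.idx[f"stance_{leg.name}"]
            l = self.idx[f"leg_{leg.name}"]
            tf, tb = self.idx[f"tfw_{leg.name}"], self.idx[f"tbw_{leg.name}"]
            self._wta(f"swing_{leg.name}", f"stance_{leg.name}")
            self._wta(f"tfw_{leg.name}", f"tbw_{leg.name}")
            self.tau[s] = self.tau[t] = cfg.tau_phase
            self.bias[t] = 0.02
            self.bias[tf] = 0.02
            # coalition: walk drives the leg unit, which enables the pair
            self.W[l, iw] = 1.0
            self.W[iw, l] = 0.05
            self.W[s, l] = 0.3
            self.W[t, l] = 0.3
            # standing suppresses swinging
            self.W[s, ist] = -2.0
            # direction units select the matching target nets
            self.W[tf, ifw] = 1.0
            self.W[tb, ibw] = 1.0
        for k in range(1, 6):
            self.W[self.idx[f"r{k}"], iw] = 1.0
        # default startup state: standing, forward selected
        self.acts[ist] = 1.0
        self.acts[ifw] = 1.0
        for leg in self.legs:
            self.acts[self.idx[f"stance_{leg.name}"]] = 1.0
            self.acts[self.idx[f"tfw_{leg.name}"]] = 1.0

    # -- queries ----------------------------------------------------------
    def output(self, name: str) -> float:
        return float(np.clip(self.acts[self.idx[name]], 0.0, 1.0))

    def outputs(self) -> np.ndarray:
        return np.clip(self.acts, 0.0, 1.0)

    def phase_winner(self, leg: LegID) -> str:
        s = self.acts[self.idx[f"swing_{leg.name}"]]
        t = self.acts[self.idx[f"stance_{leg.name}"]]
        return "swing" if s > t else "stance"

    def direction(self) -> str:
        return "fw" if self.acts[self.idx["fw"]] >= self.acts[self.idx["bw"]] else "bw"

    def walking(self) -> bool:
        return self.acts[self.idx["walk"]] > self.acts[self.idx["stand"]]

    def rule_gates(self) -> Dict[int, float]:
        return {k: self.output(f"r{k}") for k in range(1, 6)}

    def target_gate(self, leg: LegID, direction: str) -> float:
        key = f"tfw_{leg.name}" if direction == "fw" else f"tbw_{leg.name}"
        return self.output(key)


def network_step(
    net: MotivationNetwork,
    sensory: Optional[Dict[str, float]],
    dt: float,
) -> None:
    """Synchronous update: every unit reads the previous tick's outputs.

    ``sensory`` maps unit names to additive input currents (e.g. the load
    trigger into ``stance_<leg>``, the PEP-reached trigger into
    ``swing_<leg>``, external command drive is handled separately).
    """
    out = np.clip(net.acts, 0.0, 1.0)
    inp = net.W @ out + net.bias + net.drive
    if sensory:
        for name, val in sensory.items():
            inp[net.idx[name]] += val
    target = np.clip(inp, 0.0, 1.0)
    net.acts += (dt / net.tau) * (target - net.acts)
    np.clip(net.acts, 0.0, 1.0, out=net.acts)


def select_behavior(net: MotivationNetwork, command: str, dt: float = 0.0) -> None:
    """Apply external drive for a top-level command.

    ``stand`` drives the stand unit; ``walk_fw``/``walk_bw`` drive walk plus
    the corresponding direction unit.  The downstream coalition (leg units,
    target nets, rule gates) settles through the recurrent dynamics; if
    ``dt > 0`` the network is stepped once.
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; valid: {COMMANDS}")
    net.drive[:] = 0.0
    if command == "stand":
        net.drive[net.idx["stand"]] = 3.0
    else:
        net.drive[net.idx["walk"]] = 3.0
        net.drive[net.idx["fw" if command == "walk_fw" else "bw"]] = 3.0
    if dt > 0:
        network_step(net, None, dt)
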