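"""Named experiment scenarios.

Every behavioural experiment the package reproduces is expressed as a
deterministic list of :class:`~hexawalk.config.SimConfig` objects, so no
hand-built inputs are needed anywhere: ``make_scenario(name)`` plus
``simulate`` covers the whole acceptance surface.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List

from .config import Disturbance, SimConfig, default_config
from .geometry import ALL_LEGS

__all__ = ["SCENARIO_NAMES", "make_scenario", "GAIT_SWEEP_VELOCITIES"]

#: Commanded velocities (m/s) of the gait sweep, slow wave to fast tripod.
GAIT_SWEEP_VELOCITIES = (0.05, 0.1, 0.15, 0.2, 0.25, 0.35, 0.4, 0.42)

SCENARIO_NAMES = (
    "gait_sweep",
    "amputation_grid",
    "swing_prolongation",
    "stance_displacement",
    "backward_switch",
    "terrain_step",
    "random_init_convergence",
)


def make_scenario(name: str, **overrides) -> List[SimConfig]:
    """Deterministic config list for a named experiment (desk scale)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    base: Dict = dict(seed=1)
    base.update(overrides)

    if name == "gait_sweep":
        return [
            default_config(v_commanded=v, duration=60.0, **base)
            for v in GAIT_SWEEP_VELOCITIES
        ]

    if name == "amputation_grid":
        # Valid double amputations are the diagonal contralateral pairs
        # (front+hind opposite sides, both middles).  Same-side doubles
        # leave a single support on that side, and same- or adjacent-
        # segment cross pairs leave no statically feasible schedule for a
        # fixed-CoM kinematic walker: excluded.
        configs = []
        singles = [(l.name,) for l in ALL_LEGS]
        doubles = [("L1", "R3"), ("L2", "R2"), ("L3", "R1")]
        # Targeting is disabled for amputee runs: after a loss the anterior
        # neighbour's foothold is often absent or far outside the support
        # pattern the reduced leg set needs, so legs use their default AEPs.
        for amp in singles + doubles:
            configs.append(
                default_config(
                    amputations=amp, v_commanded=0.15, duration=60.0,
                    rules_enabled={1: True, 2: True, 3: True, 4: False, 5: True},
                    **base,
                )
            )
        return configs

    if name == "swing_prolongation":
        return [
            default_config(
                duration=30.0,
                disturbances=(
                    Disturbance(
                        time=12.0, leg="L2", kind="hold_swing",
                        magnitude=1.0, duration=0.6,
                    ),
                ),
                **base,
            )
        ]

    if name == "stance_displacement":
        return [
            default_config(
                duration=30.0,
                disturbances=(
                    Disturbance(
                        time=12.0, leg="R2", kind="displace_stance",
                        magnitude=0.03, duration=0.0, direction=direction,
                    ),
                ),
                **base,
            )
            for direction in ("front", "back", "in", "out")
        ]

    if name == "backward_switch":
        # the reversal passes through a brief stand, as walking animals do
        return [
            default_config(
                duration=45.0,
                command_schedule=((20.0, "stand"), (22.0, "walk_bw")),
                **base,
            )
        ]

    if name == "terrain_step":
        return [
            default_config(
                duration=40.0, terrain_steps=((3.0, 0.05),),
                **base,
            )
        ]

    if name == "random_init_convergence":
        # soft start: the walker accelerates from near standstill, letting
        # the rules sort the arbitrary initial phases before speed builds
        seed0 = base.pop("seed", 1)
        return [
            default_config(
                initial_pose="random", duration=60.0, v_commanded=0.15,
                v_ramp=(0.02, 25.0), seed=seed0 + k, **base
            )
            for k in range(10)
        ]

    raise AssertionError("unreachable")
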