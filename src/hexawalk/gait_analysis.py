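"""Footfall-pattern analysis: podograms, stance counts, gait labels and the
delay 3-1 statistic.

A podogram is a legs x time raster of swing (True) / stance (False), rows
ordered R1, R2, R3, L1, L2, L3.  Gait labels are coarse summaries of a
continuum: with the minimum number of legs on the ground over a
steady-state window being >= 5 the pattern is called wave, 4 tetrapod,
3 tripod, fewer irregular.  Delay 3-1 is the interval from a hind-leg
swing onset to the next ipsilateral front-leg swing onset; plotted against
the step period it characterizes where a walk sits on the wave-tetrapod-
tripod continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import LegID

__all__ = [
    "StepEvent",
    "Podogram",
    "InsufficientDataError",
    "extract_step_events",
    "podogram_from_trace",
    "stance_count_profile",
    "classify_gait",
    "delay31_vs_period",
]

#: Row order of podograms (right side on top, as footfall charts are drawn).
PODOGRAM_ORDER: Tuple[LegID, ...] = tuple(
    LegID(side, idx) for side in ("R", "L") for idx in (1, 2, 3)
)


class InsufficientDataError(ValueError):
    """Raised when a window is too short for the requested statistic."""


@dataclass(frozen=True, order=True)
class StepEvent:
    """A swing or stance onset of one leg."""

    t: float
    leg: LegID = field(compare=False)
    kind: str = field(compare=False)  # "swing_onset" | "stance_onset"

    def __init__(self, leg: LegID, kind: str, t: float):
        if kind not in ("swing_onset", "stance_onset"):
            raise ValueError(f"unknown event kind {kind!r}")
        object.__setattr__(self, "leg", leg)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "t", float(t))


@dataclass
class Podogram:
    """Swing raster: ``swing[i, k]`` True if leg ``legs[i]`` swings at tick
    ``k``."""

    swing: np.ndarray
    dt: float
    legs: Tuple[LegID, ...] = PODOGRAM_ORDER

    @property
    def n_ticks(self) -> int:
        return self.swing.shape[1]

    def mirror(self) -> "Podogram":
        """Left/right mirror (used by symmetry checks)."""
        order = [self.legs.index(l.mirror()) for l in self.legs]
        return Podogram(self.swing[order], self.dt, self.legs)

    def to_text(self) -> str:
        lines = []
        for leg, row in zip(self.legs, self.swing):
            lines.append(leg.name + " " + "".join("#" if s else "." for s in row))
        return "\n".join(lines)


def extract_step_events(trace) -> List[StepEvent]:
    """Digitize the per-leg phase-winner transitions of a trace.

    Events are emitted at the tick where the winner flips; per leg the
    kinds strictly alternate (asserted).
    """
    if trace.n_ticks == 0:
        raise ValueError("empty trace")
    events: List[StepEvent] = []
    for k, leg in enumerate(trace.legs):
        row = trace.phase[k]
        flips = np.nonzero(np.diff(row.astype(np.int8)))[0] + 1
        for i in flips:
            kind = "swing_onset" if row[i] == 1 else "stance_onset"
            events.append(StepEvent(leg=leg, kind=kind, t=trace.t[i]))
    events.sort()
    _assert_alternation(events)
    return events


def _assert_alternation(events: Sequence[StepEvent]) -> None:
    last: Dict[LegID, str] = {}
    for ev in events:
        if last.get(ev.leg) == ev.kind:
            raise AssertionError(
                f"step events of {ev.leg} do not alternate at t={ev.t}"
            )
        last[ev.leg] = ev.kind


def podogram_from_trace(trace) -> Podogram:
    """Podogram of a trace, rows in standard order (absent legs dropped)."""
    order = [l for l in PODOGRAM_ORDER if l in trace.legs]
    rows = [trace.phase[trace.leg_index(l)] == 1 for l in order]
    return Podogram(np.array(rows), trace.dt, tuple(order))


def stance_count_profile(
    p: Podogram, window: Optional[Tuple[float, float]] = None
) -> Tuple[np.ndarray, int]:
    """Per-tick stance counts and their minimum over the steady-state
    window (default: the last half of the record)."""
    counts = p.swing.shape[0] - p.swing.sum(axis=0)
    if window is None:
        lo = p.n_ticks // 2
        hi = p.n_ticks
    else:
        lo = int(window[0] / p.dt)
        hi = int(window[1] / p.dt)
    if hi <= lo:
        raise InsufficientDataError("empty steady-state window")
    return counts, int(counts[lo:hi].min())


def classify_gait(
    p: Podogram, window: Optional[Tuple[float, float]] = None
) -> str:
    """Coarse gait label from the minimum stance count over the window.

    Requires at least five complete step cycles of every stepping leg in
    the window; raises :class:`InsufficientDataError` otherwise.  The label
    is a convenience summary -- the underlying patterns form a continuum.
    """
    counts, min_count = stance_count_profile(p, window)
    lo = p.n_ticks // 2 if window is None else int(window[0] / p.dt)
    hi = p.n_ticks if window is None else int(window[1] / p.dt)
    for row in p.swing:
        seg = row[lo:hi]
        onsets = np.count_nonzero(np.diff(seg.astype(np.int8)) == 1)
        if onsets > 0 and onsets < 5:
            raise InsufficientDataError(
                f"only {onsets} step cycles in window; need >= 5"
            )
    if min_count >= 5:
        return "wave"
    if min_count == 4:
        return "tetrapod"
    if min_count == 3:
        return "tripod"
    return "irregular"


def delay31_vs_period(
    events: Sequence[StepEvent], min_cycles: int = 5
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Delay 3-1 versus step period, pooled over both body sides.

    For each hind-leg swing onset: the delay to the next ipsilateral
    front-leg swing onset, and the period as the interval to the hind leg's
    own next swing onset.  Cycles without a front-leg onset before the next
    hind onset are skipped and counted.  Returns a tidy frame with columns
    (side, period, delay) and a summary with mean/SD of both and the number
    of skipped cycles.
    """
    rows = []
    skipped = 0
    for side in ("L", "R"):
        hind = sorted(
            ev.t for ev in events
            if ev.leg == LegID(side, 3) and ev.kind == "swing_onset"
        )
        front = np.array(sorted(
            ev.t for ev in events
            if ev.leg == LegID(side, 1) and ev.kind == "swing_onset"
        ))
        if len(hind) - 1 < min_cycles:
            raise InsufficientDataError(
                f"side {side}: only {max(len(hind) - 1, 0)} hind-leg cycles; "
                f"need >= {min_cycles}"
            )
        for t0, t1 in zip(hind, hind[1:]):
            nxt = front[front >= t0]
            if len(nxt) == 0 or nxt[0] >= t1:
                skipped += 1
                continue
            rows.append({"side": side, "period": t1 - t0, "delay": nxt[0] - t0})
    df = pd.DataFrame(rows, columns=["side", "period", "delay"])
    summary = {
        "delay_mean": float(df["delay"].mean()) if len(df) else float("nan"),
        "delay_sd": float(df["delay"].std(ddof=1)) if len(df) > 1 else float("nan"),
        "period_mean": float(df["period"].mean()) if len(df) else float("nan"),
        "period_sd": float(df["period"].std(ddof=1)) if len(df) > 1 else float("nan"),
        "n_pairs": float(len(df)),
        "n_skipped": float(skipped),
    }
    return df, summary
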