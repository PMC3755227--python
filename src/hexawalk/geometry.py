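"""Kinematics of a three-jointed insect leg in a body-fixed frame.

Conventions (used everywhere in the package):

* Body frame: ``+x`` anterior, ``+y`` left, ``+z`` dorsal.  The PEP/AEP of a
  leg is the ``x`` coordinate of its tarsus in this frame.
* Each leg has three revolute joints: the thorax-coxa joint (angle ``alpha``,
  protraction/retraction), the coxa-trochanterofemur joint (angle ``beta``,
  levation/depression) and the femur-tibia joint (angle ``gamma``,
  flexion/extension).
* Zero pose: ``alpha = 0`` puts the leg axis perpendicular to the body long
  axis (pointing laterally outward); ``beta = 0`` puts the femur horizontal;
  ``gamma = 0`` puts the tibia collinear with the femur.  Hence at
  ``(0, 0, 0)`` the tarsus lies at maximal planar extension, a distance
  ``len_coxa + len_femur + len_tibia`` from the thorax-coxa joint.
* Sign conventions: positive ``alpha`` moves the tarsus anteriorly on both
  body sides; positive ``beta`` lifts the femur; negative ``gamma`` flexes
  the tibia ventrally.  The inverse kinematics always selects the knee-up
  branch (``gamma <= 0``).
* The orientation of the thorax-coxa rotation axis is given by two angles
  ``phi`` (tilt in the sagittal x-z plane) and ``psi`` (lateral tilt,
  mirrored between body sides).  Both default to zero (vertical axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "LegID",
    "ALL_LEGS",
    "LegGeometry",
    "JointAngles",
    "JointVelocities",
    "OutOfWorkspaceError",
    "forward_kinematics",
    "inverse_kinematics",
    "in_workspace",
    "jacobian",
]


@dataclass(frozen=True, order=True)
class LegID:
    """Identifier of one of the six legs: side 'L'/'R', index 1 (front),
    2 (middle) or 3 (hind)."""

    side: str
    index: int

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.index not in (1, 2, 3):
            raise ValueError(f"index must be 1, 2 or 3, got {self.index!r}")

    @property
    def name(self) -> str:
        return f"{self.side}{self.index}"

    @classmethod
    def parse(cls, name: str) -> "LegID":
        name = name.strip().upper()
        if len(name) != 2:
            raise ValueError(f"cannot parse leg id {name!r}")
        return cls(name[0], int(name[1]))

    def mirror(self) -> "LegID":
        return LegID("R" if self.side == "L" else "L", self.index)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The six legs, left side then right side, front to hind.
ALL_LEGS: Tuple[LegID, ...] = tuple(
    LegID(side, idx) for side in ("L", "R") for idx in (1, 2, 3)
)


class JointAngles(NamedTuple):
    alpha: float
    beta: float
    gamma: float


class JointVelocities(NamedTuple):
    alpha_dot: float
    beta_dot: float
    gamma_dot: float


class OutOfWorkspaceError(ValueError):
    """Raised when a target point cannot be reached by the leg.

    Carries ``nearest``, the closest reachable point (body frame), so
    callers such as the swing targeting rule can fall back gracefully.
    """

    def __init__(self, msg: str, nearest: Tuple[float, float, float]):
        super().__init__(msg)
        self.nearest = nearest


@dataclass(frozen=True)
class LegGeometry:
    """Morphology of one leg: attachment point of the thorax-coxa joint in
    the body frame, orientation of its rotation axis (phi, psi), segment
    lengths, joint limits, and the body side (which fixes the outward
    direction)."""

    side: str
    attach: Tuple[float, float, float]
    phi: float = 0.0
    psi: float = 0.0
    len_coxa: float = 0.1
    len_femur: float = 0.3
    len_tibia: float = 0.3
    alpha_limits: Tuple[float, float] = (-1.45, 1.45)
    beta_limits: Tuple[float, float] = (-1.2, 1.5)
    gamma_limits: Tuple[float, float] = (-3.0, -0.02)
    # cached tilt rotation, computed lazily
    _tilt: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        for name in ("len_coxa", "len_femur", "len_tibia"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (math.isfinite(self.phi) and math.isfinite(self.psi)):
            raise ValueError("phi, psi must be finite")
        object.__setattr__(self, "_tilt", _tilt_matrix(self.phi, self.psi, self.side_sign))

    @property
    def side_sign(self) -> float:
        """+1 for left legs (outward = +y), -1 for right legs."""
        return 1.0 if self.side == "L" else -1.0

    @property
    def total_length(self) -> float:
        return self.len_coxa + self.len_femur + self.len_tibia

    @property
    def limits(self) -> Tuple[Tuple[float, float], ...]:
        return (self.alpha_limits, self.beta_limits, self.gamma_limits)

    def within_limits(self, q: JointAngles, tol: float = 1e-9) -> bool:
        return all(
            lo - tol <= v <= hi + tol
            for v, (lo, hi) in zip(q, self.limits)
        )

    def clip_to_limits(self, q: JointAngles) -> JointAngles:
        return JointAngles(
            *(min(max(v, lo), hi) for v, (lo, hi) in zip(q, self.limits))
        )


def _tilt_matrix(phi: float, psi: float, s: float) -> tuple:
    """Rotation mapping the untilted leg frame into the body frame.

    ``phi`` tilts the thorax-coxa axis in the sagittal plane (rotation about
    body y), ``psi`` tilts it laterally (rotation about body x, mirrored by
    side sign ``s``).  Returned as a tuple-of-tuples for fast scalar access.
    """
    cphi, sphi = math.cos(phi), math.sin(phi)
    cpsi, spsi = math.cos(s * psi), math.sin(s * psi)
    # R = Rx(s*psi) @ Ry(phi)
    return (
        (cphi, 0.0, sphi),
        (spsi * sphi, cpsi, -spsi * cphi),
        (-cpsi * sphi, spsi, cpsi * cphi),
    )


def _fk_local(geom: LegGeometry, q: JointAngles) -> Tuple[float, float, float]:
    """Tarsus position in the untilted leg-local frame (origin at the
    thorax-coxa joint)."""
    a, b, g = q
    s = geom.side_sign
    radial = (
        geom.len_coxa
        + geom.len_femur * math.cos(b)
        + geom.len_tibia * math.cos(b + g)
    )
    vert = geom.len_femur * math.sin(b) + geom.len_tibia * math.sin(b + g)
    return (math.sin(a) * radial, s * math.cos(a) * radial, vert)


def forward_kinematics(geom: LegGeometry, q: JointAngles) -> Tuple[float, float, float]:
    """Tarsus position (m, body frame) for joint angles ``q``.

    Raises ``ValueError`` on non-finite input.  The returned point is always
    within ``geom.total_length`` of the thorax-coxa joint.
    """
    if not all(math.isfinite(v) for v in q):
        raise ValueError("joint angles must be finite")
    p = _fk_local(geom, q)
    R = geom._tilt
    ax, ay, az = geom.attach
    return (
        ax + R[0][0] * p[0] + R[0][1] * p[1] + R[0][2] * p[2],
        ay + R[1][0] * p[0] + R[1][1] * p[1] + R[1][2] * p[2],
        az + R[2][0] * p[0] + R[2][1] * p[1] + R[2][2] * p[2],
    )


def inverse_kinematics(
    geom: LegGeometry,
    target: Sequence[float],
    check_limits: bool = True,
) -> JointAngles:
    """Joint angles placing the tarsus at ``target`` (m, body frame).

    Branch convention: knee-up, i.e. the femur-tibia angle is taken in
    ``[-pi, 0]``.  Raises :class:`OutOfWorkspaceError` (carrying the nearest
    reachable point) when the target lies outside the reachable annulus or,
    if ``check_limits``, outside the joint limits.
    """
    tx, ty, tz = float(target[0]), float(target[1]), float(target[2])
    if not (math.isfinite(tx) and math.isfinite(ty) and math.isfinite(tz)):
        raise ValueError("target must be finite")
    R = geom._tilt
    ax, ay, az = geom.attach
    dx, dy, dz = tx - ax, ty - ay, tz - az
    # local = R^T @ d
    lx = R[0][0] * dx + R[1][0] * dy + R[2][0] * dz
    ly = R[0][1] * dx + R[1][1] * dy + R[2][1] * dz
    lz = R[0][2] * dx + R[1][2] * dy + R[2][2] * dz

    s = geom.side_sign
    r_h = math.hypot(lx, ly)
    alpha = math.atan2(lx, s * ly)
    pr = r_h - geom.len_coxa
    pz = lz
    lf, lt = geom.len_femur, geom.len_tibia
    d2 = pr * pr + pz * pz
    D = (d2 - lf * lf - lt * lt) / (2.0 * lf * lt)
    if D > 1.0 or D < -1.0:
        raise OutOfWorkspaceError(
            f"target at planar distance {math.sqrt(d2):.4f} m outside "
            f"reachable annulus [{abs(lf - lt):.4f}, {lf + lt:.4f}] m",
            _nearest_reachable(geom, alpha, pr, pz),
        )
    gamma = -math.acos(D)  # knee-up branch
    beta = math.atan2(pz, pr) - math.atan2(lt * math.sin(gamma), lf + lt * math.cos(gamma))
    q = JointAngles(alpha, beta, gamma)
    if check_limits and not geom.within_limits(q):
        raise OutOfWorkspaceError(
            f"IK solution {tuple(round(v, 4) for v in q)} violates joint limits",
            forward_kinematics(geom, geom.clip_to_limits(q)),
        )
    return q


def _nearest_reachable(
    geom: LegGeometry, alpha: float, pr: float, pz: float
) -> Tuple[float, float, float]:
    """Closest point on the reachable annulus boundary, same alpha plane."""
    lf, lt = geom.len_femur, geom.len_tibia
    d = math.hypot(pr, pz)
    d_clipped = min(max(d, abs(lf - lt) + 1e-9), lf + lt - 1e-9)
    if d < 1e-12:
        pr_n, pz_n = d_clipped, 0.0
    else:
        pr_n, pz_n = pr * d_clipped / d, pz * d_clipped / d
    r_h = pr_n + geom.len_coxa
    s = geom.side_sign
    p_local = (math.sin(alpha) * r_h, s * math.cos(alpha) * r_h, pz_n)
    R = geom._tilt
    ax, ay, az = geom.attach
    return (
        ax + R[0][0] * p_local[0] + R[0][1] * p_local[1] + R[0][2] * p_local[2],
        ay + R[1][0] * p_local[0] + R[1][1] * p_local[1] + R[1][2] * p_local[2],
        az + R[2][0] * p_local[0] + R[2][1] * p_local[1] + R[2][2] * p_local[2],
    )


def in_workspace(geom: LegGeometry, point: Sequence[float]) -> bool:
    """True iff :func:`inverse_kinematics` would succeed for ``point``
    under the configured joint limits."""
    try:
        inverse_kinematics(geom, point)
        return True
    except OutOfWorkspaceError:
        return False


def jacobian(geom: LegGeometry, q: JointAngles, eps: float = 1e-7) -> np.ndarray:
    """3x3 geometric Jacobian d(tarsus)/d(q), by central differences.

    Used only for task-space overrides (levator reflex); the nominal control
    loops work in joint space or through IK.
    """
    J = np.empty((3, 3))
    for j in range(3):
        qp = list(q)
        qm = list(q)
        qp[j] += eps
        qm[j] -= eps
        pp = forward_kinematics(geom, JointAngles(*qp))
        pm = forward_kinematics(geom, JointAngles(*qm))
        J[:, j] = [(a - b) / (2 * eps) for a, b in zip(pp, pm)]
    return J
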