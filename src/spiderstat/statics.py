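"""Static reduction of cord tensions and gravity to COG and foot reactions.

All belt-routed cord forces are summed into a single resultant at the
centre of gravity (COG).  Its vertical component divided by body weight
is the *unweighting fraction*: positive values mean the cords carry part
of the weight, negative values mean they press the patient down.  The
remaining load is partitioned between the two foot-ground contact (FGC)
points by rigid-body statics:

* vertical reactions solve force balance plus the lateral (about the
  anterior X axis) moment balance about the COG's vertical projection —
  a 2x2 linear system in (left_z, right_z); the fore-aft moment is taken
  up by the extent of the foot itself, which is what the heel/toe
  classification describes;
* the net horizontal cord force is reacted at the feet as friction,
  split in proportion to each foot's vertical load, which preserves both
  equilibrium and left/right symmetry.

When the cords carry the full body weight or more the feet leave the
ground: reactions are zero and a lift-off flag is raised (unilateral
contact cannot pull).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .cage_geometry import CordState, Subject
from .errors import InvalidInputError, PerturbationRangeWarning, TandemStanceWarning

__all__ = [
    "GRAVITY",
    "Force3",
    "Stance",
    "LoadSummary",
    "resolve_cog",
    "foot_reactions",
    "classify_foot_load",
    "perturb_tension",
    "summarize",
]

#: Gravitational acceleration, m/s^2.
GRAVITY = 9.81

#: Forces smaller than this (N) classify as neutral rather than signed.
NEUTRAL_TOL = 1e-9

HeelState = Literal["unweighted", "loaded", "neutral"]
ToeState = Literal["load_toward", "load_away", "neutral"]


@dataclass(frozen=True)
class Force3:
    """A force vector in the cage frame, newtons (Z up positive)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise InvalidInputError("force components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @classmethod
    def from_array(cls, v) -> "Force3":
        return cls(float(v[0]), float(v[1]), float(v[2]))


@dataclass(frozen=True)
class Stance:
    """Foot positions on the floor, metres, in the transverse plane.

    ``left`` / ``right`` are (x, y) pairs; either may be ``None`` for a
    single-foot stance, in which case that foot carries everything.
    """

    left: tuple[float, float] | None
    right: tuple[float, float] | None

    def __post_init__(self):
        if self.left is None and self.right is None:
            raise InvalidInputError("at least one foot must be in contact")

    @classmethod
    def symmetric(cls, width: float = 0.30) -> "Stance":
        """Feet side by side, ``width`` metres apart, centred on the origin."""
        half = width / 2.0
        return cls(left=(0.0, half), right=(0.0, -half))


@dataclass(frozen=True)
class LoadSummary:
    """Everything the therapist reads off one simulated configuration."""

    cog_resultant: Force3
    unweighting_fraction: float
    left_foot: Force3
    right_foot: Force3
    lift_off: bool
    left_heel: HeelState
    left_toe: ToeState
    right_heel: HeelState
    right_toe: ToeState


def resolve_cog(
    subject: Subject, states: Sequence[CordState]
) -> tuple[Force3, float]:
    """Sum all cord forces at the COG and express the vertical part as
    a fraction of body weight.

    Returns ``(cog_resultant, unweighting_fraction)``.  The fraction is
    positive when the cords relieve the body, negative when they load it.
    """
    if not states:
        raise InvalidInputError("resolve_cog needs at least one cord state")
    total = np.zeros(3)
    for s in states:
        total = total + s.force
    fraction = float(total[2] / (subject.mass * GRAVITY))
    return Force3.from_array(total), fraction


def foot_reactions(
    subject: Subject,
    cog_resultant: Force3,
    stance: Stance,
    cog_xy: tuple[float, float] = (0.0, 0.0),
) -> tuple[Force3, Force3, bool]:
    """Partition the residual load between the two FGC points.

    Returns ``(left, right, lift_off)``.  With both feet down, vertical
    reactions come from the 2x2 force/lateral-moment solve described in
    the module docstring; horizontal reactions oppose the net horizontal
    cord force in proportion to vertical load.  If the cords carry the
    whole weight (or more) both reactions are zero and ``lift_off`` is
    True.
    """
    F = cog_resultant.as_array()
    net_vertical = subject.mass * GRAVITY - F[2]

    zero = Force3(0.0, 0.0, 0.0)
    if net_vertical <= NEUTRAL_TOL:
        return zero, zero, True

    if stance.left is None or stance.right is None:
        foot = Force3(-F[0], -F[1], net_vertical)
        if stance.left is None:
            return zero, foot, False
        return foot, zero, False

    yl = stance.left[1] - cog_xy[1]
    yr = stance.right[1] - cog_xy[1]
    # Lateral moment of the horizontal cord pull at COG height about the
    # floor-level COG projection: h * Fy must be matched by the vertical
    # reactions' moments yl*Lz + yr*Rz.
    m_lat = subject.cog_height * F[1]
    if yl == yr:
        warnings.warn(
            "feet are laterally coincident; splitting vertical load evenly",
            TandemStanceWarning,
            stacklevel=2,
        )
        lz = rz = net_vertical / 2.0
    else:
        # Closed-form 2x2 solve of lz + rz = W', yl*lz + yr*rz = m_lat,
        # written so that mirroring the scenario through the sagittal
        # plane swaps lz/rz bit-exactly (negation is exact in IEEE-754).
        lz = (m_lat - yr * net_vertical) / (yl - yr)
        rz = (m_lat - yl * net_vertical) / (yr - yl)
    wl = lz / net_vertical
    wr = rz / net_vertical
    left = Force3(-F[0] * wl, -F[1] * wl, float(lz))
    right = Force3(-F[0] * wr, -F[1] * wr, float(rz))
    return left, right, False


def classify_foot_load(
    cord_imposed: Force3, tol: float = NEUTRAL_TOL
) -> tuple[HeelState, ToeState]:
    """Read the heel/toe effect off the cord-imposed force at one foot.

    The argument is the force the cord set effectively transmits to the
    foot (the change it causes relative to standing free).  A positive Z
    unweights the heel, negative loads it; positive Y moves load toward
    the toe mound, negative away.  Components within ``tol`` of zero are
    neutral.
    """
    if cord_imposed.z > tol:
        heel: HeelState = "unweighted"
    elif cord_imposed.z < -tol:
        heel = "loaded"
    else:
        heel = "neutral"
    if cord_imposed.y > tol:
        toe: ToeState = "load_toward"
    elif cord_imposed.y < -tol:
        toe = "load_away"
    else:
        toe = "neutral"
    return heel, toe


def perturb_tension(
    states: Sequence[CordState], factor: float
) -> list[CordState]:
    """Scale every cord tension by ``factor``, geometry untouched.

    Therapists routinely raise or lower cord tension by 10-20 % around a
    working configuration; factors outside [0.8, 1.2] are accepted with a
    warning.  Downstream unweighting scales linearly by the same factor.
    """
    if factor < 0:
        raise InvalidInputError("perturbation factor must be non-negative")
    if not (0.8 <= factor <= 1.2):
        warnings.warn(
            f"perturbation factor {factor:g} is outside the usual 0.8-1.2 band",
            PerturbationRangeWarning,
            stacklevel=2,
        )
    return [replace(s, tension=s.tension * factor) for s in states]


def summarize(
    subject: Subject, states: Sequence[CordState], stance: Stance
) -> LoadSummary:
    """Full static analysis of one configuration.

    Heel/toe states are classified from the cord-imposed force at each
    foot: the baseline reaction of the cord-free stance minus the actual
    reaction, i.e. the load change the cords cause at that foot.
    """
    cog_res, fraction = resolve_cog(subject, states)
    left, right, lift_off = foot_reactions(subject, cog_res, stance)
    base_left, base_right, _ = foot_reactions(
        subject, Force3(0.0, 0.0, 0.0), stance
    )
    imp_left = Force3.from_array(base_left.as_array() - left.as_array())
    imp_right = Force3.from_array(base_right.as_array() - right.as_array())
    lh, lt = classify_foot_load(imp_left)
    rh, rt = classify_foot_load(imp_right)
    return LoadSummary(
        cog_resultant=cog_res,
        unweighting_fraction=fraction,
        left_foot=left,
        right_foot=right,
        lift_off=lift_off,
        left_heel=lh,
        left_toe=lt,
        right_heel=rh,
        right_toe=rt,
    )
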