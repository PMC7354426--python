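"""Inverse configuration solving.

Given a prescribed unweighting (or loading, if negative) fraction, find
the cord setting that produces it.  The forward map — unweighting as a
function of the shared free variable — is required to be strictly
monotone on the solve bracket (it is on a cord's working range), so a
derivative-free bracketing root-finder (Brent) is both robust to the
slight wiggle of the sum-of-sines model and guaranteed unique.

Two free variables are supported, one at a time:

``elongation``
    All cords share one elongation percent; angles and azimuths fixed.
``anchor_height``
    All anchors share one height above the COG plane; each cord keeps a
    fixed horizontal radius from its belt point, so raising the anchors
    changes both the COG-level angle and the elongation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .cage_geometry import Subject
from .cord_model import CordCharacteristic, tension, working_range
from .errors import InfeasibleTargetError, InvalidInputError
from .statics import GRAVITY

__all__ = ["PlannedCord", "PlanRequest", "PlanResult", "solve_configuration"]

#: Root-finder tolerance on the free variable (percent elongation or metres).
SOLVE_XTOL = 1e-9


@dataclass(frozen=True)
class PlannedCord:
    """One cord of the set being planned.

    ``cog_level_angle`` (degrees) is used by the ``elongation`` solve;
    ``horizontal_radius`` (metres, belt point to the anchor's vertical
    line) is used by the ``anchor_height`` solve.
    """

    characteristic: CordCharacteristic
    cog_level_angle: float = 0.0
    azimuth: float = 0.0
    horizontal_radius: float | None = None


@dataclass(frozen=True)
class PlanRequest:
    subject: Subject
    target_unweighting: float
    cords: tuple[PlannedCord, ...]
    free: Literal["elongation", "anchor_height"] = "elongation"

    def __post_init__(self):
        if abs(self.target_unweighting) > 1.0:
            raise InvalidInputError(
                "|target_unweighting| cannot exceed 1 (100% of body weight)"
            )
        if not self.cords:
            raise InvalidInputError("at least one cord is required")
        object.__setattr__(self, "cords", tuple(self.cords))


@dataclass(frozen=True)
class PlanResult:
    free: str
    #: Solved value of the free variable: elongation % or anchor height (m,
    #: above the COG plane).
    value: float
    #: Per-cord elongation percents of the solved configuration.
    elongations_pct: tuple[float, ...]
    #: Forward-simulated unweighting of the returned configuration.
    achieved_unweighting: float


def _forward_elongation(request: PlanRequest, elong: float) -> float:
    w = request.subject.mass * GRAVITY
    return (
        sum(
            tension(c.characteristic, elong) * math.sin(math.radians(c.cog_level_angle))
            for c in request.cords
        )
        / w
    )


def _cord_at_height(c: PlannedCord, h: float) -> tuple[float, float]:
    """(elongation_pct, sin of COG-level angle) for anchors at height h."""
    r = c.horizontal_radius
    L = math.hypot(r, h)
    rest = c.characteristic.spec.rest_length
    elong = max(0.0, 100.0 * (L - rest) / rest)
    return elong, (h / L if L > 0 else 0.0)


def _forward_height(request: PlanRequest, h: float) -> float:
    w = request.subject.mass * GRAVITY
    total = 0.0
    for c in request.cords:
        elong, sin_th = _cord_at_height(c, h)
        total += tension(c.characteristic, elong) * sin_th
    return total / w


def _check_monotone(f, lo: float, hi: float, n: int = 241) -> None:
    xs = np.linspace(lo, hi, n)
    ys = np.array([f(x) for x in xs])
    d = np.diff(ys)
    if not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
        raise InvalidInputError(
            "forward map is not monotone on the solve bracket; "
            "restrict the cords to their working range"
        )


def _solve_bracket(f, target: float, lo: float, hi: float) -> float:
    f_lo, f_hi = f(lo), f(hi)
    a, b = sorted((f_lo, f_hi))
    if not (a <= target <= b):
        raise InfeasibleTargetError(target, (a, b))
    _check_monotone(f, lo, hi)
    return float(brentq(lambda x: f(x) - target, lo, hi, xtol=SOLVE_XTOL))


def solve_configuration(request: PlanRequest) -> PlanResult:
    """Solve for the free variable that meets the unweighting target.

    Forward-simulating the returned configuration reproduces the target
    to well within 1e-6.  An unreachable target raises
    :class:`InfeasibleTargetError` carrying the achievable interval.
    """
    if request.free == "elongation":
        if request.target_unweighting == 0.0:
            elong = 0.0
        else:
            f = lambda e: _forward_elongation(request, e)
            hi = min(
                working_range(c.characteristic)[1] for c in request.cords
            )
            elong = _solve_bracket(f, request.target_unweighting, 0.0, hi)
        return PlanResult(
            free="elongation",
            value=elong,
            elongations_pct=tuple(elong for _ in request.cords),
            achieved_unweighting=_forward_elongation(request, elong),
        )

    if request.free == "anchor_height":
        if any(c.horizontal_radius is None or c.horizontal_radius <= 0
               for c in request.cords):
            raise InvalidInputError(
                "anchor_height solving needs a positive horizontal_radius "
                "for every cord"
            )
        f = lambda h: _forward_height(request, h)
        # Highest anchor at which every cord stays within its 0-100% domain.
        h_max = min(
            math.sqrt(
                max(
                    (2.0 * c.characteristic.spec.rest_length) ** 2
                    - c.horizontal_radius**2,
                    0.0,
                )
            )
            for c in request.cords
        )
        if h_max <= 0:
            raise InvalidInputError(
                "horizontal radius leaves no headroom below 100% elongation"
            )
        lo = -h_max if request.target_unweighting < 0 else 0.0
        hi = 0.0 if request.target_unweighting < 0 else h_max
        h = (
            0.0
            if request.target_unweighting == 0.0
            else _solve_bracket(f, request.target_unweighting, lo, hi)
        )
        elongs = tuple(_cord_at_height(c, h)[0] for c in request.cords)
        return PlanResult(
            free="anchor_height",
            value=h,
            elongations_pct=elongs,
            achieved_unweighting=f(h),
        )

    raise InvalidInputError(f"unknown free variable {request.free!r}")
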