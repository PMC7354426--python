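"""Cord geometry in the anatomical cage frame.

Frame convention (right-handed): Z vertical, up positive; X anterior
(the direction the subject faces); Y mediolateral, subject's left
positive.  The origin sits on the floor at the midpoint between the two
feet, so the frontal plane is YZ and the transverse plane is the
horizontal plane through the body's centre of gravity (COG).

All belt-routed cord action is reduced to the COG: the waist belt is
modelled as a single point per cord at COG height.  Each installed cord
is summarised by a :class:`CordState` — unit direction (belt to anchor),
stretched length, elongation, tension, and the *COG-level angle*: the
elevation of the cord above the transverse plane, positive when the
anchor is higher than the belt (unloading), negative when lower
(loading).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cord_model import CordCharacteristic, elongation_pct as _elongation_pct, tension as _tension
from .errors import (
    AmbiguousAzimuthError,
    DegenerateGeometryError,
    InvalidInputError,
)

__all__ = [
    "Subject",
    "CordAttachment",
    "CordState",
    "cord_state",
    "loading_mode",
    "attachment_from_polar",
    "estimate_cog_height",
    "MAX_MASS_KG",
    "UTILITY_RANGE_KG",
    "COG_HEIGHT_FRACTION",
]

#: Hard device limit on subject mass, kg.
MAX_MASS_KG = 110.0

#: The mass band the device is really sized for, kg (advisory only).
UTILITY_RANGE_KG = (70.0, 80.0)

#: Default COG-height-to-stature fractions when COG height is unmeasured.
COG_HEIGHT_FRACTION = {"adult": 0.56, "child": 0.58}


@dataclass(frozen=True)
class Subject:
    """Anthropometrics: mass (kg), stature (m), COG height above floor (m).

    Mass above the 110 kg device limit is a hard error.  Mass outside the
    70-80 kg utility band is legitimate (children train in the cage too);
    :meth:`advisories` reports it for display rather than warning.
    """

    mass: float
    height: float
    cog_height: float

    def __post_init__(self):
        if not self.mass > 0:
            raise InvalidInputError("mass must be positive")
        if self.mass > MAX_MASS_KG:
            raise InvalidInputError(
                f"mass {self.mass} kg exceeds the {MAX_MASS_KG:.0f} kg device limit"
            )
        if not self.height > 0:
            raise InvalidInputError("height must be positive")
        if not (0 < self.cog_height < self.height):
            raise InvalidInputError(
                "cog_height must lie strictly between 0 and height"
            )

    def advisories(self) -> list[str]:
        lo, hi = UTILITY_RANGE_KG
        if not (lo <= self.mass <= hi):
            return [
                f"subject mass {self.mass:g} kg is outside the device's "
                f"{lo:.0f}-{hi:.0f} kg utility range"
            ]
        return []


@dataclass(frozen=True)
class CordAttachment:
    """One installed cord: characteristic plus anchor and belt points (m)."""

    characteristic: CordCharacteristic
    anchor: tuple[float, float, float]
    belt: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "anchor", tuple(float(v) for v in self.anchor))
        object.__setattr__(self, "belt", tuple(float(v) for v in self.belt))


@dataclass(frozen=True)
class CordState:
    """Resolved geometry and tension of one installed cord."""

    direction: tuple[float, float, float]
    stretched_length: float
    elongation_pct: float
    cog_level_angle: float
    tension: float

    @property
    def force(self) -> np.ndarray:
        """Force the cord applies at the belt, N (pulls toward the anchor)."""
        return self.tension * np.asarray(self.direction)


def cord_state(attachment: CordAttachment) -> CordState:
    """Resolve an anchor/belt pair into direction, elongation and tension."""
    anchor = np.asarray(attachment.anchor, dtype=float)
    belt = np.asarray(attachment.belt, dtype=float)
    v = anchor - belt
    length = float(np.linalg.norm(v))
    if length == 0.0:
        raise DegenerateGeometryError("anchor coincides with the belt point")
    direction = v / length
    char = attachment.characteristic
    elong = _elongation_pct(char.spec, length)
    angle = math.degrees(math.asin(max(-1.0, min(1.0, float(direction[2])))))
    t = _tension(char, elong)
    return CordState(
        direction=tuple(direction),
        stretched_length=length,
        elongation_pct=elong,
        cog_level_angle=angle,
        tension=t,
    )


def loading_mode(state: CordState) -> Literal["unload", "load", "neutral"]:
    """Classify a cord by its anchor height relative to the waist belt.

    An anchor above the transverse plane unloads (supports) the patient;
    below it loads them; exactly level is neutral.
    """
    if state.cog_level_angle > 0:
        return "unload"
    if state.cog_level_angle < 0:
        return "load"
    return "neutral"


def attachment_from_polar(
    subject: Subject,
    cog_level_angle: float,
    elongation_pct: float,
    azimuth: float,
    characteristic: CordCharacteristic,
    belt_xy: tuple[float, float] = (0.0, 0.0),
) -> CordAttachment:
    """Reconstruct an anchor point from angle + elongation + azimuth.

    Setups are most naturally described per cord by the COG-level angle
    (degrees above the transverse plane), the elongation (percent of rest
    length) and an azimuth in the transverse plane measured from +X
    (anterior) toward +Y (subject's left).  The anchor is placed at
    distance ``rest_length * (1 + elongation/100)`` from the belt point
    along that direction; feeding the result to :func:`cord_state`
    recovers the same angle and elongation.
    """
    if not (-90.0 < cog_level_angle < 90.0):
        raise AmbiguousAzimuthError(
            "a vertical cord (|angle| >= 90 deg) has no defined azimuth"
        )
    if elongation_pct < 0:
        raise InvalidInputError("elongation_pct must be >= 0")
    rest = characteristic.spec.rest_length
    length = rest * (1.0 + elongation_pct / 100.0)
    th = math.radians(cog_level_angle)
    az = math.radians(azimuth)
    direction = np.array(
        [math.cos(th) * math.cos(az), math.cos(th) * math.sin(az), math.sin(th)]
    )
    belt = np.array([belt_xy[0], belt_xy[1], subject.cog_height])
    anchor = belt + length * direction
    return CordAttachment(
        characteristic=characteristic, anchor=tuple(anchor), belt=tuple(belt)
    )


def estimate_cog_height(
    height: float, age_class: Literal["adult", "child"] = "adult"
) -> float:
    """Estimate COG height from stature when it was not measured directly.

    Uses a fixed fraction of stature (0.56 adult, 0.58 young child).
    Direct measurement of the COG-to-floor distance is preferred; this
    helper only fills the gap.
    """
    if not height > 0:
        raise InvalidInputError("height must be positive")
    try:
        frac = COG_HEIGHT_FRACTION[age_class]
    except KeyError:
        raise InvalidInputError(
            f"unknown age class {age_class!r}; expected 'adult' or 'child'"
        ) from None
    return frac * height
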