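"""Scenario files: schema-validated YAML configs and tabular outputs.

A scenario bundles everything one simulation needs: the subject, the
cord set (each cord in polar form — COG-level angle, elongation, azimuth
— or Cartesian form — anchor and belt points), and the stance.  Units
are explicit in every key name (``_kg``, ``_m``, ``_mm``, ``_deg``);
unknown keys are rejected with the offending field path.

Example::

    subject: {mass_kg: 75, height_m: 1.75, cog_height_m: 0.98}
    cords:
      - kind: thick
        characteristic: reference_adult_thick
        cog_level_angle_deg: 45
        elongation_mm: 250
        azimuth_deg: 45
    stance: {width_m: 0.30}

``characteristic`` is either a packaged reference name or a path to a
characteristic JSON, resolved relative to the scenario file.  Cords
without an explicit ``azimuth_deg`` get the default symmetric layout
45, 135, 225, 315 degrees in listing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cage_geometry import (
    CordAttachment,
    CordState,
    Subject,
    attachment_from_polar,
    cord_state,
    estimate_cog_height,
    loading_mode,
)
from .cord_model import CordCharacteristic, CordSpec
from .errors import SchemaError
from .fixtures import REFERENCE_NAMES, reference_characteristic
from .statics import LoadSummary, Stance, summarize

__all__ = [
    "Scenario",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "write_scenario",
    "simulate_scenario",
    "force_table",
    "summary_dict",
    "format_summary",
    "packaged_scenario_path",
    "DEFAULT_AZIMUTHS_DEG",
]

#: Default cord azimuths (degrees from anterior toward subject's left),
#: symmetric about both the sagittal and the frontal plane.
DEFAULT_AZIMUTHS_DEG = (45.0, 135.0, 225.0, 315.0)


@dataclass(frozen=True)
class Scenario:
    """A subject, an installed cord set, and a stance."""

    subject: Subject
    attachments: tuple[CordAttachment, ...]
    stance: Stance
    #: The raw config dict this scenario was built from (for round-trips).
    config: dict

    @property
    def states(self) -> tuple[CordState, ...]:
        return tuple(cord_state(a) for a in self.attachments)


def _require(block: dict, path: str, allowed: set[str], required: set[str]):
    if not isinstance(block, dict):
        raise SchemaError(path, f"expected a mapping, got {type(block).__name__}")
    unknown = set(block) - allowed
    if unknown:
        raise SchemaError(f"{path}.{sorted(unknown)[0]}", "unknown key")
    missing = required - set(block)
    if missing:
        raise SchemaError(f"{path}.{sorted(missing)[0]}", "required key missing")


def _number(block: dict, path: str, key: str, default=None):
    if key not in block:
        return default
    v = block[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{path}.{key}", f"expected a number, got {v!r}")
    return float(v)


def _resolve_characteristic(
    name: str, kind: str, rest_length_m: float | None, base_dir: Path
) -> CordCharacteristic:
    if name in REFERENCE_NAMES:
        char = reference_characteristic(name)
    else:
        p = Path(name)
        if not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise SchemaError(
                "cords.characteristic",
                f"{name!r} is neither a packaged reference "
                f"({', '.join(REFERENCE_NAMES)}) nor an existing file",
            )
        char = CordCharacteristic.load(p)
    if char.spec.kind != kind:
        raise SchemaError(
            "cords.kind",
            f"scenario says {kind!r} but characteristic is {char.spec.kind!r}",
        )
    if rest_length_m is not None and rest_length_m != char.spec.rest_length:
        char = CordCharacteristic(
            spec=CordSpec(kind=kind, rest_length=rest_length_m),
            terms=char.terms,
            domain=char.domain,
            r_squared=char.r_squared,
        )
    return char


def scenario_from_dict(config: dict, base_dir: Path | str = ".") -> Scenario:
    """Validate a config mapping and build a :class:`Scenario`."""
    base_dir = Path(base_dir)
    _require(config, "scenario", {"subject", "cords", "stance"}, {"subject", "cords"})

    sb = config["subject"]
    _require(
        sb, "subject",
        {"mass_kg", "height_m", "cog_height_m", "age_class"},
        {"mass_kg", "height_m"},
    )
    age_class = sb.get("age_class", "adult")
    if age_class not in ("adult", "child"):
        raise SchemaError("subject.age_class", f"expected adult|child, got {age_class!r}")
    height = _number(sb, "subject", "height_m")
    cog_h = _number(sb, "subject", "cog_height_m")
    if cog_h is None:
        cog_h = estimate_cog_height(height, age_class)
    subject = Subject(
        mass=_number(sb, "subject", "mass_kg"), height=height, cog_height=cog_h
    )

    cords_cfg = config["cords"]
    if not isinstance(cords_cfg, list) or not cords_cfg:
        raise SchemaError("cords", "expected a non-empty list")
    attachments = []
    for i, cb in enumerate(cords_cfg):
        path = f"cords[{i}]"
        _require(
            cb, path,
            {
                "kind", "characteristic", "rest_length_m",
                "cog_level_angle_deg", "elongation_mm", "elongation_pct",
                "azimuth_deg", "anchor_m", "belt_m",
            },
            {"kind", "characteristic"},
        )
        char = _resolve_characteristic(
            cb["characteristic"], cb["kind"], _number(cb, path, "rest_length_m"),
            base_dir,
        )
        polar = "cog_level_angle_deg" in cb
        cartesian = "anchor_m" in cb
        if polar == cartesian:
            raise SchemaError(
                path,
                "give either cog_level_angle_deg (+elongation) or anchor_m, "
                "not both or neither",
            )
        if polar:
            e_mm = _number(cb, path, "elongation_mm")
            e_pct = _number(cb, path, "elongation_pct")
            if (e_mm is None) == (e_pct is None):
                raise SchemaError(
                    path, "give exactly one of elongation_mm or elongation_pct"
                )
            if e_pct is None:
                e_pct = 100.0 * (e_mm / 1000.0) / char.spec.rest_length
            az = _number(cb, path, "azimuth_deg")
            if az is None:
                az = DEFAULT_AZIMUTHS_DEG[i % len(DEFAULT_AZIMUTHS_DEG)]
            attachments.append(
                attachment_from_polar(
                    subject,
                    cog_level_angle=_number(cb, path, "cog_level_angle_deg"),
                    elongation_pct=e_pct,
                    azimuth=az,
                    characteristic=char,
                )
            )
        else:
            anchor = cb["anchor_m"]
            belt = cb.get("belt_m", [0.0, 0.0, subject.cog_height])
            for key, val in (("anchor_m", anchor), ("belt_m", belt)):
                if not (isinstance(val, (list, tuple)) and len(val) == 3):
                    raise SchemaError(f"{path}.{key}", "expected [x, y, z] metres")
            attachments.append(
                CordAttachment(
                    characteristic=char, anchor=tuple(anchor), belt=tuple(belt)
                )
            )

    st = config.get("stance", {"width_m": 0.30})
    _require(st, "stance", {"width_m", "left_m", "right_m"}, set())
    if "left_m" in st or "right_m" in st:
        if "width_m" in st:
            raise SchemaError("stance.width_m", "give width_m or foot points, not both")

        def _foot(key):
            if key not in st or st[key] is None:
                return None
            v = st[key]
            if not (isinstance(v, (list, tuple)) and len(v) == 2):
                raise SchemaError(f"stance.{key}", "expected [x, y] metres or null")
            return (float(v[0]), float(v[1]))

        stance = Stance(left=_foot("left_m"), right=_foot("right_m"))
    else:
        stance = Stance.symmetric(_number(st, "stance", "width_m", 0.30))

    return Scenario(
        subject=subject, attachments=tuple(attachments), stance=stance,
        config=config,
    )


def load_scenario(path) -> Scenario:
    """Read and validate a scenario YAML file."""
    path = Path(path)
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise SchemaError("scenario", "file does not contain a mapping")
    return scenario_from_dict(config, base_dir=path.parent)


def scenario_to_dict(scenario: Scenario) -> dict:
    return scenario.config


def write_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.config, sort_keys=False))


def packaged_scenario_path(name: str) -> Path:
    """Path of a packaged example scenario by bare name (no suffix)."""
    from importlib import resources

    p = resources.files("spiderstat").joinpath(f"data/scenarios/{name}.yaml")
    return Path(str(p))


def simulate_scenario(scenario: Scenario) -> LoadSummary:
    """Resolve every cord and run the full static analysis."""
    return summarize(scenario.subject, scenario.states, scenario.stance)


def force_table(scenario: Scenario, summary: LoadSummary) -> pd.DataFrame:
    """Per-cord and per-point force components as a tidy table.

    Columns: ``point`` (cord_1..n, cog_resultant, left_foot, right_foot),
    ``fx_N``, ``fy_N``, ``fz_N``, plus per-cord geometry columns
    (``tension_N``, ``elongation_pct``, ``cog_level_angle_deg``,
    ``loading_mode``).
    """
    rows = []
    for i, s in enumerate(scenario.states, start=1):
        f = s.force
        rows.append(
            {
                "point": f"cord_{i}",
                "fx_N": f[0], "fy_N": f[1], "fz_N": f[2],
                "tension_N": s.tension,
                "elongation_pct": s.elongation_pct,
                "cog_level_angle_deg": s.cog_level_angle,
                "loading_mode": loading_mode(s),
            }
        )
    for label, f in (
        ("cog_resultant", summary.cog_resultant),
        ("left_foot", summary.left_foot),
        ("right_foot", summary.right_foot),
    ):
        rows.append({"point": label, "fx_N": f.x, "fy_N": f.y, "fz_N": f.z})
    return pd.DataFrame(rows)


def summary_dict(scenario: Scenario, summary: LoadSummary) -> dict:
    """JSON-ready summary of one simulation."""
    return {
        "subject": {
            "mass_kg": scenario.subject.mass,
            "height_m": scenario.subject.height,
            "cog_height_m": scenario.subject.cog_height,
        },
        "unweighting_pct": 100.0 * summary.unweighting_fraction,
        "lift_off": summary.lift_off,
        "cog_resultant_N": [
            summary.cog_resultant.x, summary.cog_resultant.y, summary.cog_resultant.z,
        ],
        "left_foot_N": [summary.left_foot.x, summary.left_foot.y, summary.left_foot.z],
        "right_foot_N": [
            summary.right_foot.x, summary.right_foot.y, summary.right_foot.z,
        ],
        "left_heel": summary.left_heel,
        "left_toe": summary.left_toe,
        "right_heel": summary.right_heel,
        "right_toe": summary.right_toe,
        "advisories": scenario.subject.advisories(),
    }


def format_summary(scenario: Scenario, summary: LoadSummary) -> str:
    """Human-readable report for the terminal."""
    s = summary
    verb = "unweighted" if s.unweighting_fraction >= 0 else "loaded"
    lines = [
        f"Subject: {scenario.subject.mass:g} kg, "
        f"COG height {scenario.subject.cog_height:.3f} m",
        f"Cords: {len(scenario.attachments)}",
        f"Body {verb} by {abs(s.unweighting_fraction) * 100:.1f}% of body weight",
    ]
    if s.lift_off:
        lines.append("LIFT-OFF: cords carry the full body weight; feet unloaded")
    lines += [
        f"COG resultant [N]: x={s.cog_resultant.x:+.2f} "
        f"y={s.cog_resultant.y:+.2f} z={s.cog_resultant.z:+.2f}",
        f"Left foot  [N]: x={s.left_foot.x:+.2f} y={s.left_foot.y:+.2f} "
        f"z={s.left_foot.z:+.2f}  heel={s.left_heel} toe={s.left_toe}",
        f"Right foot [N]: x={s.right_foot.x:+.2f} y={s.right_foot.y:+.2f} "
        f"z={s.right_foot.z:+.2f}  heel={s.right_heel} toe={s.right_toe}",
    ]
    for a in scenario.subject.advisories():
        lines.append(f"note: {a}")
    return "\n".join(lines)
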