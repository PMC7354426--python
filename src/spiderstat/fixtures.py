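"""Synthetic bench data and packaged reference characteristics.

No cord force tables are published for the physical device, so the
package carries two substitutes that make every other module testable:

* a seeded synthetic bench generator that emulates the dynamometer
  protocol — a cord stretched step by step over 0-100 % elongation with
  the force read at each step — using a smooth, strictly increasing,
  saturating ground-truth curve with multiplicative Gaussian noise;

* two packaged *reference characteristics* (JSON), produced by fitting
  the 3-term sum-of-sines model to noiseless synthetic bench curves.
  These are calibrated constructions, not measurements: each ground
  truth is anchored so that the standard four-cord worked configurations
  (75 kg adult, 45 deg, 250 mm elongation; 12 kg child, 10 deg, 100 mm)
  reproduce their published 15 % and 16 % unweighting figures.

The ground-truth family is a stretched exponential saturation

    F(x) = F_sat * (1 - exp(-(x / scale)^p)),

strictly increasing on [0, 100] with F(0) = 0; ``p`` > 1 gives a soft
toe region, ``scale`` sets where the curve bends over, ``F_sat`` the
asymptotic force.  The anchor calibration solves ``scale`` in closed
form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .cord_model import (
    BenchMeasurement,
    CordCharacteristic,
    CordSpec,
    FitResult,
    fit_sum_of_sines,
)
from .errors import InvalidInputError
from .statics import GRAVITY

__all__ = [
    "SyntheticCordSpec",
    "generate_bench",
    "thin_bench_spec",
    "thick_bench_spec",
    "reference_characteristic",
    "build_reference",
    "REFERENCE_NAMES",
]

#: Default bench grid: 21 points, every 5 % of elongation.
DEFAULT_GRID = tuple(float(x) for x in range(0, 101, 5))


@dataclass(frozen=True)
class SyntheticCordSpec:
    """Parameters of one synthetic bench session.

    ``saturation_n`` is the asymptotic force (N); ``scale_pct`` the
    elongation scale at which the curve bends toward saturation;
    ``toe_exponent`` (>= 1) softens the initial toe region; ``noise_cv``
    is the coefficient of variation of the multiplicative reading noise.
    """

    cord: CordSpec
    saturation_n: float
    scale_pct: float
    toe_exponent: float = 1.1
    noise_cv: float = 0.0
    grid: tuple[float, ...] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self):
        if not self.saturation_n > 0:
            raise InvalidInputError("saturation_n must be positive")
        if not self.scale_pct > 0:
            raise InvalidInputError("scale_pct must be positive")
        if not self.toe_exponent >= 1:
            raise InvalidInputError("toe_exponent must be >= 1")
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))

    def ground_truth(self, x) -> np.ndarray:
        """Noise-free tension curve, N, strictly increasing, F(0)=0."""
        x = np.asarray(x, dtype=float)
        return self.saturation_n * (
            1.0 - np.exp(-((x / self.scale_pct) ** self.toe_exponent))
        )

    @classmethod
    def calibrated(
        cls,
        cord: CordSpec,
        anchor_elongation_pct: float,
        anchor_force_n: float,
        saturation_n: float,
        toe_exponent: float = 1.1,
        **kwargs,
    ) -> "SyntheticCordSpec":
        """Construct a spec whose curve passes through the given anchor.

        Solves ``scale_pct`` in closed form from
        ``F(anchor) = anchor_force``; the anchor force must lie below the
        saturation level.
        """
        if not 0 < anchor_force_n < saturation_n:
            raise InvalidInputError(
                "anchor force must lie strictly between 0 and saturation_n"
            )
        u = -math.log(1.0 - anchor_force_n / saturation_n)
        scale = anchor_elongation_pct / u ** (1.0 / toe_exponent)
        return cls(
            cord=cord,
            saturation_n=saturation_n,
            scale_pct=scale,
            toe_exponent=toe_exponent,
            **kwargs,
        )


def generate_bench(spec: SyntheticCordSpec) -> list[BenchMeasurement]:
    """Simulate one bench session: ground truth times (1 + noise), floored at 0.

    Deterministic for a fixed spec (the seed is part of the spec).
    """
    if not spec.grid:
        raise InvalidInputError("bench grid is empty")
    x = np.asarray(spec.grid)
    truth = spec.ground_truth(x)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_cv, size=x.size)
    forces = np.maximum(truth * (1.0 + eps), 0.0)
    return [
        BenchMeasurement(elongation_pct=float(xi), force=float(fi))
        for xi, fi in zip(x, forces)
    ]


# ---------------------------------------------------------------------------
# Reference characteristics
# ---------------------------------------------------------------------------

def _adult_thick_recipe() -> dict:
    cord = CordSpec("thick")  # mid-range rest length 0.6175 m
    elong = 100.0 * 0.250 / cord.rest_length  # 250 mm of stretch
    force = 0.15 * 75.0 * GRAVITY / (4.0 * math.sin(math.radians(45.0)))
    return {
        "cord": cord,
        "anchor_elongation_pct": elong,
        "anchor_force_n": force,
        "saturation_n": 150.0,
        "seed": 7,
        "n_restarts": 30,
    }


def _child_thin_recipe() -> dict:
    cord = CordSpec("thin")  # mid-range rest length 0.6375 m
    elong = 100.0 * 0.100 / cord.rest_length  # 100 mm of stretch
    force = 0.16 * 12.0 * GRAVITY / (4.0 * math.sin(math.radians(10.0)))
    return {
        "cord": cord,
        "anchor_elongation_pct": elong,
        "anchor_force_n": force,
        "saturation_n": 80.0,
        "seed": 7,
        "n_restarts": 30,
    }


_RECIPES = {
    "reference_adult_thick": _adult_thick_recipe,
    "reference_child_thin": _child_thin_recipe,
}

REFERENCE_NAMES = tuple(_RECIPES)


def _bench_spec_from_recipe(recipe: dict, noise_cv: float = 0.0, seed: int | None = None) -> SyntheticCordSpec:
    return SyntheticCordSpec.calibrated(
        cord=recipe["cord"],
        anchor_elongation_pct=recipe["anchor_elongation_pct"],
        anchor_force_n=recipe["anchor_force_n"],
        saturation_n=recipe["saturation_n"],
        noise_cv=noise_cv,
        seed=recipe["seed"] if seed is None else seed,
    )


def thick_bench_spec(noise_cv: float = 0.0, seed: int = 7) -> SyntheticCordSpec:
    """The thick-cord synthetic bench (adult-calibrated ground truth)."""
    return _bench_spec_from_recipe(_adult_thick_recipe(), noise_cv, seed)


def thin_bench_spec(noise_cv: float = 0.0, seed: int = 7) -> SyntheticCordSpec:
    """The thin-cord synthetic bench (child-calibrated ground truth)."""
    return _bench_spec_from_recipe(_child_thin_recipe(), noise_cv, seed)


def build_reference(name: str) -> tuple[FitResult, SyntheticCordSpec]:
    """Recompute a reference characteristic from its recorded recipe.

    Running this twice (or regenerating the packaged JSON with
    ``scripts/regenerate_fixtures.py``) reproduces the fixture
    bit-exactly: the bench is noiseless and the fit seed is recorded.
    """
    try:
        recipe = _RECIPES[name]()
    except KeyError:
        raise InvalidInputError(
            f"unknown reference characteristic {name!r}; "
            f"expected one of {sorted(_RECIPES)}"
        ) from None
    bench_spec = _bench_spec_from_recipe(recipe)
    bench = generate_bench(bench_spec)
    fit = fit_sum_of_sines(
        bench,
        recipe["cord"],
        n_restarts=recipe["n_restarts"],
        seed=recipe["seed"],
    )
    return fit, bench_spec


def reference_fixture_dict(name: str) -> dict:
    """The JSON payload of a packaged fixture, recomputed from its recipe."""
    fit, bench_spec = build_reference(name)
    return {
        **fit.characteristic.to_dict(),
        "provenance": {
            "note": (
                "synthetic: 3-term sum-of-sines fit to a noiseless "
                "calibrated bench curve, not a physical measurement"
            ),
            "generator": {
                "saturation_n": bench_spec.saturation_n,
                "scale_pct": bench_spec.scale_pct,
                "toe_exponent": bench_spec.toe_exponent,
                "grid": list(bench_spec.grid),
            },
            "fit_seed": bench_spec.seed,
        },
    }


def reference_characteristic(name: str) -> CordCharacteristic:
    """Load a packaged reference characteristic by name.

    Available names: ``reference_adult_thick`` (calibrated to the 75 kg /
    45 deg / 250 mm, 15 % unweighting case) and ``reference_child_thin``
    (12 kg / 10 deg / 100 mm, 16 %).
    """
    if name not in _RECIPES:
        raise InvalidInputError(
            f"unknown reference characteristic {name!r}; "
            f"expected one of {sorted(_RECIPES)}"
        )
    payload = json.loads(
        resources.files("spiderstat").joinpath(f"data/{name}.json").read_text()
    )
    return CordCharacteristic.from_dict(payload)
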