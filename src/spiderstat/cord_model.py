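"""Elastic-cord (expander) tension as a function of elongation.

The cords of the cage come in two catalogue types, *thick* and *thin*,
with rest (zero-force) lengths in narrow catalogue bands.  Tension is
modelled as a three-term sum of sines of the elongation expressed as a
percent of rest length,

    T(x) = sum_k  a_k * sin(b_k * x + c_k),        x in [0, 100] %,

fitted to bench dynamometer measurements by seeded multi-start nonlinear
least squares.  A cord transmits tension only, so the evaluated model is
floored at 0 N.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CatalogueRangeWarning,
    FitInfeasibleError,
    InvalidInputError,
    OutOfDomainError,
    DegenerateCharacteristicWarning,
    SlackCordWarning,
)

__all__ = [
    "CordSpec",
    "BenchMeasurement",
    "CordCharacteristic",
    "FitResult",
    "elongation_pct",
    "tension",
    "parallel_tension",
    "fit_sum_of_sines",
    "working_range",
    "N_TERMS",
    "MAX_FREQUENCY",
    "DEFAULT_REST_LENGTH",
    "CATALOGUE_BANDS",
]

#: Number of sine terms in the tension model.
N_TERMS = 3

#: Upper bound on the angular frequency per percent elongation used by the
#: fitter; pi/50 keeps every term's half-period at least as long as the
#: 0-100 % domain, which is ample for smooth monotone cord curves.
MAX_FREQUENCY = np.pi / 50.0

#: Mid-range default rest lengths per cord type, metres.
DEFAULT_REST_LENGTH = {"thick": 0.6175, "thin": 0.6375}

#: Catalogue rest-length bands per cord type, metres.
CATALOGUE_BANDS = {"thick": (0.605, 0.630), "thin": (0.620, 0.655)}


@dataclass(frozen=True)
class CordSpec:
    """A cord type plus its rest (zero-force, straight-line) length.

    Parameters
    ----------
    kind:
        ``"thick"`` or ``"thin"``.
    rest_length:
        Rest length in metres.  ``None`` selects the mid-range default
        for the kind.  A value outside the catalogue band for the kind
        emits :class:`CatalogueRangeWarning` but is accepted.
    """

    kind: str
    rest_length: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.kind not in CATALOGUE_BANDS:
            raise InvalidInputError(
                f"unknown cord kind {self.kind!r}; expected 'thick' or 'thin'"
            )
        if self.rest_length is None:
            object.__setattr__(
                self, "rest_length", DEFAULT_REST_LENGTH[self.kind]
            )
        if not self.rest_length > 0:
            raise InvalidInputError("rest_length must be positive")
        lo, hi = CATALOGUE_BANDS[self.kind]
        if not (lo <= self.rest_length <= hi):
            warnings.warn(
                f"rest length {self.rest_length} m is outside the "
                f"{self.kind}-cord catalogue band [{lo}, {hi}] m",
                CatalogueRangeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class BenchMeasurement:
    """One dynamometer reading: elongation (percent of rest length), force (N)."""

    elongation_pct: float
    force: float

    def __post_init__(self):
        if self.elongation_pct < 0:
            raise InvalidInputError("elongation_pct must be >= 0")
        if self.force < 0:
            raise InvalidInputError("force must be >= 0")


@dataclass(frozen=True)
class CordCharacteristic:
    """A fitted three-term sum-of-sines tension model for one cord type.

    ``terms`` holds exactly three ``(amplitude_N, frequency_per_pct,
    phase_rad)`` triples.  The model domain is elongation 0-100 % of rest
    length; evaluation outside it is an error (above) or slack (below).
    """

    spec: CordSpec
    terms: tuple[tuple[float, float, float], ...]
    domain: tuple[float, float] = (0.0, 100.0)
    r_squared: float | None = None

    def __post_init__(self):
        terms = tuple(tuple(float(v) for v in t) for t in self.terms)
        if len(terms) != N_TERMS or any(len(t) != 3 for t in terms):
            raise InvalidInputError(
                f"a characteristic has exactly {N_TERMS} (a, b, c) terms"
            )
        object.__setattr__(self, "terms", terms)
        if self.r_squared is not None and not self.r_squared <= 1.0:
            raise InvalidInputError("r_squared cannot exceed 1")
        grid = np.linspace(*self.domain, 201)
        if not np.all(np.isfinite(self._raw(grid))):
            raise InvalidInputError("tension is not finite over the domain")

    def _raw(self, x):
        """Un-floored model value; used internally and by the fitter."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, b, c in self.terms:
            out = out + a * np.sin(b * x + c)
        return out

    def tension(self, elongation_pct: float) -> float:
        return tension(self, elongation_pct)

    # -- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.spec.kind,
            "rest_length_m": self.spec.rest_length,
            "terms": [
                {"a_N": a, "b_per_pct": b, "c_rad": c} for a, b, c in self.terms
            ],
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CordCharacteristic":
        return cls(
            spec=CordSpec(kind=d["kind"], rest_length=d["rest_length_m"]),
            terms=tuple(
                (t["a_N"], t["b_per_pct"], t["c_rad"]) for t in d["terms"]
            ),
            r_squared=d.get("r_squared"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "CordCharacteristic":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start sum-of-sines fit."""

    characteristic: CordCharacteristic
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n_restarts_used: int = 0


def elongation_pct(spec: CordSpec, stretched_length: float) -> float:
    """Elongation as percent of rest length, clamped below at 0.

    A stretched length shorter than the rest length means the cord is
    slack; it carries no tension, so the elongation reports as 0 %.
    """
    if not stretched_length > 0:
        raise InvalidInputError("stretched_length must be positive")
    return max(
        0.0, 100.0 * (stretched_length - spec.rest_length) / spec.rest_length
    )


def tension(char: CordCharacteristic, elongation_pct: float) -> float:
    """Evaluate the tension model at one elongation, in newtons.

    Negative elongation (slack cord) returns 0 N with a warning.
    Elongation above the fitted domain raises :class:`OutOfDomainError`
    rather than extrapolating an oscillatory basis.
    """
    lo, hi = char.domain
    if elongation_pct < lo:
        warnings.warn(
            f"slack cord: elongation {elongation_pct:.2f}% < {lo}%, tension 0 N",
            SlackCordWarning,
            stacklevel=2,
        )
        return 0.0
    if elongation_pct > hi:
        # tolerate pure round-off at the upper edge, reject real overshoot
        if elongation_pct <= hi + 1e-9:
            elongation_pct = hi
        else:
            raise OutOfDomainError(
                f"elongation {elongation_pct:.2f}% is above the fitted domain "
                f"[{lo}, {hi}]%"
            )
    return float(max(0.0, char._raw(elongation_pct)))


def parallel_tension(
    chars: Sequence[CordCharacteristic], elongation_pct: float
) -> float:
    """Total tension of co-routed cords sharing one elongation (sum)."""
    if not chars:
        raise InvalidInputError("parallel_tension needs at least one cord")
    return float(sum(tension(c, elongation_pct) for c in chars))


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a = params[0::3, None]
    b = params[1::3, None]
    c = params[2::3, None]
    return (a * np.sin(b * x[None, :] + c)).sum(axis=0)


def fit_sum_of_sines(
    measurements: Iterable[BenchMeasurement],
    spec: CordSpec,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit the 3-term sum-of-sines tension model to bench measurements.

    The objective is multimodal in the frequencies, so the fit runs
    ``n_restarts`` seeded random initialisations (amplitudes in
    (0, 2*max force], frequencies in (0, pi/50] per percent, phases in
    [-pi, pi]) of bounded trust-region least squares and keeps the restart
    with the smallest residual sum of squares.  Deterministic for a fixed
    seed.

    Requires at least 10 measurements spanning at least 50 percentage
    points of elongation, with non-constant forces.
    """
    meas = list(measurements)
    if len(meas) < 10:
        raise FitInfeasibleError(
            f"need >= 10 measurements, got {len(meas)}"
        )
    x = np.array([m.elongation_pct for m in meas], dtype=float)
    f = np.array([m.force for m in meas], dtype=float)
    if x.max() - x.min() < 50.0:
        raise FitInfeasibleError(
            "measurements must span >= 50 percentage points of elongation"
        )
    if np.ptp(f) == 0.0:
        raise FitInfeasibleError("forces are constant; nothing to fit")
    if n_restarts < 1:
        raise InvalidInputError("n_restarts must be >= 1")

    fmax = float(f.max())
    tiny = 1e-9
    lower = np.tile([tiny, tiny, -np.pi], N_TERMS)
    upper = np.tile([2.0 * fmax, MAX_FREQUENCY, np.pi], N_TERMS)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        p0 = rng.uniform(lower, upper)
        sol = least_squares(
            lambda p: _model(p, x) - f,
            p0,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    residuals = _model(best.x, x) - f
    ss_res = float(residuals @ residuals)
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot
    terms = tuple(tuple(best.x[3 * k : 3 * k + 3]) for k in range(N_TERMS))
    char = CordCharacteristic(spec=spec, terms=terms, r_squared=r_squared)
    return FitResult(
        characteristic=char,
        r_squared=r_squared,
        residuals=residuals,
        n_restarts_used=n_restarts,
    )


def working_range(
    char: CordCharacteristic, step: float = 0.1
) -> tuple[float, float]:
    """Strictly increasing sub-interval of the desirable 20-80 % band.

    Cord elongations between 20 and 80 % are the recommended operating
    band; within it the tension curve should rise monotonically so that
    lengthening a cord always increases its pull.  The scan walks a dense
    grid from 20 % upward and returns the longest strictly increasing run
    anchored at 20 %.  A characteristic that never increases in the band
    returns the empty range ``(20.0, 20.0)`` with a warning.
    """
    lo, hi = 20.0, 80.0
    grid = np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)
    vals = np.maximum(char._raw(grid), 0.0)
    increasing = np.diff(vals) > 0
    if not increasing.any():
        warnings.warn(
            "tension is non-increasing everywhere in the 20-80% band",
            DegenerateCharacteristicWarning,
            stacklevel=2,
        )
        return (lo, lo)
    stop = int(np.argmin(increasing)) if not increasing.all() else increasing.size
    if stop == 0:
        warnings.warn(
            "tension does not increase at the lower edge of the 20-80% band",
            DegenerateCharacteristicWarning,
            stacklevel=2,
        )
        return (lo, lo)
    return (lo, float(grid[stop]))
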