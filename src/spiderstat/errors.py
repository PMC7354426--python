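"""Exception and warning types shared across the package."""


class SpiderError(Exception):
    """Base class for all spiderstat errors."""


class InvalidInputError(SpiderError, ValueError):
    """An argument violates a precondition (wrong sign, empty list, ...)."""


class OutOfDomainError(SpiderError, ValueError):
    """A characteristic was evaluated outside its fitted elongation domain."""


class FitInfeasibleError(SpiderError, ValueError):
    """Bench data are insufficient or degenerate for a sum-of-sines fit."""


class DegenerateGeometryError(SpiderError, ValueError):
    """Cord geometry is degenerate (e.g. anchor coincides with belt point)."""


class AmbiguousAzimuthError(SpiderError, ValueError):
    """A vertical cord direction leaves the azimuth undefined."""


class InfeasibleTargetError(SpiderError, ValueError):
    """The requested unweighting target lies outside the achievable range.

    Carries the achievable interval so callers can report it.
    """

    def __init__(self, target: float, achievable: tuple[float, float]):
        self.target = target
        self.achievable = achievable
        lo, hi = achievable
        super().__init__(
            f"target unweighting {target:+.4f} is outside the achievable "
            f"interval [{lo:+.4f}, {hi:+.4f}] for this cord set"
        )


class SchemaError(SpiderError, ValueError):
    """A scenario file violates the schema; message names the field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class SpiderWarning(UserWarning):
    """Base class for all spiderstat warnings."""


class SlackCordWarning(SpiderWarning):
    """A cord was evaluated at negative elongation (slack): tension is 0 N."""


class CatalogueRangeWarning(SpiderWarning):
    """A rest length lies outside the catalogue band for its cord type."""


class DegenerateCharacteristicWarning(SpiderWarning):
    """A fitted characteristic is non-increasing over the working band."""


class PerturbationRangeWarning(SpiderWarning):
    """A tension perturbation factor lies outside the usual 0.8-1.2 band."""


class TandemStanceWarning(SpiderWarning):
    """Feet are laterally coincident; lateral moment cannot be balanced."""
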