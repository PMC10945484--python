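"""Exception hierarchy for dibkit."""


class DibkitError(Exception):
    """Base class for all dibkit errors."""


class GeometryError(DibkitError, ValueError):
    """Invalid or degenerate droplet-pair geometry."""


class DetectionError(DibkitError):
    """Wrong number of droplet candidates found in an image frame."""

    def __init__(self, n_found: int, message: str | None = None):
        self.n_found = n_found
        super().__init__(message or f"expected exactly 2 droplets, found {n_found}")


class TrackingError(DibkitError):
    """Droplet identity could not be preserved across frames."""


class IntegrationError(DibkitError):
    """ODE integration produced a non-finite state or failed to converge."""


class FitError(DibkitError):
    """Parameter fit failed to converge."""


class UndefinedEstimateError(DibkitError):
    """The requested estimate is undefined for the given inputs (e.g. zero gradient)."""


class BaselineError(DibkitError):
    """Baseline windows overlap the transition peak, or baseline iteration failed."""


class NoTransitionError(DibkitError):
    """No peak rises sufficiently above the flanking noise."""


class AmbiguousPeakError(DibkitError):
    """Multiple comparable peaks; analysis refuses to pick one."""

    def __init__(self, candidates, message: str | None = None):
        self.candidates = list(candidates)
        super().__init__(
            message
            or f"{len(self.candidates)} comparable peaks at {self.candidates}"
        )


class MissingPeakError(DibkitError):
    """A required spectral band has no discernible peak."""

    def __init__(self, center: float, message: str | None = None):
        self.center = center
        super().__init__(message or f"no peak found near {center:g} cm^-1")


class NormalizationError(DibkitError):
    """Anchor-window intensity is non-positive; spectrum cannot be normalized."""


class ConfigError(DibkitError):
    """Invalid study or simulation configuration."""
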