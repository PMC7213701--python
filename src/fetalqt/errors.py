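"""Exception hierarchy shared across the package."""


class FetalQtError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FetalQtError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(FetalQtError, ValueError):
    """A configuration value is unknown or inconsistent."""


class DegenerateGridError(InvalidArgumentError):
    """The requested curve grid has fewer than one usable sample."""


class NoEstimateError(FetalQtError):
    """A per-beat estimator could not produce a value for this beat.

    Carries ``beat`` (an identifier, when known) so batch callers can log
    which beat failed and continue.
    """

    def __init__(self, message: str, beat=None):
        super().__init__(message)
        self.beat = beat


class ImplausibleBeatError(FetalQtError):
    """A beat produced measurements outside physiological bounds."""

    def __init__(self, message: str, beat=None):
        super().__init__(message)
        self.beat = beat
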