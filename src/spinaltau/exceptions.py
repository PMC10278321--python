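"""Exception hierarchy for spinaltau."""


class SpinalTauError(Exception):
    """Base class for all package errors."""


class DomainError(SpinalTauError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class EstimationError(SpinalTauError, RuntimeError):
    """A fit failed or did not converge.

    When a best iterate is available it is attached as ``best``
    (a mapping of parameter name to value).
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigurationError(SpinalTauError, ValueError):
    """A simulation or IO configuration is invalid."""


class FixtureError(SpinalTauError, RuntimeError):
    """A bundled data fixture is missing or corrupted."""


class SummaryError(SpinalTauError, ValueError):
    """A dataset summary could not be computed (e.g. missing observation)."""
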