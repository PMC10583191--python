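"""Exception hierarchy shared by all pipeline stages."""


class PhenoseasonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenoseasonError):
    """Invalid generation or run configuration."""


class DomainError(PhenoseasonError, ValueError):
    """Input outside the mathematical domain of an operation."""


class InsufficientDataError(PhenoseasonError):
    """Too few observations for the requested fit."""


class EmptyTrajectoryError(PhenoseasonError):
    """A shoot with no positive size anywhere in the season."""


class FitFailureError(PhenoseasonError):
    """No candidate model converged; carries per-candidate diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ProfileError(PhenoseasonError):
    """Senescence profile could not be constructed (empty grid overlap)."""


class SpecificationError(PhenoseasonError):
    """Invalid structural equation model specification."""


class InputError(PhenoseasonError):
    """Malformed tabular input (duplicate keys, bad columns)."""
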