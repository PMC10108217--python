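"""Exception hierarchy shared across the package."""


class CirsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CirsError):
    """Invalid configuration; message names the offending field."""


class SchemaError(CirsError):
    """Input table is missing a required column or has the wrong dtype."""


class ValidationError(CirsError):
    """Row-level invariant violations; carries a per-row report."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report or []


class LeakageError(CirsError):
    """A discovery stage was handed outcomes from outside the training split."""


class FitError(CirsError):
    """A statistical fit failed (degenerate input, non-convergence, ...)."""
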