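"""Exception hierarchy for the panel-analysis pipeline.

Every error raised on a contract violation derives from :class:`StepPanelError`
so callers (and the CLI) can catch pipeline failures without masking bugs.
"""


class StepPanelError(Exception):
    """Base class for all package errors."""


class FormatError(StepPanelError):
    """A file does not conform to its container format (e.g. RCC sections)."""


class SchemaError(StepPanelError):
    """Structurally valid input referencing unknown genes/samples/columns."""


class ValidationError(StepPanelError):
    """A domain invariant is violated (e.g. a batch without a reference)."""


class ConfigurationError(StepPanelError):
    """A parameter or precondition on configuration is not satisfied."""


class DegenerateInputError(StepPanelError):
    """Statistically degenerate input (e.g. zero variance in a correlation)."""


class InsufficientDataError(StepPanelError):
    """Too few observations for the requested analysis."""
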