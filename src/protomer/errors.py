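"""Exception hierarchy for the protomer pipeline.

Every pipeline stage raises a subclass of :class:`ProtomerError` so callers
can catch one type; stage orchestration attaches the stage name.
"""


class ProtomerError(Exception):
    """Base class for all package errors."""


class InputError(ProtomerError):
    """Malformed user input (e.g. an unparsable SMILES string)."""


class ParseError(InputError):
    """A structured file (XYZ, CSV) violated its format; carries a line number
    when one is known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmbeddingError(ProtomerError):
    """3D coordinate generation failed after retries."""


class ConfigurationError(ProtomerError):
    """A required element is missing from an internal data table, or an
    option names an unavailable backend/resource."""


class NoTitratableSitesError(ProtomerError):
    """The molecule has no N/O site eligible for the requested ion mode and
    is therefore out of scope for charge-state modeling."""


class UnsupportedElementError(ProtomerError):
    """An element is neither supported by the potential backend nor covered
    by a surrogate-substitution rule."""


class OptimizationError(ProtomerError):
    """The potential backend produced a non-finite energy or force."""


class TrainingError(ProtomerError):
    """The training table is degenerate (e.g. constant features) or too
    small to fit the energy regressor."""


class StageError(ProtomerError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
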