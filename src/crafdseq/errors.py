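"""Exception hierarchy shared across the pipeline stages.

Validation/domain problems raise :class:`CrafdValidationError` subclasses
(CLI exit code 2); file problems raise the built-in ``OSError`` family
(CLI exit code 3).
"""


class CrafdError(Exception):
    """Base class for all package-specific errors."""


class CrafdValidationError(CrafdError, ValueError):
    """Invalid input values, parameters, or object state."""


class ParseError(CrafdValidationError):
    """A text input (wiggle, grp, TSV) could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class CoordinateError(CrafdValidationError):
    """A genomic coordinate falls outside the declared genome."""


class StateError(CrafdValidationError):
    """An operation was applied to an object in the wrong state
    (e.g. normalizing an already-normalized track)."""


class IncompatibleTracksError(CrafdValidationError):
    """Tracks with mismatched strand, length, genome, or normalization
    were combined."""
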