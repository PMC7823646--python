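"""Exception hierarchy for cowseg.

All errors derive from :class:`CowsegError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
also derive from the matching builtin (``ValueError`` etc.) so generic
code behaves sensibly.
"""


class CowsegError(Exception):
    """Base class for all cowseg errors."""


class InvalidParameterError(CowsegError, ValueError):
    """A parameter violates its documented range or type."""


class IncompletePatchError(CowsegError, ValueError):
    """A 3x3 depth patch contains background (zero) pixels."""


class InvalidPolygonError(CowsegError, ValueError):
    """A labelling polygon has fewer than three vertices."""


class EmptyInputError(CowsegError, ValueError):
    """An operation that needs data received an empty table/array."""


class ShapeError(CowsegError, ValueError):
    """Array dimensions do not match the operation's contract."""


class FormatError(CowsegError, IOError):
    """A file on disk is malformed (bad PGM header, truncation, ...)."""


class InsufficientClassSizeError(CowsegError, ValueError):
    """A class is too small for the requested resampling."""


class EncodingError(CowsegError, ValueError):
    """Label matrix rows are not valid one-hot indicator vectors."""


class TrainingFailureError(CowsegError, RuntimeError):
    """Network training diverged; carries the history so far."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class InvalidComparisonError(CowsegError, ValueError):
    """Two metric reports cover different class sets."""
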