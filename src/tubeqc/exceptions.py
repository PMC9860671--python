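"""Exception hierarchy.

``InvalidInputError`` covers validation failures (bad values, unmatched
labels, malformed files); ``DegenerateComputationError`` covers inputs
that are formally valid but make the requested computation meaningless
(zero slope, identical calibration levels, zero divisor). The CLI maps
them to exit codes 2 and 3 respectively.
"""


class TubeQCError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TubeQCError, ValueError):
    """Input fails a precondition or schema check."""


class SchemaError(InvalidInputError):
    """A delimited-text table does not match any registered schema."""


class DegenerateComputationError(TubeQCError, ArithmeticError):
    """The computation is degenerate for this input (e.g. zero slope)."""
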