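"""Exception hierarchy shared across the pipeline."""


class FractalGazeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FractalGazeError, ValueError):
    """A generator or parameter specification violates its invariants."""


class InvalidInputError(FractalGazeError, ValueError):
    """Input data violate a precondition (empty segment, bad indices, ...)."""


class InvalidGeometryError(FractalGazeError, ValueError):
    """Screen geometry is unusable (nonpositive distance or size)."""


class InvalidWindowError(FractalGazeError, ValueError):
    """A DFA window size is too small for the requested detrend order."""


class DegenerateSeriesError(FractalGazeError, ValueError):
    """A series has no residual fluctuation (constant / exact polynomial)."""


class NotEstimableError(FractalGazeError, ValueError):
    """A quantity (e.g. precision) cannot be estimated from the data given."""


class InvalidComparisonError(FractalGazeError, ValueError):
    """Two model fits cannot be compared (non-nested, different rows)."""


class ParseError(FractalGazeError, ValueError):
    """A data file is malformed; message names the offending line."""
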