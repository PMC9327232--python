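"""Exception hierarchy for parse and validation failures."""


class GraphselError(Exception):
    """Base class for all package errors."""


class ParseError(GraphselError):
    """A file could not be parsed into a valid in-memory object."""


class SampleAlignmentError(ParseError):
    """Sample ids in the expression matrix and label file do not match."""


class NonNumericValueError(ParseError):
    """An expression cell could not be interpreted as a number."""


class DuplicateFeatureError(ParseError):
    """The same probe id occurs more than once in the matrix."""


class NegativeWeightError(ParseError):
    """A prior-network row carries a negative weight (strict mode)."""


class ValidationError(GraphselError):
    """An in-memory object violates a documented precondition."""


class NegativeSamplingError(GraphselError):
    """The graph cannot supply the requested number of non-edges."""

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(
            f"negative sampling shortfall: requested {requested} non-edges "
            f"but only {available} are available"
        )
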