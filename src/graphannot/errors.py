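"""Error hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`graphannot.cli`).
"""


class GraphAnnotError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(GraphAnnotError):
    """A file could not be parsed (ragged rows, non-numeric entries, ...)."""

    exit_code = 2


class ValidationError(GraphAnnotError):
    """Input data violates a structural contract (duplicate ids, bad labels, ...)."""

    exit_code = 3


class ParameterError(GraphAnnotError):
    """A hyperparameter is outside its admissible range."""

    exit_code = 4


class NumericError(GraphAnnotError):
    """A numerical computation degenerated (non-finite values, failed decomposition)."""

    exit_code = 5


class ConvergenceError(GraphAnnotError):
    """An iterative procedure failed to converge within its iteration budget."""

    exit_code = 6
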