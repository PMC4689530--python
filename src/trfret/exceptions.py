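"""Exception hierarchy for trfret."""


class TRFretError(Exception):
    """Base class for all trfret errors."""


class RangeError(TRFretError, ValueError):
    """A value (distance, time, index) lies outside its valid domain."""


class ContractError(TRFretError, ValueError):
    """Mismatched inputs: incompatible grids, roles or shapes."""


class ConvergenceError(TRFretError, RuntimeError):
    """An iterative procedure failed to converge.

    Carries optional context (e.g. the offending moment in a
    moment-to-parameter inversion, or the best chi-square trace of a
    failed global fit) in ``.details``.
    """

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details


class StabilityError(TRFretError, RuntimeError):
    """Non-finite values encountered during numerical integration."""


class ParseError(TRFretError, ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
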