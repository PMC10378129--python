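"""Exception types shared across the package."""


class RecspecError(Exception):
    """Base class for all package-specific errors."""


class SingularRecurrenceError(RecspecError, ZeroDivisionError):
    """Some R_j = 0 inside the evaluation range, so the recurrence cannot be
    solved forward (the closed form divides by the product of the R_j)."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"R_{index} = 0: recurrence is singular at row {index}")


class CoefficientRangeError(RecspecError, IndexError):
    """A tabulated coefficient family was asked for an index it does not
    cover.  Tables are never padded."""

    def __init__(self, name: str, index: int, length: int):
        self.name, self.index, self.length = name, index, length
        super().__init__(
            f"coefficient table {name!r} has {length} entries; index {index} requested"
        )


class PoleError(RecspecError, ZeroDivisionError):
    """A continued-fraction denominator vanished; carries the ladder index."""

    def __init__(self, index: int, what: str = "continued-fraction denominator"):
        self.index = index
        super().__init__(f"{what} vanished at index {index}")


class ConvergenceDomainError(RecspecError, ValueError):
    """Evaluation point lies outside the series' disc of convergence and the
    series is not a polynomial."""


class NotAnEigenvalueError(RecspecError, ValueError):
    """The truncation condition C_{N+1} = 0 failed for the supplied rate."""

    def __init__(self, lam, tail):
        self.lam, self.tail = lam, tail
        super().__init__(
            f"lambda = {lam} is not in the spectrum: |C_N+1| = {tail:.3e} above tolerance"
        )


class ReducibleChainError(RecspecError, ValueError):
    """A birth-death chain has a cut state (zero interior rate)."""

    def __init__(self, state: int):
        self.state = state
        super().__init__(f"chain is reducible: zero rate cuts the state space at n = {state}")
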