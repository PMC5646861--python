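"""Exception hierarchy shared across the package."""


class SumoNmrError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(SumoNmrError, ValueError):
    """A synthetic-data design violates its invariants."""


class PeakMismatchError(SumoNmrError, ValueError):
    """Two peaks paired for a CSP do not belong to the same residue."""


class AmbiguousMatchError(SumoNmrError, ValueError):
    """Two reference peaks claim the same target peak during matching."""


class DegenerateDataError(SumoNmrError, ValueError):
    """Input data too degenerate for the requested statistic."""


class UnderdeterminedFitError(SumoNmrError, ValueError):
    """Fewer observations than free parameters."""


class FitError(SumoNmrError, RuntimeError):
    """A nonlinear fit failed to converge or produced an invalid optimum."""


class DecayFitError(FitError):
    """Exponential decay fit failed (non-decaying or divergent data)."""


class DegenerateGeometryError(SumoNmrError, ValueError):
    """Coordinate set too degenerate for superposition (too few or collinear points)."""


class SelectionError(SumoNmrError, ValueError):
    """Atom/residue selection matched nothing."""


class ParseError(SumoNmrError, ValueError):
    """A text input file could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
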