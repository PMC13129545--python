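"""Exception hierarchy shared across the package."""


class CasKineticsError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(CasKineticsError, ValueError):
    """Sequence contains characters outside the expected alphabet."""


class LengthError(CasKineticsError, ValueError):
    """Sequence or window length violates a precondition."""


class DomainError(CasKineticsError, ValueError):
    """Numeric argument outside its physical domain (e.g. negative concentration)."""


class DesignError(CasKineticsError, RuntimeError):
    """A designed background sequence could not satisfy its constraints."""


class GridError(CasKineticsError, ValueError):
    """Time grids of traces do not match."""


class NormalizationError(CasKineticsError, ValueError):
    """Trace plateau is non-positive; normalization undefined."""


class HalfTimeError(CasKineticsError, ValueError):
    """No half-time crossing exists (e.g. all-zero trace)."""


class FitError(CasKineticsError, RuntimeError):
    """Parameter fit failed or the data are degenerate.

    Carries ``best_params`` when a best-so-far estimate exists.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class JoinError(CasKineticsError, KeyError):
    """A name-keyed join between tables was not total."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)
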