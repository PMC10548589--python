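"""Exception types shared across the package."""


class PrevRatioError(Exception):
    """Base class for all package errors."""


class ValidationError(PrevRatioError):
    """Malformed or inconsistent input (negative counts, unseen factor level, ...)."""


class UndefinedEstimateError(PrevRatioError):
    """An estimate that does not exist for the given data (e.g. a zero cell).

    Raised instead of returning a silent infinity; the message names the
    offending cell or sum.
    """


class NoConsistentTableError(PrevRatioError):
    """Exhaustive table reconstruction found no integer table matching the
    printed summary statistics. Carries the nearest misses for diagnosis."""

    def __init__(self, message: str, nearest=()):
        super().__init__(message)
        self.nearest = list(nearest)


class RankDeficiencyError(PrevRatioError):
    """Design matrix is not of full column rank."""
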