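"""Exception hierarchy shared across the pipeline."""


class WheatStressError(Exception):
    """Base class for all package errors."""


class ParameterError(WheatStressError, ValueError):
    """A parameter set violates its documented invariants."""


class WeatherDataError(WheatStressError, ValueError):
    """Observed weather input is incomplete or malformed."""


class SeasonFailureError(WheatStressError, RuntimeError):
    """A simulated season could not be completed (e.g. thermal-time
    requirement never met, or a stress window falls off the season edge)."""


class UndefinedIndexError(WheatStressError, ZeroDivisionError):
    """A stress index is undefined because the tolerant-cultivar yield is
    zero for that year."""
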