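"""Exception taxonomy for sewersense.

All package errors derive from :class:`SewerSenseError` so callers can catch
one base class; each also subclasses the closest builtin (ValueError /
KeyError) so generic handling keeps working.
"""


class SewerSenseError(Exception):
    """Base class for all sewersense errors."""


class ConfigError(SewerSenseError, ValueError):
    """Invalid configuration (bad threshold, non-PSD correlation matrix, ...)."""


class MissingAnalyteError(SewerSenseError, KeyError):
    """An analyte required downstream has no entry (e.g. no sampling rate)."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class DomainError(SewerSenseError, ValueError):
    """A physical quantity is outside its domain (negative mass, zero flow, ...)."""


class InsufficientDataError(SewerSenseError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(SewerSenseError, ValueError):
    """Data are degenerate for the requested operation (zero variance,
    singular matrix, constant column)."""
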