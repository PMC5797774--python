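"""Exception hierarchy for lfpdyn.

All package-specific failures derive from :class:`LfpdynError` so callers can
catch one base class at pipeline level while tests can assert on the precise
failure mode.
"""


class LfpdynError(Exception):
    """Base class for all lfpdyn errors."""


class MalformedInputError(LfpdynError):
    """A file or in-memory structure violates the trial-set layout."""


class ParseError(MalformedInputError):
    """A cell could not be parsed; carries row/column context in the message."""


class EmptyWindowError(LfpdynError):
    """The requested steady window discards the entire trial."""


class DegenerateSeriesError(LfpdynError):
    """A statistic is undefined for this input (e.g. constant series)."""


class NoZeroCrossingError(LfpdynError):
    """The autocorrelation never crosses zero within the searched range."""


class NoMinimumError(LfpdynError):
    """The average mutual information has no local minimum in range."""


class NoEmbeddingError(LfpdynError):
    """FNN never dropped below threshold up to d_max.

    The partial FNN curve is attached as ``.curve``.
    """

    def __init__(self, message, curve=None):
        super().__init__(message)
        self.curve = curve
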