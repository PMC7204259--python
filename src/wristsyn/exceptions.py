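"""Exception hierarchy for wristsyn.

Validation of arguments raises :class:`ValueError` subclasses so that callers
can distinguish bad configuration (recoverable, exit code 2 in the CLI) from
computation failures (exit code 1).
"""


class WristSynError(Exception):
    """Base class for all package-specific errors."""


class DataError(WristSynError, ValueError):
    """Input data violate a precondition (NaN samples, too-short series...)."""


class DegenerateDataError(DataError):
    """Data are structurally degenerate: all-zero matrix, zero-peak channel,
    zero-range angle axis."""


class FormatError(WristSynError, ValueError):
    """A time-series or manifest file is malformed; message carries the line."""


class SelectionError(WristSynError, RuntimeError):
    """No synergy count satisfied the VAF threshold.

    Carries the full VAF-versus-count table so the caller can inspect it.
    """

    def __init__(self, message, vaf_table=None):
        super().__init__(message)
        self.vaf_table = vaf_table


class CalibrationError(WristSynError, ValueError):
    """Grip-force calibration failed (zero peak activation in training)."""
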