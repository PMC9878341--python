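"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific class that applies.
"""


class BayesNetError(Exception):
    """Base class for all errors raised by prediabn."""


class InputError(BayesNetError):
    """Malformed user input: unknown variables or states, missing values,
    schema violations, inconsistent shapes."""


class InconsistentEvidenceError(BayesNetError):
    """The supplied evidence has probability (numerically) zero under the
    network, so no posterior is defined."""


class CalibrationError(BayesNetError):
    """Calibration failed to bring every target within its tolerance."""

    def __init__(self, message, offending=()):
        super().__init__(message)
        self.offending = tuple(offending)
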