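"""Exception hierarchy."""


class LfpCleanError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LfpCleanError, ValueError):
    """An argument violates a precondition."""


class TooShortError(LfpCleanError, ValueError):
    """The input trace is too short for the requested operation."""


class InsufficientEventsError(LfpCleanError, ValueError):
    """Too few usable events to build a QRS template.

    Carries the usable-event count in ``n_usable``.
    """

    def __init__(self, n_usable: int, n_required: int):
        self.n_usable = n_usable
        self.n_required = n_required
        super().__init__(
            f"only {n_usable} usable QRS events, need at least {n_required}"
        )


class FitError(LfpCleanError, RuntimeError):
    """Nonlinear fit did not converge.  Carries the best iterate."""

    def __init__(self, message: str, best_params=None, diagnostic: str = ""):
        self.best_params = best_params
        self.diagnostic = diagnostic
        super().__init__(message)


class AllWindowsRejectedError(LfpCleanError, RuntimeError):
    """Every spectrogram window was rejected as an outlier."""


class RecordingFormatError(LfpCleanError, ValueError):
    """An on-disk recording violates the format contract."""
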