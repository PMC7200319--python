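"""Exception hierarchy for the preprocessing pipeline.

Every error raised by the library derives from :class:`RamanCleanError`
so callers (and the CLI) can catch pipeline failures in one place.
"""


class RamanCleanError(Exception):
    """Base class for all library errors."""


class ParseError(RamanCleanError):
    """A text export line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class StructureError(RamanCleanError):
    """File rows have inconsistent column counts or no intensity columns."""


class AxisError(RamanCleanError):
    """Wavenumber axis is not strictly monotonic (duplicate channels)."""


class WriteError(RamanCleanError):
    """Output file could not be written."""


class ContractError(RamanCleanError):
    """An argument violates a documented precondition."""


class CapabilityError(RamanCleanError):
    """The requested operation needs data the input does not provide."""


class UnrecoverableChannelError(RamanCleanError):
    """A channel is spike-flagged in every frame, so no donor exists."""

    def __init__(self, channels):
        self.channels = list(channels)
        super().__init__(
            f"channel(s) {self.channels} flagged in all frames; no clean donor"
        )


class EmptySelectionError(RamanCleanError):
    """Zone arithmetic selected no channels; a fit is impossible."""


class UnderdeterminedError(RamanCleanError):
    """Fewer fit channels than polynomial coefficients."""


class WindowError(RamanCleanError):
    """A baseline window does not intersect the spectrum axis."""


class StageError(RamanCleanError):
    """A pipeline stage failed; wraps the cause with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
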