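"""Exception hierarchy for the nchr toolkit.

Every error raised on a violated contract derives from :class:`NCHRError`
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class NCHRError(Exception):
    """Base class for all toolkit errors."""


class InvalidSpecError(NCHRError, ValueError):
    """A phantom specification violates its invariants."""


class InvalidAcquisitionError(NCHRError, ValueError):
    """An acquisition model violates its invariants (e.g. speed factor < 1)."""


class UndefinedMetricError(NCHRError, ValueError):
    """SNR/CNR is undefined for the given inputs (zero variance, empty mask)."""


class CannotEstimateDeltaError(NCHRError, ValueError):
    """No noise information available to derive the k-space tolerance."""


class MalformedContainerError(NCHRError, ValueError):
    """An HDF5 container is missing datasets or has inconsistent shapes."""


class UnsupportedFormatError(NCHRError, ValueError):
    """An image file has an unsupported layout or bit depth."""


class NumericalFailureError(NCHRError, RuntimeError):
    """The solver produced non-finite values; carries the trace so far."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
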