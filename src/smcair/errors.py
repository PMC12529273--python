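"""Exception hierarchy shared across the package."""


class SmcairError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SmcairError, ValueError):
    """A precondition on an argument was violated."""


class OutOfBoundsError(SmcairError):
    """A point fell outside the grid extent."""


class UnsupportedFormatError(SmcairError):
    """File extension not recognised by the I/O layer."""


class ValidationError(SmcairError):
    """Loaded data failed schema or content validation."""


class AlignmentError(SmcairError):
    """Rasters expected on a shared grid do not align."""


class ConvergenceError(SmcairError):
    """An iterative procedure failed to converge."""


class ZeroVarianceError(SmcairError):
    """Analysed variable is constant; statistic undefined."""


class DegenerateTableError(SmcairError):
    """Contingency table has a zero margin."""


class StageError(SmcairError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
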