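"""Exception types shared across the pipeline."""


class WindEEGError(Exception):
    """Base class for all windeeg errors."""


class InvalidParameterError(WindEEGError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidGeometryError(WindEEGError, ValueError):
    """Head/source geometry is degenerate (e.g. dipole outside the inner shell)."""


class SchedulingError(WindEEGError, RuntimeError):
    """The trial-schedule constraints could not be satisfied."""


class QualityError(WindEEGError, RuntimeError):
    """Data quality gate failed (too many bad channels / all epochs rejected)."""


class NumericalError(WindEEGError, ArithmeticError):
    """A numerical precondition was violated (singular matrix, non-positive power...)."""


class ConvergenceError(WindEEGError, RuntimeError):
    """An iterative solver did not reach its tolerance within the iteration budget."""
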