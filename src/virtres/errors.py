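"""Exception hierarchy for virtres.

All package-specific errors derive from :class:`VirtresError` so callers can
catch everything with one except clause; most also derive from the closest
builtin so existing ``except ValueError`` style code keeps working.
"""


class VirtresError(Exception):
    """Base class for all virtres errors."""


class MatrixFormatError(VirtresError, ValueError):
    """A connectivity-matrix file or array violates the expected format
    (non-square, label-count mismatch, unparsable text)."""


class MatrixDomainError(VirtresError, ValueError):
    """Matrix entries violate domain constraints (negative weight,
    asymmetry beyond tolerance, non-binary where binary is required)."""


class ParameterError(VirtresError, ValueError):
    """An argument is outside its valid range or inconsistent with the data."""


class GenerationError(VirtresError, RuntimeError):
    """The synthetic-connectome generator exhausted its retry budget
    without producing a valid (connected) realization."""


class CalibrationError(VirtresError, RuntimeError):
    """The infection-probability grid search could not reach the target
    final recovered fraction."""

    def __init__(self, message: str, best_final_r: float | None = None):
        super().__init__(message)
        self.best_final_r = best_final_r


class DegenerateGraphError(VirtresError, ValueError):
    """A spectral quantity is undefined (all-zero adjacency)."""


class DegenerateEffectError(VirtresError, ValueError):
    """A normalized resection effect is undefined because the full-resection
    effect is (numerically) zero."""


class StatisticsError(VirtresError, ValueError):
    """A statistical routine received groups too small (or degenerate) to test."""


class ConfigError(VirtresError, ValueError):
    """A pipeline configuration file contains unknown or invalid keys."""
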