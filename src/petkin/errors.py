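"""Exception hierarchy for petkin.

Every error raised by the package derives from :class:`PetkinError`, so
callers can catch one type at a pipeline boundary.  Subclasses mark the
stage or contract that was violated; messages name the offending field,
row or file so that fixture problems are diagnosable from the message
alone.
"""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class FormatError(PetkinError):
    """A delimited-text input is structurally malformed (missing columns,
    unparsable values, unknown section)."""


class ScheduleError(PetkinError):
    """A frame schedule violates monotonicity / overlap invariants."""


class RangeError(PetkinError):
    """A value lies outside its physical range (e.g. parent fraction > 1)."""


class InsufficientDataError(PetkinError):
    """Too few samples to perform the requested fit."""


class JoinError(PetkinError):
    """Automated and manual blood curves cannot be joined (uncovered gap)."""


class DivisionError(PetkinError):
    """A ratio is undefined because its denominator is zero."""


class ParameterError(PetkinError):
    """A model or configuration parameter is inadmissible."""


class ConvergenceError(PetkinError):
    """An iterative fit failed to converge."""


class CoverageError(PetkinError):
    """A frame or analysis window extends beyond the available input grid."""


class WindowError(PetkinError):
    """An analysis window (e.g. Logan t*) lies outside the acquisition."""


class ConfigurationError(PetkinError):
    """The requested procedure is inconsistently configured."""


class OracleError(PetkinError):
    """The independent verification integrator failed; tests must abort."""
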