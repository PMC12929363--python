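"""Exception hierarchy for calibration failures.

Every failure mode the pipeline can signal maps to one of these, so callers
can distinguish "the data cannot support this operation" (degeneracy,
insufficient correspondences) from "the estimate is geometrically invalid"
(cheirality) without string matching.
"""


class MsmcalError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(MsmcalError):
    """Too few correspondences / points for the requested estimation."""


class DegenerateGeometryError(MsmcalError):
    """Input configuration is degenerate (collinear points, zero baseline...)."""


class CheiralityError(MsmcalError):
    """A point lies at or behind a camera that is supposed to observe it."""


class IllConditionedError(MsmcalError):
    """Problem is solvable in principle but numerically hopeless (tiny baseline)."""


class DecompositionError(MsmcalError):
    """No homography-decomposition candidate is consistent with the data."""


class RegistrationError(MsmcalError):
    """PnP-based camera registration failed (inlier ratio below floor)."""


class CalibrationError(MsmcalError):
    """Top-level calibration cannot start or continue."""


class ScheduleError(MsmcalError):
    """Invalid projection schedule (duplicate centers, bad ids...)."""
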