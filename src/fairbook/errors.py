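"""Exception hierarchy shared across the package."""


class FairbookError(Exception):
    """Base class for all package-specific errors."""


class RosterMismatchError(FairbookError):
    """An assignment or show vector refers to patients not on the roster,
    or fails to cover the roster exactly."""


class InvalidAssignmentError(FairbookError):
    """An assignment violates the slot grid (capacity, unknown slot index,
    duplicated patient)."""


class ConfigurationError(FairbookError):
    """A configuration value is out of its admissible range."""


class SizeLimitError(FairbookError):
    """An exact method was asked for an instance above its enumeration
    cutoff; the message points to the scalable alternative."""


class InfeasibleError(FairbookError):
    """No assignment satisfies the active quota constraints; the message
    names the binding quota."""


class FitError(FairbookError):
    """A show model could not be fitted (empty or degenerate history)."""


class MissingFeatureError(FairbookError):
    """A patient record lacks a feature the show model requires."""


class MetricUndefinedError(FairbookError):
    """A fairness metric is undefined for the given inputs (e.g. an empty
    group, or a nonpositive reference cost)."""
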