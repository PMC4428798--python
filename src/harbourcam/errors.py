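"""Exception hierarchy.

Configuration errors are raised when a rig or simulation setup is internally
inconsistent; data errors when supplied observation/tide/fix tables cannot be
used; positioning errors when the geometry of a single observation is
unresolvable (these are normally converted to skip records by batch drivers
rather than aborting a run).
"""


class HarbourcamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HarbourcamError):
    """Rig, landmark or simulation configuration is invalid."""


class DataError(HarbourcamError):
    """An input table is missing, empty, out of range or inconsistent."""


class PositioningError(HarbourcamError):
    """A single observation cannot be resolved to a position."""


class MatchingError(DataError):
    """Ambiguous or failed fix-to-observation matching."""


class ConvergenceError(HarbourcamError):
    """An iterative fit failed to converge."""
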