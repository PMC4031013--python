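"""Exception hierarchy.

All errors derive from :class:`NwistratError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class NwistratError(Exception):
    """Base class for all nwistrat errors."""


class ParameterError(NwistratError, ValueError):
    """A generation or analysis parameter violates its invariants."""


class CalibrationError(NwistratError, ValueError):
    """Waveform/pressure calibration is infeasible or degenerate."""


class SegmentationError(NwistratError, ValueError):
    """No complete cardiac beat could be segmented from a recording."""


class DetectionError(NwistratError, ValueError):
    """Peak detection cannot run on the given beat window."""


class AnalysisError(NwistratError, ValueError):
    """A recording could not be analyzed end to end."""


class DomainError(NwistratError, ValueError):
    """A scalar formula was called outside its mathematical domain."""


class InsufficientDataError(NwistratError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateTableError(NwistratError, ValueError):
    """A 2x2 table has an empty margin and no correction was allowed."""


class InputError(NwistratError, ValueError):
    """Mismatched or malformed in-memory inputs."""


class FormatError(NwistratError, ValueError):
    """An on-disk file does not conform to the expected text format."""


class JoinError(NwistratError, ValueError):
    """Patient identifiers do not match between two tables."""


class ConfigError(NwistratError, ValueError):
    """A pipeline configuration is incomplete or inconsistent."""
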