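"""Exception hierarchy for cyclefda.

Every error raised on bad data names the offending cycle and/or day so that
pipeline failures are actionable from the message alone.
"""


class CycleFDAError(Exception):
    """Base class for all cyclefda errors."""


class ParseError(CycleFDAError):
    """Malformed input row (bad type, negative concentration, bad header)."""


class IntegrityError(CycleFDAError):
    """Structurally inconsistent input (e.g. duplicate cycle/day rows)."""


class DetectionError(CycleFDAError):
    """Day-0 peak detection failed (window empty or all-missing)."""


class ReindexError(CycleFDAError):
    """Requested day-index grid does not intersect a cycle's sampled span."""


class GridError(CycleFDAError):
    """No common day grid (or incompatible curve grids) for a cohort."""


class InvariantError(CycleFDAError):
    """A domain invariant violated (non-monotone warp, bad boundary, ...)."""


class DegenerateSDError(CycleFDAError):
    """Standardization requested for a constant (zero-variance) series."""


class InsufficientDataError(CycleFDAError):
    """Fewer data points than the operation's minimum (e.g. <3 lag pairs)."""


class DegeneracyError(CycleFDAError):
    """Zero variance in a correlation coordinate."""


class ParameterError(CycleFDAError):
    """Out-of-range analysis parameter (CI level, bootstrap count, ...)."""


class StabilityError(CycleFDAError):
    """Feedback-map parameters produce a divergent oscillation."""


class ConvergenceWarning(UserWarning):
    """Karcher alignment stopped at max_iter without meeting tolerance."""
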