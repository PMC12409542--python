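"""Exception hierarchy shared across the package.

Every error raised on a user-facing contract violation derives from
:class:`ConfdynError`, so callers can catch one base class.
"""


class ConfdynError(Exception):
    """Base class for all confdyn errors."""


class TrajectoryFormatError(ConfdynError):
    """Topology/coordinate files disagree or cannot be interpreted."""


class SelectionError(ConfdynError):
    """An atom selection expression is malformed or resolves to nothing."""


class AlignmentError(ConfdynError):
    """A per-frame series does not align with its trajectory."""


class ConfigurationError(ConfdynError):
    """A parameter combination is invalid (lag too long, bad overlap, ...)."""


class InsufficientDataError(ConfdynError):
    """Not enough frames/transitions to estimate the requested quantity."""


class DegenerateSignalError(ConfdynError):
    """A time series has zero variance where variation is required."""


class IntegratorError(ConfdynError):
    """The Brownian integrator diverged; a smaller time step is needed."""


class BandwidthError(ConfdynError):
    """A kernel bandwidth left the similarity graph numerically disconnected."""


class EstimationError(ConfdynError):
    """A statistical estimate could not be formed (e.g. empty count matrix)."""
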