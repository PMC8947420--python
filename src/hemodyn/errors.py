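"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`HemodynError`
so callers can catch domain errors without masking programming errors.
"""


class HemodynError(Exception):
    """Base class for all hemodyn errors."""


class InvalidSpecError(HemodynError, ValueError):
    """A generator or run specification violates its contract."""


class StabilityError(HemodynError, ValueError):
    """A difference-equation discretization would be unstable."""


class SignalFormatError(HemodynError, ValueError):
    """A signal file or array violates the expected format."""


class ParameterError(HemodynError, ValueError):
    """A stage parameter is out of its valid range."""


class AlignmentError(HemodynError, ValueError):
    """Two signals that must share a grid do not."""


class BeatDetectionError(HemodynError, RuntimeError):
    """Heartbeat detection failed or produced too few beats."""


class DegenerateRangeError(HemodynError, ValueError):
    """A signal is constant where a non-degenerate range is required."""


class TrainingError(HemodynError, RuntimeError):
    """Model fitting failed (degenerate targets, solver failure)."""


class DivergenceError(HemodynError, RuntimeError):
    """A free-run simulation produced non-finite or unbounded output."""


class InsufficientWindowError(HemodynError, ValueError):
    """A step response does not cover the required analysis window."""


class DistributionError(HemodynError, ValueError):
    """A vector that must be a probability distribution is not."""


class DecompositionError(HemodynError, ValueError):
    """Requested wavelet decomposition depth exceeds what the signal allows."""


class DesignError(HemodynError, ValueError):
    """A statistical design is incomplete or unbalanced."""


class SampleSizeError(HemodynError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigError(HemodynError, ValueError):
    """Run configuration fails schema validation."""
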