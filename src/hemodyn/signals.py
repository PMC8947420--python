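"""Core in-memory containers for evenly sampled and beat-indexed signals."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SignalFormatError


@dataclass
class UniformSignal:
    """An evenly sampled scalar time series.

    Parameters
    ----------
    values : ndarray
        Sample values.
    dt : float
        Sampling interval in seconds (must be positive).
    units : str
        Physical units label (e.g. ``"mmHg"``, ``"cm/s"``).
    t0 : float
        Time of the first sample, in seconds from recording start.
    """

    values: np.ndarray
    dt: float
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SignalFormatError("signal values must be one-dimensional")
        if self.values.size < 2:
            raise SignalFormatError("a signal needs at least two samples")
        if not self.dt > 0:
            raise ParameterError(f"sampling interval must be positive, got {self.dt}")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Time spanned from first to last sample, in seconds."""
        return (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.n)

    def with_values(self, values: np.ndarray) -> "UniformSignal":
        """Copy of this signal carrying new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "UniformSignal":
        return replace(self, values=self.values.copy())


@dataclass
class BeatSeries:
    """Per-heartbeat times and beat-averaged values.

    ``beat_times`` are anchored at the upstroke of each beat.  ``landmarks``
    holds the sample indices of the (upstroke, max, min) points located on
    the pressure waveform during detection; it is carried along so that a
    derived channel average can be audited against the raw waveform.
    """

    beat_times: np.ndarray
    values: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    units: str = ""

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.beat_times.size != self.values.size:
            raise SignalFormatError("beat_times and values must have equal length")
        if self.beat_times.size >= 2 and not np.all(np.diff(self.beat_times) > 0):
            raise SignalFormatError("beat_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.beat_times.size

    def mean_interval(self) -> float:
        """Mean inter-beat interval in seconds."""
        if self.n < 2:
            raise SignalFormatError("need at least two beats for an interval")
        return float(np.mean(np.diff(self.beat_times)))
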