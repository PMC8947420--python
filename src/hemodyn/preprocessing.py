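"""Raw-signal conditioning chain for pulsatile BP/BFV recordings.

Fixed stage order: spline gap repair -> Hampel outlier removal -> zero-phase
low-pass -> beat detection (on BP) -> beat averaging -> uniform resampling
-> min-max normalization.  Long dropouts (> 4 samples) are repaired by cubic
spline through the surrounding valid samples; short spikes are left to the
Hampel median filter.  Beat averages are taken over half-open
[upstroke_i, upstroke_{i+1}) intervals and resampled by cubic interpolation
onto a uniform grid (default interval 0.4 s, i.e. 2.5 Hz) before Eq-style
min-max scaling to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .errors import (
    BeatDetectionError,
    DegenerateRangeError,
    ParameterError,
    SignalFormatError,
)
from .signals import BeatSeries, UniformSignal

#: runs of masked samples longer than this go to spline repair
SPLINE_REPAIR_MIN_RUN = 4
#: scale factor making the median absolute deviation a consistent SD estimate
MAD_SCALE = 1.4826


def _masked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def spline_repair(
    signal: UniformSignal,
    gap_mask: np.ndarray,
    context: int = 50,
) -> UniformSignal:
    """Replace long masked dropouts by natural cubic-spline interpolation.

    Only runs longer than ``SPLINE_REPAIR_MIN_RUN`` samples are repaired
    (shorter artifacts are the Hampel filter's job).  Each repaired run must
    be bordered by at least 4 valid samples on each side; the spline is fit
    on up to ``context`` valid samples per side.
    """
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.shape != signal.values.shape:
        raise ParameterError("gap mask must match the signal shape")
    out = signal.values.copy()
    for start, stop in _masked_runs(gap_mask):
        if stop - start <= SPLINE_REPAIR_MIN_RUN:
            continue
        left = np.flatnonzero(~gap_mask[:start])
        right = np.flatnonzero(~gap_mask[stop:]) + stop
        if left.size < 4 or right.size < 4:
            raise SignalFormatError(
                f"gap [{start}:{stop}] touches the signal boundary; cannot repair"
            )
        support = np.concatenate((left[-context:], right[:context]))
        cs = CubicSpline(support, out[support], bc_type="natural")
        out[start:stop] = cs(np.arange(start, stop))
    return signal.with_values(out)


def hampel_filter(
    signal: UniformSignal,
    window_halfwidth: int = 10,
    n_mad: float = 3.0,
) -> UniformSignal:
    """Sliding-window median outlier filter.

    A sample is replaced by its window median when it deviates from that
    median by more than ``n_mad`` scaled median absolute deviations.  Edges
    are handled by reflecting the signal so every sample sees a full window.
    """
    if window_halfwidth < 1:
        raise ParameterError("window halfwidth must be at least 1")
    x = signal.values
    w = 2 * window_halfwidth + 1
    if w > x.size:
        raise ParameterError(
            f"window of {w} samples exceeds the signal length {x.size}"
        )
    padded = np.pad(x, window_halfwidth, mode="reflect")
    windows = sliding_window_view(padded, w)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    bad = np.abs(x - med) > n_mad * MAD_SCALE * mad
    out = np.where(bad, med, x)
    return signal.with_values(out)


def lowpass_zero_phase(signal: UniformSignal, cutoff_hz: float = 20.0) -> UniformSignal:
    """Zero-phase low-pass: 4th-order Butterworth run forward and backward.

    The two passes give an 8th-order magnitude response and cancel the phase
    exactly (the push-pull arrangement).
    """
    nyq = signal.fs / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ParameterError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    b, a = butter(4, cutoff_hz / nyq)
    return signal.with_values(filtfilt(b, a, signal.values))


def detect_beats(
    bp: UniformSignal,
    min_hr_hz: float = 0.67,
    max_hr_hz: float = 3.0,
) -> BeatSeries:
    """Locate heartbeats on a filtered BP waveform.

    End-diastolic minima are found first (refractory spacing 1/max_hr);
    the upstroke of each beat is the point of maximum positive derivative
    between successive minima, and the systolic max is the largest sample in
    the same span.  Beat times are anchored at the upstroke.
    """
    if not (0 < min_hr_hz < max_hr_hz):
        raise ParameterError("heart-rate bounds must satisfy 0 < min < max")
    x = bp.values
    refractory = max(1, int(round(bp.fs / max_hr_hz)))
    amp = np.percentile(x, 90) - np.percentile(x, 10)
    minima, _ = find_peaks(-x, distance=refractory, prominence=0.25 * amp)
    if minima.size < 3:
        raise BeatDetectionError(f"only {minima.size} beats found; need at least 3")
    dx = np.gradient(x)

    def _upstrokes_for(mins: np.ndarray) -> np.ndarray:
        ups = np.empty(mins.size - 1, dtype=int)
        for i in range(mins.size - 1):
            ups[i] = mins[i] + int(np.argmax(dx[mins[i] : mins[i + 1]]))
        return ups

    # a false minimum (e.g. an artifact notch on a systolic rise) yields two
    # upstrokes inside one cycle; enforce the refractory period by merging
    # the offending intervals
    minima = np.asarray(minima)
    upstrokes = _upstrokes_for(minima)
    while upstrokes.size >= 2:
        gaps = np.diff(upstrokes)
        short = np.flatnonzero(gaps < refractory)
        if short.size == 0:
            break
        minima = np.delete(minima, short[0] + 1)
        if minima.size < 3:
            raise BeatDetectionError("too few beats after refractory merging")
        upstrokes = _upstrokes_for(minima)
    maxima = np.empty(minima.size - 1, dtype=int)
    for i in range(minima.size - 1):
        maxima[i] = minima[i] + int(np.argmax(x[minima[i] : minima[i + 1]]))
    beat_times = bp.t0 + upstrokes * bp.dt
    rate = (upstrokes.size - 1) / (beat_times[-1] - beat_times[0])
    if not (min_hr_hz * 0.8 <= rate <= max_hr_hz * 1.2):
        raise BeatDetectionError(f"detected beat rate {rate:.2f} Hz is implausible")
    return BeatSeries(
        beat_times=beat_times,
        values=x[upstrokes],
        landmarks={"upstroke": upstrokes, "max": maxima, "min": minima[:-1]},
        units=bp.units,
    )


def beat_average(channel: UniformSignal, beats: BeatSeries) -> BeatSeries:
    """Per-beat mean of a channel over [upstroke_i, upstroke_{i+1}).

    The last detected beat has no closing upstroke and is dropped.
    """
    ups = beats.landmarks.get("upstroke")
    if ups is None:
        ups = np.round((beats.beat_times - channel.t0) / channel.dt).astype(int)
    if ups.size < 2:
        raise BeatDetectionError("need at least two upstrokes to average a beat")
    if ups[0] < 0 or ups[-1] > channel.n:
        raise BeatDetectionError("beats fall outside the channel time range")
    means = np.empty(ups.size - 1)
    for i in range(ups.size - 1):
        seg = channel.values[ups[i] : ups[i + 1]]
        if seg.size == 0:
            raise BeatDetectionError(f"empty beat interval at beat {i}")
        means[i] = seg.mean()
    return BeatSeries(
        beat_times=beats.beat_times[:-1],
        values=means,
        landmarks={k: v[:-1] if v.size == ups.size else v for k, v in beats.landmarks.items()},
        units=channel.units,
    )


def hampel_beats(beats: BeatSeries, window_halfwidth: int = 5, n_mad: float = 4.0) -> BeatSeries:
    """Hampel pass over beat means (beat-domain artifact rejection).

    An artifact that coincides with a systolic upstroke can slip through the
    sample-domain filter (the window's deviation scale explodes on the steep
    rise) and corrupt one beat average; because min-max normalization is
    driven entirely by the extremes, a single bad beat would then rescale
    the whole channel.  Beat means are therefore screened once more in the
    beat domain before resampling.
    """
    if beats.n < 2 * window_halfwidth + 1:
        return beats
    cleaned = hampel_filter(
        UniformSignal(values=beats.values, dt=1.0, units=beats.units),
        window_halfwidth,
        n_mad,
    )
    return BeatSeries(
        beat_times=beats.beat_times,
        values=cleaned.values,
        landmarks=beats.landmarks,
        units=beats.units,
    )


def resample_uniform(beats: BeatSeries, dt_out: float = 0.4) -> UniformSignal:
    """Cubic interpolation of beat means onto a uniform grid.

    The default interval of 0.4 s (2.5 Hz) keeps the 3-6 s autoregulation
    recovery window well resolved.  The grid spans first to last beat time.
    """
    if dt_out <= 0:
        raise ParameterError(f"output interval must be positive, got {dt_out}")
    if beats.n < 4:
        raise BeatDetectionError("need at least 4 beats to resample")
    cs = CubicSpline(beats.beat_times, beats.values)
    t0 = beats.beat_times[0]
    n = int(np.floor((beats.beat_times[-1] - t0) / dt_out)) + 1
    grid = t0 + dt_out * np.arange(n)
    return UniformSignal(values=cs(grid), dt=dt_out, units=beats.units, t0=float(t0))


def minmax_normalize(signal: UniformSignal) -> UniformSignal:
    """Min-max scale to [-1, 1]: x' = 2 (x - xmin)/(xmax - xmin) - 1."""
    xmin = signal.values.min()
    xmax = signal.values.max()
    if xmax <= xmin:
        raise DegenerateRangeError("cannot normalize a constant signal")
    out = 2.0 * (signal.values - xmin) / (xmax - xmin) - 1.0
    sig = signal.with_values(out)
    sig.units = "normalized"
    return sig


@dataclass
class PreprocessConfig:
    """Stage parameters of the conditioning chain, with field defaults."""

    hampel_halfwidth: int = 10
    hampel_n_mad: float = 3.0
    lowpass_cutoff_hz: float = 20.0
    min_hr_hz: float = 0.67
    max_hr_hz: float = 3.0
    beat_hampel_halfwidth: int = 5
    beat_hampel_n_mad: float = 4.0
    resample_dt_s: float = 0.4
    normalize: bool = True


def preprocess_pair(
    bp: UniformSignal,
    bfv: UniformSignal,
    cfg: PreprocessConfig | None = None,
    bp_gap_mask: np.ndarray | None = None,
    bfv_gap_mask: np.ndarray | None = None,
) -> tuple[UniformSignal, UniformSignal, BeatSeries]:
    """Run the full chain on a BP/BFV pair.

    Beats are detected on the conditioned BP and applied to both channels so
    the outputs share one uniform grid.  Returns (bp_out, bfv_out,
    bp_beat_series); outputs are normalized to [-1, 1] unless disabled.
    """
    cfg = cfg or PreprocessConfig()
    if abs(bp.dt - bfv.dt) > 1e-9 or bp.n != bfv.n:
        raise ParameterError("BP and BFV must share the raw sampling grid")
    chans = {}
    for name, sig, mask in (("bp", bp, bp_gap_mask), ("bfv", bfv, bfv_gap_mask)):
        if mask is not None:
            sig = spline_repair(sig, mask)
        sig = hampel_filter(sig, cfg.hampel_halfwidth, cfg.hampel_n_mad)
        sig = lowpass_zero_phase(sig, cfg.lowpass_cutoff_hz)
        chans[name] = sig
    beats = detect_beats(chans["bp"], cfg.min_hr_hz, cfg.max_hr_hz)
    out = {}
    for name in ("bp", "bfv"):
        means = beat_average(chans[name], beats)
        means = hampel_beats(means, cfg.beat_hampel_halfwidth, cfg.beat_hampel_n_mad)
        sig = resample_uniform(means, cfg.resample_dt_s)
        if cfg.normalize:
            sig = minmax_normalize(sig)
        out[name] = sig
    return out["bp"], out["bfv"], beats
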