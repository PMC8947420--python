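"""Synthetic cerebral-hemodynamics generator.

Emulates the statistical structure of a posture-change study: per subject
and posture, five minutes of pulsatile arterial blood pressure (BP, mmHg)
sampled at 100 Hz, and a cerebral blood-flow-velocity channel (BFV, cm/s)
produced from that BP through the Tiecks second-order autoregulation model
at a chosen grade, plus measurement noise and artifacts.

The BP waveform is a clipped raised-cosine pulse train (distinct upstroke /
systolic-max / end-diastolic-min landmarks for beat detection) riding on
posture-specific baselines, with respiratory (~0.25 Hz) and Mayer-wave
(~0.10 Hz) oscillations, 1/f background noise, and optional isolated spike
outliers.  Every generator is a pure function of its seed.

Posture baselines default to the group means of a young-adult cohort
(lay/sit/stand BP 74.96/81.45/84.81 mmHg; BFV 59.27/52.88/53.50 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DecompositionError, InvalidSpecError
from .signals import UniformSignal
from . import tiecks
from .tiecks import TiecksParams, params_for_grade

POSTURES = ("lay", "sit", "stand")

#: posture -> mean arterial pressure baseline, mmHg
BP_BASELINE = {"lay": 74.96, "sit": 81.45, "stand": 84.81}
#: posture -> mean flow-velocity baseline, cm/s
BFV_BASELINE = {"lay": 59.27, "sit": 52.88, "stand": 53.50}

#: fraction of the cardiac cycle occupied by the systolic pulse
SYSTOLIC_FRACTION = 0.35
#: fall of the pressure floor across one cycle (systole to end-diastole);
#: large enough that the end-diastolic minimum stays pinned to the pulse
#: foot against respiratory/Mayer baseline sway, as in real arterial traces
DIASTOLIC_DECAY = 8.0
RESP_FREQ_HZ = 0.25
MAYER_FREQ_HZ = 0.10
RESP_AMP_MMHG = 1.5
MAYER_AMP_MMHG = 2.5
#: band of the very-low-frequency baseline drift, Hz
DRIFT_BAND_HZ = (0.01, 0.08)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    ``heart_rate_hz`` may be a single rate applied to everyone or ``None``,
    in which case each subject receives a rate drawn uniformly from
    ``heart_rate_range``.  ``ari_grade_per_posture`` maps posture labels to
    the true autoregulation grade used to generate BFV.
    """

    n_subjects: int = 6
    postures: tuple[str, ...] = POSTURES
    duration_s: float = 300.0
    fs_raw: float = 100.0
    heart_rate_hz: float | None = None
    heart_rate_range: tuple[float, float] = (0.9, 1.25)
    ari_grade_per_posture: dict[str, int] = field(
        default_factory=lambda: {"lay": 5, "sit": 5, "stand": 5}
    )
    pulse_pressure_mmhg: float = 40.0
    drift_sd_mmhg: float = 3.0
    noise_sd: float = 0.02
    outlier_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_raw <= 0:
            raise InvalidSpecError("duration and sampling rate must be positive")
        if self.n_subjects < 1:
            raise InvalidSpecError("need at least one subject")
        for p in self.postures:
            if p not in POSTURES:
                raise InvalidSpecError(f"unknown posture {p!r}")
        for p, g in self.ari_grade_per_posture.items():
            if g not in tiecks.TIECKS_TABLE:
                raise InvalidSpecError(f"ARI grade for {p!r} must be in 0..9, got {g}")
        hi_hr = self.heart_rate_hz or self.heart_rate_range[1]
        if self.fs_raw <= 2 * hi_hr:
            raise InvalidSpecError("sampling rate must exceed twice the cardiac frequency")
        if not (0 <= self.noise_sd < 1):
            raise InvalidSpecError("noise_sd is a fraction of signal SD in [0, 1)")
        if not (0 <= self.outlier_rate < 0.05):
            raise InvalidSpecError("outlier_rate must be a small fraction of samples")

    def subject_heart_rate(self, subject: int) -> float:
        if self.heart_rate_hz is not None:
            return float(self.heart_rate_hz)
        rng = np.random.default_rng([self.seed, subject, 101])
        lo, hi = self.heart_rate_range
        return float(rng.uniform(lo, hi))


def bp_waveform(
    duration_s: float,
    fs: float,
    heart_rate_hz: float,
    mean_bp: float,
    pulse_pressure: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pulsatile component of the BP signal.

    Returns ``(values, onset_times)`` where ``onset_times`` is the schedule
    of pulse feet (ground truth for beat-detection tests).  The waveform is,
    within each cardiac cycle of phase ``phi in [0, 1)``::

        p(phi) = diastolic + DIASTOLIC_DECAY * (1 - phi) + A * w(phi)
        w(phi) = 0.5 * (1 - cos(2 pi phi / s))   for phi < s, else 0

    with systolic fraction ``s``; amplitude ``A`` and the diastolic floor are
    solved so that the cycle maximum equals the systolic pressure and the
    cycle mean equals ``mean_bp``.
    """
    if duration_s <= 0 or fs <= 0 or heart_rate_hz <= 0:
        raise InvalidSpecError("duration, rate and heart rate must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    s = SYSTOLIC_FRACTION
    delta = DIASTOLIC_DECAY
    amp = pulse_pressure - delta * (1.0 - s / 2.0)
    # cycle mean = diastolic + delta/2 + amp * s/2  ->  solve for diastolic
    diastolic = mean_bp - delta / 2.0 - amp * s / 2.0
    phase = np.mod(t * heart_rate_hz, 1.0)
    w = np.where(phase < s, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / s)), 0.0)
    values = diastolic + delta * (1.0 - phase) + amp * w
    onsets = np.arange(0.0, duration_s - 1.0 / fs, 1.0 / heart_rate_hz)
    return values, onsets


def _baseline_drift(
    t: np.ndarray, sd: float, rng: np.random.Generator, band: tuple[float, float] = DRIFT_BAND_HZ
) -> np.ndarray:
    """Very-low-frequency baseline wander as a random-phase sinusoid sum.

    Spontaneous arterial pressure carries substantial power below 0.1 Hz;
    it is this band that probes the autoregulation plateau (the steady-state
    gain), so the generator must supply it.  Twelve equally spaced tones in
    ``band`` with random phases and 1/f-weighted amplitudes are scaled to
    standard deviation ``sd``.
    """
    if sd <= 0:
        return np.zeros_like(t)
    freqs = np.linspace(band[0], band[1], 12)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    amps = 1.0 / freqs
    x = np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    return x * (sd / x.std())


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with ~1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _inject_outliers(
    values: np.ndarray, rate: float, rng: np.random.Generator, max_run: int = 3
) -> np.ndarray:
    """Add isolated +/-5 SD spikes covering ~``rate`` of all samples.

    Spike runs are at most ``max_run`` consecutive samples (short enough for
    a median filter; longer dropouts are the business of spline repair) and
    are kept at least 50 samples apart so each sits alone in its window.
    """
    n = values.size
    n_bad = int(round(rate * n))
    if n_bad == 0:
        return values
    out = values.copy()
    sd = values.std()
    placed = 0
    taken = np.zeros(n, dtype=bool)
    guard = 50
    attempts = 0
    while placed < n_bad and attempts < 100 * n_bad:
        attempts += 1
        run = int(rng.integers(1, max_run + 1))
        run = min(run, n_bad - placed)
        start = int(rng.integers(guard, n - guard - run))
        lo, hi = max(0, start - guard), min(n, start + run + guard)
        if taken[lo:hi].any():
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[start : start + run] += sign * 5.0 * sd
        taken[lo:hi] = True
        placed += run
    return out


def generate_bp(spec: SyntheticCohortSpec, subject: int, posture: str) -> UniformSignal:
    """Raw pulsatile BP for one subject and posture (seed-deterministic)."""
    signal, _ = generate_bp_with_truth(spec, subject, posture)
    return signal


def generate_bp_with_truth(
    spec: SyntheticCohortSpec, subject: int, posture: str
) -> tuple[UniformSignal, dict]:
    """As :func:`generate_bp` but also return the ground-truth construction.

    The truth dict carries the pulse-onset schedule, heart rate and the
    deterministic (noise- and outlier-free) waveform, for oracle tests.
    """
    if posture not in POSTURES:
        raise InvalidSpecError(f"unknown posture {posture!r}")
    hr = spec.subject_heart_rate(subject)
    mean_bp = BP_BASELINE[posture]
    pulse, onsets = bp_waveform(
        spec.duration_s, spec.fs_raw, hr, mean_bp, spec.pulse_pressure_mmhg
    )
    n = pulse.size
    t = np.arange(n) / spec.fs_raw
    slow = RESP_AMP_MMHG * np.sin(2 * np.pi * RESP_FREQ_HZ * t) + MAYER_AMP_MMHG * np.sin(
        2 * np.pi * MAYER_FREQ_HZ * t
    )
    deterministic = pulse + slow
    rng = np.random.default_rng([spec.seed, subject, POSTURES.index(posture), 7])
    # physiologic pressure: waveform + VLF drift + 1/f variability.  Sensor
    # artifacts (spikes) are added afterwards and must NOT drive the
    # flow-generating model — they are measurement error, not physiology.
    physiologic = deterministic + _baseline_drift(t, spec.drift_sd_mmhg, rng)
    if spec.noise_sd > 0:
        physiologic = physiologic + spec.noise_sd * deterministic.std() * _one_over_f_noise(
            n, rng
        )
    values = _inject_outliers(physiologic, spec.outlier_rate, rng)
    truth = {
        "heart_rate_hz": hr,
        "onset_times": onsets,
        "deterministic": deterministic,
        "physiologic": physiologic,
        "mean_bp": mean_bp,
    }
    return UniformSignal(values=values, dt=1.0 / spec.fs_raw, units="mmHg"), truth


def tiecks_bfv(
    bp: UniformSignal,
    params: TiecksParams,
    baseline_v: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    bp_baseline: float | None = None,
    ccp: float = tiecks.DEFAULT_CCP_MMHG,
) -> UniformSignal:
    """BFV generated from a BP signal through the Tiecks recursion.

    ``bp_baseline`` defaults to the mean of the input pressure.  Additive
    Gaussian noise has standard deviation ``noise_sd * baseline_v``;
    ``noise_sd = 0`` makes the output a deterministic function of the input.
    """
    if baseline_v <= 0:
        raise InvalidSpecError(f"baseline velocity must be positive, got {baseline_v}")
    base_p = float(np.mean(bp.values)) if bp_baseline is None else float(bp_baseline)
    dp = tiecks.pressure_deviation(bp.values, base_p, ccp)
    frac = tiecks.flow_fraction(dp, params, bp.dt)
    v = baseline_v * frac
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 13])
        v = v + noise_sd * baseline_v * rng.standard_normal(v.size)
    return UniformSignal(values=v, dt=bp.dt, units="cm/s", t0=bp.t0)


def negative_step(
    duration_s: float,
    fs: float,
    step_time_s: float,
    pre_level: float,
    post_level: float,
) -> UniformSignal:
    """Piecewise-constant negative pressure step.

    The boundary sample at ``step_time_s`` is assigned to the post level.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidSpecError("duration and rate must be positive")
    if not (0 < step_time_s < duration_s):
        raise InvalidSpecError("step time must lie strictly inside the record")
    if post_level >= pre_level:
        raise InvalidSpecError("a negative step requires post_level < pre_level")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    values = np.where(t < step_time_s, pre_level, post_level)
    return UniformSignal(values=values, dt=1.0 / fs)


def scale_concentrated_signal(
    level_j: int, length: int, wavelet_name: str = "db4"
) -> UniformSignal:
    """Signal whose wavelet energy is a point mass at detail level ``j``.

    Built by inverse-transforming a coefficient array that is zero except
    for one unit detail coefficient at level ``j`` (periodized transform, so
    orthogonal wavelets on dyadic lengths leak no energy across bands).
    """
    if 2**level_j >= length:
        raise DecompositionError(
            f"level {level_j} is too deep for a signal of length {length}"
        )
    wavelet = pywt.Wavelet(wavelet_name)
    coeffs = pywt.wavedec(
        np.zeros(length), wavelet, mode="periodization", level=level_j
    )
    detail = coeffs[1]  # detail coefficients at level j
    detail[detail.size // 2] = 1.0
    values = pywt.waverec(coeffs, wavelet, mode="periodization")[:length]
    return UniformSignal(values=values, dt=1.0)


def band_weighted_signal(
    weights: np.ndarray,
    length: int,
    wavelet_name: str = "db4",
    seed: int = 0,
) -> UniformSignal:
    """Random signal whose detail-band energies follow ``weights``.

    ``weights[j-1]`` is the target relative energy of detail level ``j``
    (finest = 1).  Gaussian coefficients are drawn per band and rescaled so
    each band's energy matches its weight; the approximation band is zero.
    Used to synthesize groups with controlled entropy/complexity.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise InvalidSpecError("band weights must be non-negative and not all zero")
    m = weights.size
    if 2**m >= length:
        raise DecompositionError(f"{m} levels is too deep for length {length}")
    rng = np.random.default_rng([seed, 29])
    wavelet = pywt.Wavelet(wavelet_name)
    coeffs = pywt.wavedec(np.zeros(length), wavelet, mode="periodization", level=m)
    # coeffs[0] approx at level m; coeffs[i] detail at level m - i + 1
    for i in range(1, m + 1):
        level = m - i + 1
        c = rng.standard_normal(coeffs[i].size)
        energy = np.sum(c**2)
        target = weights[level - 1] / weights.sum()
        coeffs[i][:] = c * np.sqrt(target / energy) if energy > 0 else 0.0
    values = pywt.waverec(coeffs, wavelet, mode="periodization")[:length]
    return UniformSignal(values=values, dt=1.0)


def random_gap_mask(
    n: int,
    n_gaps: int,
    gap_len: int,
    seed: int = 0,
    margin: int = 20,
) -> np.ndarray:
    """Boolean mask with ``n_gaps`` runs of ``gap_len`` invalid samples.

    Gap runs longer than 4 samples exercise the spline-repair stage; they
    are placed away from the signal boundary so repair has valid context.
    """
    if gap_len < 1 or n_gaps < 0:
        raise InvalidSpecError("gap count and length must be positive")
    if n_gaps * (gap_len + 2 * margin) > n:
        raise InvalidSpecError("gaps do not fit in the signal")
    rng = np.random.default_rng([seed, 31])
    mask = np.zeros(n, dtype=bool)
    placed = 0
    while placed < n_gaps:
        start = int(rng.integers(margin, n - margin - gap_len))
        lo, hi = start - margin, start + gap_len + margin
        if mask[max(0, lo) : hi].any():
            continue
        mask[start : start + gap_len] = True
        placed += 1
    return mask


def generate_cohort(spec: SyntheticCohortSpec, outdir) -> "CohortManifest":
    """Write per-subject, per-posture CSV recordings plus a YAML manifest."""
    from pathlib import Path

    from .signal_io import CohortManifest, RecordingManifest, write_manifest, write_signal_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest(root=str(outdir))
    for subject in range(spec.n_subjects):
        sid = f"S{subject:02d}"
        for posture in spec.postures:
            grade = spec.ari_grade_per_posture.get(posture, 5)
            bp, truth = generate_bp_with_truth(spec, subject, posture)
            bp_physio = UniformSignal(
                values=truth["physiologic"], dt=bp.dt, units="mmHg", t0=bp.t0
            )
            bfv = tiecks_bfv(
                bp_physio,
                params_for_grade(grade),
                baseline_v=BFV_BASELINE[posture],
                noise_sd=spec.noise_sd,
                seed=int(np.random.default_rng([spec.seed, subject, POSTURES.index(posture), 17]).integers(2**31)),
                bp_baseline=truth["mean_bp"],
            )
            rel = f"{sid}_{posture}.csv"
            write_signal_csv(outdir / rel, {"bp_mmHg": bp, "bfv_cm_s": bfv})
            manifest.recordings.append(
                RecordingManifest(
                    subject_id=sid,
                    posture=posture,
                    bp_file=rel,
                    bfv_files=[rel],
                    hemisphere="merged",
                    true_ari=grade,
                    heart_rate_hz=truth["heart_rate_hz"],
                )
            )
    write_manifest(manifest, outdir / "manifest.yaml")
    return manifest
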