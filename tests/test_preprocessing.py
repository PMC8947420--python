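"""Conditioning chain: gap repair, outlier removal, filtering, beat
detection, beat averaging, resampling and normalization."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import hemodyn as hd
from hemodyn.errors import (
    BeatDetectionError,
    DegenerateRangeError,
    ParameterError,
    SignalFormatError,
)
from hemodyn.signals import BeatSeries, UniformSignal
from hemodyn.preprocessing import (
    beat_average,
    detect_beats,
    hampel_filter,
    hampel_beats,
    lowpass_zero_phase,
    minmax_normalize,
    preprocess_pair,
    resample_uniform,
    spline_repair,
)
from hemodyn.synthetic import generate_bp_with_truth


def sig(values, dt=0.01, **kw):
    return UniformSignal(values=np.asarray(values, float), dt=dt, **kw)


class TestSplineRepair:
    def test_quadratic_reproduced_exactly(self):
        x = np.arange(100.0)
        s = sig(0.5 * x**2 - 3 * x + 2)
        mask = np.zeros(100, dtype=bool)
        mask[40:46] = True  # 6-sample gap
        out = spline_repair(s, mask)
        assert np.allclose(out.values, s.values, atol=1e-9)

    def test_empty_mask_is_identity(self):
        s = sig(np.random.default_rng(0).normal(size=50))
        out = spline_repair(s, np.zeros(50, dtype=bool))
        assert np.array_equal(out.values, s.values)

    def test_short_runs_left_to_hampel(self):
        s = sig(np.ones(50))
        corrupted = s.values.copy()
        corrupted[10:13] = 99.0
        s2 = sig(corrupted)
        mask = np.zeros(50, dtype=bool)
        mask[10:13] = True  # 3 samples <= 4: untouched
        out = spline_repair(s2, mask)
        assert np.array_equal(out.values, corrupted)

    def test_boundary_gap_unrepairable(self):
        s = sig(np.ones(50))
        mask = np.zeros(50, dtype=bool)
        mask[:6] = True
        with pytest.raises(SignalFormatError, match="boundary"):
            spline_repair(s, mask)

    def test_sinusoid_gap_against_dense_spline_oracle(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 0.1 * t)
        mask = np.zeros(t.size, dtype=bool)
        mask[500:510] = True
        out = spline_repair(sig(x), mask)
        # independent oracle: scipy spline through the same valid support
        valid = ~mask
        oracle = CubicSpline(np.flatnonzero(valid), x[valid])(np.arange(t.size))
        assert np.max(np.abs(out.values[mask] - x[mask])) < 1e-4
        assert np.max(np.abs(out.values[mask] - oracle[mask])) < 1e-4


class TestHampel:
    def test_single_spike_on_constant(self):
        x = np.full(100, 5.0)
        x[50] = 30.0
        out = hampel_filter(sig(x), window_halfwidth=5, n_mad=3.0)
        assert out.values[50] == 5.0

    def test_clean_ramp_untouched(self):
        x = np.linspace(0, 1, 200)
        out = hampel_filter(sig(x), window_halfwidth=10, n_mad=3.0)
        assert np.array_equal(out.values, x)

    def test_against_brute_force_oracle(self):
        # bounded (uniform) jitter: with unbounded noise some clean samples
        # would legitimately exceed any MAD threshold
        rng = np.random.default_rng(42)
        t = np.arange(1000) * 0.01
        x = np.sin(2 * np.pi * 0.25 * t) + 0.05 * rng.uniform(-1, 1, 1000)
        spike_idx = rng.choice(np.arange(50, 950), size=10, replace=False)
        x[spike_idx] += np.where(rng.random(10) < 0.5, 5.0, -5.0)
        out = hampel_filter(sig(x), window_halfwidth=10, n_mad=3.0)
        # brute-force sliding median/MAD with the same reflect padding
        pad = np.pad(x, 10, mode="reflect")
        changed = []
        for i in range(1000):
            w = pad[i : i + 21]
            med = np.median(w)
            mad = np.median(np.abs(w - med))
            if abs(x[i] - med) > 3.0 * 1.4826 * mad:
                changed.append(i)
        assert set(np.flatnonzero(out.values != x)) == set(changed)
        assert set(spike_idx).issubset(set(changed))
        false_pos = set(changed) - set(spike_idx)
        assert not false_pos

    def test_window_larger_than_signal(self):
        with pytest.raises(ParameterError):
            hampel_filter(sig(np.ones(5)), window_halfwidth=10)


class TestLowpass:
    def test_passband_tone_amplitude_and_phase(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t)
        out = lowpass_zero_phase(sig(x), cutoff_hz=20.0)
        mid = slice(200, 800)
        assert np.abs(out.values[mid]).max() == pytest.approx(1.0, rel=0.01)
        xc = np.correlate(out.values[mid], x[mid], mode="full")
        lag = int(np.argmax(xc)) - (len(x[mid]) - 1)
        assert lag == 0  # zero phase

    def test_stopband_attenuation_matches_butterworth(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 40.0 * t)
        out = lowpass_zero_phase(sig(x), cutoff_hz=20.0)
        # two 4th-order passes: |H|^2 = 1/(1 + (f/fc)^8) at f = 2 fc
        bound = 1.0 / (1.0 + 2.0**8)
        assert np.abs(out.values[300:700]).max() <= bound * 1.5

    def test_dc_preserved(self):
        out = lowpass_zero_phase(sig(np.full(500, 3.3)), cutoff_hz=20.0)
        assert np.allclose(out.values, 3.3, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_zero_phase(sig(np.ones(100)), cutoff_hz=60.0)


class TestBeatDetection:
    def test_beat_count_and_rate(self, clean_spec):
        bp, truth = generate_bp_with_truth(clean_spec, 0, "lay")
        beats = detect_beats(lowpass_zero_phase(bp))
        assert beats.n == pytest.approx(72, abs=2)  # 60 s at 1.2 Hz
        rate = 1.0 / beats.mean_interval()
        assert rate == pytest.approx(truth["heart_rate_hz"], rel=0.01)

    def test_foot_landmarks_match_schedule(self):
        spec = hd.SyntheticCohortSpec(
            n_subjects=1,
            postures=("lay",),
            duration_s=60.0,
            heart_rate_hz=1.2,
            noise_sd=0.05,
            drift_sd_mmhg=0.0,
            outlier_rate=0.0,
            seed=13,
        )
        bp, truth = generate_bp_with_truth(spec, 0, "lay")
        filtered = lowpass_zero_phase(hampel_filter(bp))
        beats = detect_beats(filtered)
        from hemodyn.synthetic import SYSTOLIC_FRACTION

        up_times = beats.landmarks["upstroke"] * bp.dt
        # the scheduled steepest-rise instant: onset + quarter of the
        # systolic segment (raised-cosine upstroke)
        sched = truth["onset_times"] + SYSTOLIC_FRACTION / 4 / 1.2
        errs = np.array(
            [abs(u - sched[np.argmin(np.abs(sched - u))]) for u in up_times[1:-1]]
        )
        # typical beat anchored to the schedule within two samples; noise
        # (5% of signal SD) legitimately jitters a few individual rises
        assert np.median(errs) <= 0.020
        assert np.quantile(errs, 0.95) <= 0.080

    def test_too_few_beats(self):
        with pytest.raises(BeatDetectionError):
            detect_beats(sig(np.sin(2 * np.pi * 1.2 * np.arange(0, 1.0, 0.01))))


class TestBeatAverage:
    def test_constant_channel(self):
        ch = sig(np.full(1000, 7.0))
        beats = BeatSeries(
            beat_times=np.array([1.0, 2.0, 3.0]),
            values=np.zeros(3),
            landmarks={"upstroke": np.array([100, 200, 300])},
        )
        out = beat_average(ch, beats)
        assert np.allclose(out.values, 7.0)
        assert out.n == 2

    def test_single_interval_gives_global_mean(self):
        x = np.random.default_rng(1).normal(size=1000)
        ch = sig(x)
        beats = BeatSeries(
            beat_times=np.array([0.0, 9.99]),
            values=np.zeros(2),
            landmarks={"upstroke": np.array([0, 1000])},
        )
        out = beat_average(ch, beats)
        assert out.values[0] == pytest.approx(x.mean())

    def test_means_match_analytic_cycle_mean(self, clean_spec):
        """Beat means of the noise-free pulse train equal the analytic cycle
        mean (posture baseline plus the integrated slow oscillations) to 1%."""
        from hemodyn.synthetic import MAYER_AMP_MMHG, MAYER_FREQ_HZ, RESP_AMP_MMHG, RESP_FREQ_HZ

        bp, truth = generate_bp_with_truth(clean_spec, 0, "lay")
        beats = detect_beats(lowpass_zero_phase(bp))
        means = beat_average(bp, beats)
        ups = beats.landmarks["upstroke"]

        def slow_integral(t0, t1):
            total = 0.0
            for amp, f in ((RESP_AMP_MMHG, RESP_FREQ_HZ), (MAYER_AMP_MMHG, MAYER_FREQ_HZ)):
                w = 2 * np.pi * f
                total += amp * (np.cos(w * t0) - np.cos(w * t1)) / (w * (t1 - t0))
            return total

        for i, m in enumerate(means.values[1:-1], start=1):
            t0, t1 = ups[i] * bp.dt, ups[i + 1] * bp.dt
            expected = truth["mean_bp"] + slow_integral(t0, t1)
            assert m == pytest.approx(expected, rel=0.01)


class TestResample:
    def test_linear_trend_reproduced(self):
        bt = np.array([0.0, 1.0, 2.1, 2.9, 4.0, 5.0])
        beats = BeatSeries(beat_times=bt, values=2.0 * bt + 1.0)
        out = resample_uniform(beats, dt_out=0.4)
        expected = 2.0 * out.times() + 1.0
        assert np.allclose(out.values, expected, atol=1e-9)

    def test_default_rate_sample_count(self):
        bt = np.arange(0.0, 300.0, 1.0)
        beats = BeatSeries(beat_times=bt, values=np.sin(bt / 20))
        out = resample_uniform(beats)
        assert abs(out.n - 748) <= 2  # (299 s span) / 0.4 s + 1
        assert out.dt == 0.4

    def test_round_trip_at_beat_interval(self):
        bt = np.arange(0.0, 50.0, 1.0)
        vals = np.cos(bt / 7.0)
        beats = BeatSeries(beat_times=bt, values=vals)
        out = resample_uniform(beats, dt_out=1.0)
        assert np.allclose(out.values, vals, atol=1e-6)

    def test_parameter_errors(self):
        beats = BeatSeries(beat_times=np.arange(5.0), values=np.ones(5))
        with pytest.raises(ParameterError):
            resample_uniform(beats, dt_out=0.0)


class TestNormalize:
    def test_three_point_example(self):
        out = minmax_normalize(sig([0.0, 5.0, 10.0]))
        assert np.allclose(out.values, [-1.0, 0.0, 1.0])

    def test_exact_bounds_and_idempotence(self):
        rng = np.random.default_rng(5)
        s = sig(rng.normal(size=300))
        once = minmax_normalize(s)
        assert once.values.min() == -1.0
        assert once.values.max() == 1.0
        twice = minmax_normalize(once)
        assert np.allclose(twice.values, once.values, atol=1e-15)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        a = minmax_normalize(sig(x)).values
        b = minmax_normalize(sig(3.7 * x + 11.0)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize(sig(np.ones(10)))


class TestChain:
    def test_beat_means_recover_baseline(self):
        """Full chain on default-noise data: beat-averaged BP within 2% of
        the configured posture baseline."""
        spec = hd.SyntheticCohortSpec(
            n_subjects=1, postures=("lay",), duration_s=120.0, seed=17
        )
        bp, truth = generate_bp_with_truth(spec, 0, "lay")
        from hemodyn.preprocessing import PreprocessConfig

        cfg = PreprocessConfig(normalize=False)
        bfv = hd.tiecks_bfv(
            hd.UniformSignal(values=truth["physiologic"], dt=bp.dt, units="mmHg"),
            hd.params_for_grade(5),
            baseline_v=59.27,
            bp_baseline=truth["mean_bp"],
        )
        p, v, _ = preprocess_pair(bp, bfv, cfg)
        assert p.values.mean() == pytest.approx(truth["mean_bp"], rel=0.02)
        assert v.values.mean() == pytest.approx(59.27, rel=0.02)

    def test_stage_lengths_preserved_until_resample(self):
        rng = np.random.default_rng(8)
        s = sig(80 + rng.normal(0, 2, 2000))
        assert hampel_filter(s).n == s.n
        assert lowpass_zero_phase(s).n == s.n
        assert spline_repair(s, np.zeros(s.n, dtype=bool)).n == s.n

    def test_beat_hampel_cleans_single_bad_beat(self):
        bt = np.arange(0.0, 60.0, 1.0)
        vals = 80 + 0.5 * np.sin(bt / 5)
        vals[30] = 140.0  # one corrupted beat mean
        beats = BeatSeries(beat_times=bt, values=vals)
        out = hampel_beats(beats)
        assert abs(out.values[30] - 80) < 2.0
        # interior beats away from the spike are untouched (edge windows see
        # reflected padding and may act on boundary trends)
        interior = np.r_[5:30, 31:55]
        assert np.array_equal(out.values[interior], vals[interior])
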