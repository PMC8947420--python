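"""Shared fixtures: small synthetic recordings and preprocessed pairs."""

import numpy as np
import pytest

import hemodyn as hd
from hemodyn.tiecks import params_for_grade


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-, drift- and artifact-free cohort spec (deterministic waveform)."""
    return hd.SyntheticCohortSpec(
        n_subjects=1,
        postures=("lay",),
        duration_s=60.0,
        heart_rate_hz=1.2,
        noise_sd=0.0,
        drift_sd_mmhg=0.0,
        outlier_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_spec():
    """Default study conditions at reduced duration for unit tests."""
    return hd.SyntheticCohortSpec(
        n_subjects=1, postures=("lay",), duration_s=120.0, seed=11
    )


def make_recording(grade: int, seed: int, duration_s: float = 300.0, noise_sd: float = 0.02):
    """One synthetic (BP, BFV) pair at a known autoregulation grade."""
    spec = hd.SyntheticCohortSpec(
        n_subjects=1,
        postures=("lay",),
        duration_s=duration_s,
        noise_sd=noise_sd,
        seed=seed,
        ari_grade_per_posture={"lay": grade},
    )
    from hemodyn.synthetic import BFV_BASELINE, generate_bp_with_truth
    from hemodyn.signals import UniformSignal

    bp, truth = generate_bp_with_truth(spec, 0, "lay")
    bp_physio = UniformSignal(values=truth["physiologic"], dt=bp.dt, units="mmHg")
    bfv = hd.tiecks_bfv(
        bp_physio,
        params_for_grade(grade),
        baseline_v=BFV_BASELINE["lay"],
        noise_sd=noise_sd,
        seed=seed + 1,
        bp_baseline=truth["mean_bp"],
    )
    return bp, bfv, truth


@pytest.fixture(scope="session")
def grade5_preprocessed():
    """Preprocessed normalized (p, v) of one grade-5 subject at 2.5 Hz."""
    bp, bfv, _ = make_recording(grade=5, seed=21)
    p, v, beats = hd.preprocess_pair(bp, bfv)
    return p, v, beats
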