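"""Dynamic nu-SVR flow models: embedding, training, free-run prediction and
grid search."""

import numpy as np
import pytest

from hemodyn.errors import AlignmentError, ParameterError, TrainingError
from hemodyn.models import (
    ModelSpec,
    default_grid,
    embed,
    free_run_predict,
    grid_search,
    pearson_cc,
    split_halves,
    train_model,
)


def rich_input(n, seed=0):
    """Multi-band excitation covering the frequencies the models must learn."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 0.4
    x = (
        np.sin(2 * np.pi * 0.02 * t)
        + 0.8 * np.sin(2 * np.pi * 0.1 * t + 1.0)
        + 0.5 * np.sin(2 * np.pi * 0.25 * t + 2.0)
        + 0.3 * rng.standard_normal(n)
    )
    return x / np.abs(x).max()


class TestEmbed:
    def test_row_and_feature_counts(self):
        p = np.arange(10.0)
        v = np.arange(10.0) * 2
        X, y = embed(p, v, n_p=2, n_v=0)
        assert X.shape == (8, 3)
        assert y.size == 8
        X2, y2 = embed(p, v, n_p=2, n_v=3)
        assert X2.shape == (7, 6)
        assert y2.size == 7

    def test_random_index_audit(self):
        rng = np.random.default_rng(3)
        p = rng.standard_normal(50)
        v = rng.standard_normal(50)
        n_p, n_v = 3, 2
        X, y = embed(p, v, n_p, n_v)
        w = max(n_p, n_v)
        for row in rng.integers(0, X.shape[0], size=10):
            n = row + w
            expected = np.concatenate(
                ([v[n - 1], v[n - 2]], [p[n], p[n - 1], p[n - 2], p[n - 3]])
            )
            assert np.array_equal(X[row], expected)
            assert y[row] == v[n]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            embed(np.arange(10.0), np.arange(9.0), 1, 1)


class TestSpecValidation:
    def test_family_order_constraints(self):
        with pytest.raises(ParameterError):
            ModelSpec("FIR", n_p=2, n_v=1)
        with pytest.raises(ParameterError):
            ModelSpec("NARX", n_p=2, n_v=0)
        with pytest.raises(ParameterError):
            ModelSpec("FIR", n_p=2, nu=1.5)

    def test_kernel_follows_family(self):
        assert ModelSpec("FIR", 2).kernel == "linear"
        assert ModelSpec("ARX", 2, 1).kernel == "linear"
        assert ModelSpec("NFIR", 2).kernel == "rbf"
        assert ModelSpec("NARX", 2, 1).kernel == "rbf"


class TestTraining:
    def test_linear_fir_recovers_two_tap_system(self):
        p = rich_input(600, seed=1)
        v = 0.8 * p + 0.2 * np.roll(p, 1)
        v[0] = 0.8 * p[0]
        spec = ModelSpec("FIR", n_p=1, C=100.0, nu=0.8)
        model = train_model(p, v, spec, dt=0.4)
        resid = model.one_step(p, v) - v[1:]
        assert np.sqrt(np.mean(resid**2)) < 1e-3

    def test_training_is_deterministic(self):
        p = rich_input(300, seed=2)
        v = np.tanh(0.9 * p + 0.3 * np.roll(p, 1))
        spec = ModelSpec("NARX", n_p=1, n_v=1, C=4.0, nu=0.5, sigma=2.0)
        m1 = train_model(p, v, spec, dt=0.4)
        m2 = train_model(p, v, spec, dt=0.4)
        X, _ = embed(p, v, 1, 1)
        assert np.array_equal(m1.predict_rows(X), m2.predict_rows(X))

    def test_nu_property_on_support_fraction(self):
        """nu lower-bounds the fraction of support vectors."""
        p = rich_input(400, seed=4)
        v = 0.7 * p + 0.1 * np.roll(p, 1)
        for nu in (0.3, 0.6):
            spec = ModelSpec("NFIR", n_p=1, C=10.0, nu=nu, sigma=2.0)
            model = train_model(p, v, spec, dt=0.4)
            frac = model.svr.support_.size / (p.size - 1)
            assert frac >= nu - 0.05

    def test_constant_targets_rejected(self):
        p = rich_input(100, seed=5)
        with pytest.raises(TrainingError):
            train_model(p, np.ones(100), ModelSpec("FIR", 2), dt=0.4)

    def test_fast_predict_matches_sklearn(self):
        p = rich_input(300, seed=6)
        v = np.tanh(p) + 0.05 * np.roll(p, 2)
        for spec in (
            ModelSpec("ARX", n_p=2, n_v=2, C=2.0, nu=0.5),
            ModelSpec("NARX", n_p=2, n_v=2, C=2.0, nu=0.5, sigma=1.5),
        ):
            model = train_model(p, v, spec, dt=0.4)
            X, _ = embed(p, v, spec.n_p, spec.n_v)
            assert np.allclose(model.predict_rows(X), model.svr.predict(X), atol=1e-10)


class TestFreeRun:
    def test_fir_free_run_equals_one_step(self):
        p = rich_input(400, seed=7)
        v = 0.6 * p + 0.3 * np.roll(p, 1)
        model = train_model(p, v, ModelSpec("FIR", n_p=1, C=50.0, nu=0.7), dt=0.4)
        free = free_run_predict(model, p)
        assert np.allclose(free, model.one_step(p, v), atol=1e-12)

    def test_narx_free_run_tracks_true_recursion(self):
        """Free run on a noise-free realizable system stays near the truth."""
        p = rich_input(500, seed=8)
        v = np.zeros(p.size)
        for n in range(1, p.size):
            v[n] = 0.6 * v[n - 1] + 0.4 * p[n]  # true recursion (oracle)
        spec = ModelSpec("NARX", n_p=0, n_v=1, C=100.0, nu=0.8, sigma=4.0)
        model = train_model(p[:400], v[:400], spec, dt=0.4)
        free = free_run_predict(model, p[400:500], v_init=v[399:400])
        rms = np.sqrt(np.mean((free - v[400:500]) ** 2))
        assert rms < 1e-2

    def test_output_length(self):
        p = rich_input(200, seed=9)
        v = 0.5 * p + 0.2 * np.roll(p, 1)
        model = train_model(p, v, ModelSpec("FIR", n_p=3, C=10.0, nu=0.5), dt=0.4)
        assert free_run_predict(model, p[:50]).size == 47

    def test_short_validation_rejected(self):
        p = rich_input(100, seed=10)
        v = 0.5 * p + 0.1 * np.roll(p, 1)
        model = train_model(p, v, ModelSpec("FIR", n_p=5, C=10.0, nu=0.5), dt=0.4)
        with pytest.raises(AlignmentError):
            free_run_predict(model, p[:4])


class TestPearson:
    def test_perfect_and_inverted(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_cc(v, v) == pytest.approx(1.0)
        assert pearson_cc(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # direct evaluation of the formula: cov = 4.5, sds = sqrt(5), sqrt(4.75)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        v_hat = np.array([1.0, 2.0, 2.0, 4.0])
        assert pearson_cc(v, v_hat) == pytest.approx(4.5 / np.sqrt(5 * 4.75), abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            pearson_cc(np.ones(5), np.arange(5.0))


class TestGridSearch:
    def test_singleton_grid_returns_that_model(self):
        p = rich_input(400, seed=11)
        v = 0.7 * p + 0.2 * np.roll(p, 1)
        spec = ModelSpec("FIR", n_p=2, C=10.0, nu=0.5)
        res = grid_search(p, v, "FIR", grid=[spec], dt=0.4)
        assert res.model.spec == spec
        assert len(res.table) == 1

    def test_enumeration_is_exhaustive(self):
        p = rich_input(300, seed=12)
        v = 0.7 * p + 0.2 * np.roll(p, 1)
        grid = [ModelSpec("FIR", n_p=k, C=10.0, nu=0.5) for k in range(1, 5)]
        res = grid_search(p, v, "FIR", grid=grid, dt=0.4)
        assert len(res.table) + res.n_failed == 4

    def test_true_orders_among_maximizers(self):
        """On a noise-free realizable system the true (n_p, n_v) wins or ties."""
        p = rich_input(600, seed=13)
        v = np.zeros(p.size)
        for n in range(2, p.size):
            v[n] = 0.5 * v[n - 1] + 0.3 * p[n] + 0.2 * p[n - 1]
        grid = [
            ModelSpec("ARX", n_p=n_p, n_v=n_v, C=100.0, nu=0.8)
            for n_p in (1, 2)
            for n_v in (1, 2)
        ]
        res = grid_search(p, v, "ARX", grid=grid, dt=0.4)
        ccs = {(s.n_p, s.n_v): cc for s, cc in res.table}
        assert max(ccs.values()) - ccs[(1, 1)] < 1e-3

    def test_empty_and_mismatched_grid(self):
        p = rich_input(100, seed=14)
        v = 0.5 * p + 0.1 * np.roll(p, 1)
        with pytest.raises(ParameterError):
            grid_search(p, v, "FIR", grid=[], dt=0.4)
        with pytest.raises(ParameterError):
            grid_search(p, v, "FIR", grid=[ModelSpec("ARX", 1, 1)], dt=0.4)

    def test_default_grid_shapes(self):
        assert len(default_grid("FIR")) == 10 * 9 * 5
        assert len(default_grid("NARX")) == 8 * 6 * 9 * 5 * 4
        reduced = default_grid("NARX", reduced=True)
        assert 0 < len(reduced) < 60

    def test_split_is_half_by_duration(self):
        a, b = split_halves(np.arange(11))
        assert a.size == 5 and b.size == 6

    def test_nfir_at_least_as_good_as_fir_on_linear_data(self):
        """The Gaussian-kernel family nests near-linear behavior."""
        p = rich_input(500, seed=15)
        v = 0.7 * p + 0.2 * np.roll(p, 1)
        fir = grid_search(
            p, v, "FIR", grid=[ModelSpec("FIR", 1, C=10.0, nu=0.6)], dt=0.4
        )
        nfir_grid = [
            ModelSpec("NFIR", 1, C=10.0, nu=0.6, sigma=s) for s in (1.0, 2.0, 4.0)
        ]
        nfir = grid_search(p, v, "NFIR", grid=nfir_grid, dt=0.4)
        assert nfir.cc_val >= fir.cc_val - 0.02
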