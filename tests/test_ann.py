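"""Neural-network protocol tests: scaling, splitting, training, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lueyield import (
    DegenerateDataError,
    FeatureVector,
    InvalidInputError,
    MLPSpec,
    make_linear_feature_dataset,
    predict_yield,
    split_dataset,
    standardize_features,
    train_mlp,
)
from lueyield.ann import features_matrix
from lueyield.model import ANNYieldModel


def _rows(matrix, targets=None):
    return [
        FeatureVector(
            region_id=f"r{i}",
            year=2020,
            features=tuple(row),
            target=None if targets is None else float(targets[i]),
        )
        for i, row in enumerate(matrix)
    ]


class TestStandardize:
    def test_zscore_definition(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 9))
        std, scaler = standardize_features(_rows(x))
        z = features_matrix(std)
        assert np.allclose(z.mean(axis=0), 0.0)
        assert np.allclose(z.std(axis=0), 1.0)

    def test_idempotent_on_zscored_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (50, 9))
        x = (x - x.mean(0)) / x.std(0)
        std, _ = standardize_features(_rows(x))
        assert np.allclose(features_matrix(std), x, atol=1e-12)

    def test_scaler_reproduces_training_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 3, (20, 9))
        rows = _rows(x)
        std, scaler = standardize_features(rows)
        again = scaler.transform_rows(rows)
        assert np.allclose(features_matrix(std), features_matrix(again))

    def test_minmax_range(self):
        rng = np.random.default_rng(2)
        std, _ = standardize_features(_rows(rng.normal(0, 1, (30, 9))), "minmax")
        z = features_matrix(std)
        assert np.allclose(z.min(0), 0.0) and np.allclose(z.max(0), 1.0)

    def test_constant_column_named(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (10, 9))
        x[:, 2] = 7.0  # precip column
        with pytest.raises(DegenerateDataError, match="precip"):
            standardize_features(_rows(x))


class TestSplit:
    def test_exact_sizes_n100(self):
        s = split_dataset(100, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (70, 15, 15)

    def test_largest_remainder_n10(self):
        s = split_dataset(10, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (7, 2, 1)

    def test_determinism(self):
        assert split_dataset(57, seed=9) == split_dataset(57, seed=9)
        assert split_dataset(57, seed=9) != split_dataset(57, seed=10)

    def test_proportions_for_all_n(self):
        """Partition is exact and sizes within one of the fraction quotas."""
        for n in range(7, 1001, 1):
            s = split_dataset(n, seed=1)
            sizes = (len(s.train), len(s.validation), len(s.test))
            assert sum(sizes) == n
            for size, frac in zip(sizes, (0.70, 0.15, 0.15)):
                assert abs(size - frac * n) < 1.0

    def test_too_few_samples(self):
        with pytest.raises(InvalidInputError):
            split_dataset(6, seed=0)


class TestTraining:
    def test_constant_zero_target_learnable(self):
        rng = np.random.default_rng(0)
        rows = _rows(rng.normal(0, 1, (60, 9)), np.zeros(60))
        model = train_mlp(MLPSpec(seed=0, max_epochs=200), rows[:45], rows[45:])
        val_mse = model.history[model.best_epoch - 1][2]
        assert val_mse < 1e-5

    def test_seeded_determinism(self):
        rows = make_linear_feature_dataset(80, seed=5, noise_sd=0.2)
        spec = MLPSpec(seed=4, max_epochs=150)
        m1 = train_mlp(spec, rows[:56], rows[56:])
        m2 = train_mlp(spec, rows[:56], rows[56:])
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))
        assert m1.history == m2.history

    def test_noiseless_linear_target_high_skill(self):
        """Median test R^2 over 5 seeds >= 0.99 on a noiseless linear yield."""
        r2s = []
        for seed in range(5):
            rows = make_linear_feature_dataset(200, seed=seed, noise_sd=0.0)
            res = ANNYieldModel(rows, MLPSpec(seed=seed), split_seed=seed).fit()
            r2s.append(res.test_rsquared)
        assert float(np.median(r2s)) >= 0.99

    def test_best_epoch_validation_is_running_minimum(self):
        rows = make_linear_feature_dataset(120, seed=3, noise_sd=0.3)
        res = ANNYieldModel(rows, MLPSpec(seed=1), split_seed=1).fit()
        hist = np.array([h[2] for h in res.net.history])
        assert res.net.best_epoch >= 1
        assert hist[res.net.best_epoch - 1] == pytest.approx(hist.min())


class TestPrediction:
    def test_cardinality_and_duplicates(self):
        rows = make_linear_feature_dataset(50, seed=0)
        model = train_mlp(MLPSpec(seed=0, max_epochs=50), rows[:40], rows[40:])
        preds = predict_yield(model, rows)
        assert preds.shape == (50,)
        dup = [rows[3], rows[3]]
        p = predict_yield(model, dup)
        assert p[0] == p[1]

    def test_feature_count_mismatch(self):
        rows = make_linear_feature_dataset(20, seed=0)
        model = train_mlp(MLPSpec(seed=0, max_epochs=10), rows[:15], rows[15:])
        with pytest.raises(InvalidInputError):
            model.forward(np.zeros((3, 5)))

    def test_zero_weight_network_predicts_output_bias(self):
        rows = make_linear_feature_dataset(20, seed=0)
        model = train_mlp(MLPSpec(seed=0, max_epochs=5), rows[:15], rows[15:])
        for w in model.weights:
            w[:] = 0.0
        for b in model.biases:
            b[:] = 0.0
        model.biases[-1][:] = 2.0
        preds = model.forward(features_matrix(rows))
        assert np.allclose(preds, 2.0 * model.y_scale + model.y_shift)
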