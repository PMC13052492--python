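"""Standardization, SVM tiers, tile construction, and the CNN engine."""

import numpy as np
import pandas as pd
import pytest

from optophen import classify, nn
from optophen.spatial_io import ImageStack


class TestStandardize:
    def test_train_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 7, size=(50, 4))
        (xs,), mean, sd = classify.standardize(x)
        np.testing.assert_allclose(xs.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(xs.std(axis=0), 1, atol=1e-9)

    def test_train_stats_applied_to_other_splits(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(30, 3))
        (xs, same), _, _ = classify.standardize(x, x.copy())
        np.testing.assert_allclose(xs, same)

    def test_constant_feature_passes_through_centred(self, caplog):
        x = np.column_stack([np.arange(10.0), np.full(10, 5.0)])
        with caplog.at_level("WARNING"):
            (xs,), mean, sd = classify.standardize(x)
        assert sd[1] == 1.0
        np.testing.assert_allclose(xs[:, 1], 0.0)
        assert "constant" in caplog.text

    def test_no_leakage_from_test_shift(self):
        """Shifting the held-out set must not change the fitted
        statistics or the transformed training data."""
        rng = np.random.default_rng(2)
        x_tr = rng.normal(0, 1, (40, 3))
        x_te = rng.normal(0, 1, (10, 3))
        (a_tr, _), m1, s1 = classify.standardize(x_tr, x_te)
        (b_tr, _), m2, s2 = classify.standardize(x_tr, x_te + 100.0)
        np.testing.assert_array_equal(a_tr, b_tr)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(s1, s2)


class TestSplitPlan:
    def test_partitions_disjoint_exhaustive_stratified(self):
        labels = np.repeat([0, 1, 2], 20)
        plan = classify.SplitPlan.stratified(labels, 5, seed=0)
        seen = np.concatenate([te for _, te in plan.folds])
        assert sorted(seen) == list(range(60))
        for _, te in plan.folds:
            _, counts = np.unique(labels[te], return_counts=True)
            assert counts.tolist() == [4, 4, 4]

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            classify.SplitPlan.stratified(np.array([0, 0, 0, 1]), 5, seed=0)


def _feature_frame(x, y):
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    df.insert(0, "label", y)
    df.insert(0, "spot", [f"s{i}" for i in range(len(y))])
    return df


class TestSVM:
    def test_separable_classes_perfect_cv_accuracy(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 0.1, (25, 2)), rng.normal(5, 0.1, (25, 2))])
        y = np.repeat([0, 1], 25)
        model = classify.train_svm(_feature_frame(x, y), n_folds=5, seed=0)
        assert model.mean_accuracy == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (120, 5))
        y = rng.permutation(np.repeat([0, 1, 2], 40))
        model = classify.train_svm(_feature_frame(x, y), n_folds=5, seed=0)
        assert abs(model.mean_accuracy - 1 / 3) < 0.15

    def test_single_class_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            classify.train_svm(_feature_frame(x, np.zeros(10, int)))

    def test_pooled_predictions_cover_every_spot_once(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (40, 3))
        y = np.repeat([0, 1], 20)
        model = classify.train_svm(_feature_frame(x, y), n_folds=5, seed=0)
        assert sorted(model.predictions["index"]) == list(range(40))


class TestTiles:
    def _stack(self, h=300, w=300):
        data = np.zeros((5, h, w), dtype=np.uint16)
        for c in range(5):
            data[c] = 2000 + c * 10000
        return ImageStack(data=data)

    def test_constant_channels_predictable_8bit_values(self):
        stack = self._stack()
        ts = classify.make_tiles(
            stack, [(150, 150)], [0], tile_px=32, mode="native"
        )
        tile = ts.tiles[0]
        # R <- ch1 (2000), G <- ch3 (22000), B <- ch5 (42000)
        want = classify.to_8bit(np.array([2000, 22000, 42000]))
        assert tile.shape == (32, 32, 3)
        for band in range(3):
            assert (tile[:, :, band] == want[band]).all()

    def test_to_8bit_window_endpoints(self):
        assert classify.to_8bit(np.array([2000])) == 0
        assert classify.to_8bit(np.array([65535])) == 255

    def test_adjacent_window_overlap_fraction(self):
        """Two spots one grid spacing (78 px) apart with 224-px windows
        share (224-78)/224 of their width."""
        overlap = (224 - 78) / 224
        assert overlap == pytest.approx(0.6518, abs=1e-4)
        stack = self._stack(600, 600)
        ts = classify.make_tiles(
            stack, [(200, 300), (278, 300)], [0, 1], tile_px=224
        )
        assert len(ts.tiles) == 2
        shared = 224 - 78
        np.testing.assert_array_equal(
            ts.tiles[0][:, 78:, :], ts.tiles[1][:, :shared, :]
        )

    def test_out_of_bounds_spot_dropped(self, caplog):
        stack = self._stack(100, 100)
        with caplog.at_level("WARNING"):
            ts = classify.make_tiles(
                stack, [(50, 50), (5, 5)], [0, 1], tile_px=64
            )
        assert len(ts.tiles) == 1
        assert ts.labels.tolist() == [0]

    def test_crop_resize_mode_shape(self):
        stack = self._stack()
        ts = classify.make_tiles(
            stack, [(150, 150)], [0], tile_px=112, mode="crop-resize", crop_px=70
        )
        assert ts.tiles.shape == (1, 112, 112, 3)


class TestCNNEngine:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through conv/pool/dense layers agrees with central
        finite differences on a tiny network (dropout off)."""
        rng = np.random.default_rng(6)
        model = nn.SmallCNN((2, 8, 8), 3, filters=(2, 3), hidden=4,
                            dropout=0.0, seed=0)
        x = rng.normal(0, 1, (4, 2, 8, 8))
        y = np.eye(3)[rng.integers(0, 3, 4)]
        _, grads = model.loss_and_grads(x, y, train=False)
        eps = 1e-6
        for p, g in zip(model.params, grads):
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = model.loss_and_grads(x, y, train=False)
                flat[idx] = orig - eps
                lm, _ = model.loss_and_grads(x, y, train=False)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(num, abs=1e-4)

    def test_training_reduces_loss_on_separable_tiles(self):
        rng = np.random.default_rng(7)
        n = 40
        x = rng.normal(0, 0.05, (n, 3, 8, 8)).astype(np.float32)
        y = np.repeat([0, 1], n // 2)
        x[y == 1] += 0.5
        perm = rng.permutation(n)
        tr, va = perm[:32], perm[32:]
        model = nn.SmallCNN((3, 8, 8), 2, filters=(4, 4), hidden=8, seed=1)
        log = nn.train_network(
            model, x[tr], y[tr], x[va], y[va],
            epochs=15, augment=False, seed=2,
        )
        assert log.train_loss[-1] < log.train_loss[0]
        proba = model.predict_proba(x[va])
        assert (proba.argmax(1) == y[va]).mean() == 1.0

    def test_constant_tiles_shuffled_labels_chance(self):
        rng = np.random.default_rng(8)
        tiles = classify.TileSet(
            tiles=np.full((60, 8, 8, 3), 128, np.uint8),
            labels=rng.permutation(np.repeat([0, 1, 2], 20)),
            spot_ids=np.arange(60),
        )
        model = classify.train_cnn(tiles, n_folds=3, seed=0, epochs=4,
                                   filters=(2, 2), hidden=4)
        assert abs(model.mean_accuracy - 1 / 3) < 0.25

    def test_cnn_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 255, (36, 8, 8, 3), dtype=np.uint8)
        y = np.repeat([0, 1, 2], 12)
        ts = classify.TileSet(tiles=x, labels=y, spot_ids=np.arange(36))
        m1 = classify.train_cnn(ts, n_folds=3, seed=5, epochs=3,
                                filters=(2, 2), hidden=4)
        m2 = classify.train_cnn(ts, n_folds=3, seed=5, epochs=3,
                                filters=(2, 2), hidden=4)
        pd.testing.assert_frame_equal(m1.predictions, m2.predictions)
        np.testing.assert_array_equal(m1.scores, m2.scores)


class TestMetricAveraging:
    def test_weighted_average_formula_brute_force(self):
        from optophen.evaluate import confusion_and_report

        truth = np.array(["a"] * 6 + ["b"] * 3 + ["c"] * 1)
        pred = np.array(["a", "a", "b", "c", "a", "a", "b", "b", "a", "c"])
        rep = confusion_and_report(truth, pred)
        per = rep.per_class.set_index("class")
        want = sum(
            per.loc[c, "support"] * per.loc[c, "precision"] for c in "abc"
        ) / 10
        assert rep.weighted["precision"] == pytest.approx(want)
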