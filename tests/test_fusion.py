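import numpy as np
import pytest

from depthbcs._nn import (Conv2D, Dense, Flatten, MaxPool2, ReLU, Sequential,
                          softmax, weighted_cross_entropy)
from depthbcs.depth_io import CameraView
from depthbcs.fusion import (BackboneConfig, FusionClassifier, FusionDataset,
                             FusionKind, TrainConfig, build_model,
                             class_weights, ensemble_average, model_stats,
                             predict_proba, train)

CAMS = (CameraView.ANGLED, CameraView.REAR, CameraView.TOP)
SHAPES = {CameraView.ANGLED: (16, 16, 3), CameraView.REAR: (18, 14, 3),
          CameraView.TOP: (14, 18, 3)}

# Per-camera training counts of the study's angled camera after augmentation.
ANGLED_TRAIN_COUNTS = (320, 452, 1196, 1468, 2516, 1780, 368, 112)


class TestClassWeights:
    def test_balanced_counts_equal_weights(self):
        np.testing.assert_allclose(class_weights([10, 10, 10]), np.ones(3))

    def test_inverse_proportionality(self):
        w = class_weights([1, 2])
        assert w[0] / w[1] == pytest.approx(2.0)

    def test_cost_sensitivity_identity_on_herd_counts(self):
        """w_c * n_c is constant across populated classes."""
        counts = np.array(ANGLED_TRAIN_COUNTS, dtype=float)
        w = class_weights(counts)
        products = w * counts
        np.testing.assert_allclose(products, products[0])
        assert np.sum(w * counts) == pytest.approx(counts.sum())

    def test_empty_class_gets_zero_weight(self):
        w = class_weights([5, 0, 5])
        assert w[1] == 0.0 and w[0] > 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0, 0, 0])


class TestEnsembleAverage:
    def test_identical_vectors_fixed_point(self):
        v = np.array([0.1, 0.2, 0.7])
        fused, cls = ensemble_average([v, v, v])
        np.testing.assert_allclose(fused, v)
        assert cls == 2

    def test_tie_breaks_to_lowest_index(self):
        a = np.zeros(8); a[0] = 1.0
        b = np.zeros(8); b[1] = 1.0
        fused, cls = ensemble_average([a, b])
        np.testing.assert_allclose(fused[:2], [0.5, 0.5])
        assert cls == 0

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(0)
        vecs = [rng.dirichlet(np.ones(8)) for _ in range(3)]
        fused, _ = ensemble_average(vecs)
        brute = np.array([sum(v[k] for v in vecs) / 3 for k in range(8)])
        np.testing.assert_allclose(fused, brute)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        vecs = [rng.dirichlet(np.ones(8)) for _ in range(4)]
        a, _ = ensemble_average(vecs)
        b, _ = ensemble_average(vecs[::-1])
        np.testing.assert_allclose(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([np.ones(8) / 8, np.ones(7) / 7])


class TestModelStats:
    def test_dense_closed_form(self):
        assert Dense(10, 8).n_params() == 10 * 8 + 8

    def test_conv_closed_form(self):
        assert Conv2D(3, 16, 3).n_params() == 3 * 3 * 3 * 16 + 16

    def test_late_stats_additive_over_members(self):
        late = build_model(FusionKind.LATE, CAMS, SHAPES)
        singles = [build_model(FusionKind.LATE, (c,), SHAPES) for c in CAMS]
        assert model_stats(late).n_params == sum(
            model_stats(s).n_params for s in singles)
        assert model_stats(late).flops == sum(
            model_stats(s).flops for s in singles)

    def test_flops_counts_conv_and_dense_macs(self):
        net = Sequential([Dense(10, 8)])
        assert net.flops((10,)) == 2 * 10 * 8


class TestBuildModel:
    def test_early_three_cameras_nine_channels(self):
        model = build_model(FusionKind.EARLY, CAMS, SHAPES)
        assert model.network.layers[0].W.shape[2] == 9

    def test_mid_feature_length_doubles_with_two_cameras(self):
        cams2 = CAMS[:2]
        model = build_model(FusionKind.MID, cams2, SHAPES)
        per_trunk = model.network.feat_dims
        head_in = model.network.head.layers[0].W.shape[0]
        assert head_in == sum(per_trunk)
        assert len(per_trunk) == 2

    def test_empty_camera_set_rejected(self):
        with pytest.raises(ValueError):
            build_model(FusionKind.LATE, (), SHAPES)

    def test_late_single_camera_fusion_is_identity(self):
        rng = np.random.default_rng(2)
        data = _dataset(rng, n=12)
        model = build_model(FusionKind.LATE, (CameraView.ANGLED,), SHAPES)
        fused, per_cam = predict_proba(model, data)
        np.testing.assert_allclose(fused, per_cam[CameraView.ANGLED])


def _dataset(rng, n=24, separable=False):
    X = {}
    y = rng.integers(0, 8, n)
    for cam in CAMS:
        arr = rng.normal(0, 0.2, size=(n,) + SHAPES[cam]).astype(np.float32)
        if separable:
            arr += (y[:, None, None, None] / 8.0).astype(np.float32)
        X[cam] = arr
    return FusionDataset(X=X, y=y, cow_ids=np.array([f"c{i}" for i in range(n)]))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Finite-difference check of the full conv/pool/dense backward pass.

        Parameters are upcast to float64 so the central differences are not
        dominated by single-precision rounding.
        """
        rng = np.random.default_rng(3)
        net = Sequential([Conv2D(2, 3, 3, rng=rng), ReLU(), MaxPool2(),
                          Flatten(), Dense(3 * 2 * 2, 4, rng=rng)])
        for layer in net.layers:
            if layer.trainable:
                layer.W = layer.W.astype(np.float64)
                layer.dW = layer.dW.astype(np.float64)
                layer.b = layer.b.astype(np.float64)
                layer.db = layer.db.astype(np.float64)
        x = rng.normal(size=(3, 4, 4, 2))
        y = np.array([0, 2, 1])
        w = np.array([1.0, 0.5, 2.0, 1.0])

        def loss_fn():
            loss, _ = weighted_cross_entropy(net.forward(x), y, w)
            return loss

        loss, dlogits = weighted_cross_entropy(net.forward(x), y, w)
        net.backward(dlogits.astype(np.float64))
        eps = 1e-6
        for p, g in net.params_grads():
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                dn = loss_fn()
                flat[idx] = orig
                numeric = (up - dn) / (2 * eps)
                assert numeric == pytest.approx(gflat[idx], rel=1e-4, abs=1e-7)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        p = softmax(rng.normal(size=(5, 8)) * 10)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(5)
        n = 32
        y = np.repeat([0, 5], n // 2)
        X = {}
        for cam in CAMS:
            arr = rng.normal(0, 0.05, size=(n,) + SHAPES[cam]).astype(np.float32)
            arr[y == 5] += 1.0
            X[cam] = arr
        data = FusionDataset(X=X, y=y, cow_ids=np.array([f"c{i}" for i in range(n)]))
        model = build_model(FusionKind.LATE, (CameraView.ANGLED,), SHAPES,
                            BackboneConfig(conv_filters=(8, 8, 8), dense=(16,),
                                           seed=0))
        train(model, data, data, TrainConfig(epochs=30, batch_size=8, seed=0))
        fused, _ = predict_proba(model, data)
        assert (np.argmax(fused, axis=1) == y).mean() == 1.0

    def test_class_weighting_lifts_minority_recall(self):
        """9:1 imbalance: the cost-sensitive run must not lose minority recall."""
        rng = np.random.default_rng(6)
        n = 40
        y = np.array([0] * 36 + [1] * 4)
        X = {}
        for cam in CAMS[:1]:
            arr = rng.normal(0, 0.4, size=(n,) + SHAPES[cam]).astype(np.float32)
            arr[y == 1] += 0.4
            X[cam] = arr
        data = FusionDataset(X=X, y=y, cow_ids=np.array([f"c{i}" for i in range(n)]))
        recalls = {}
        for weighted in (True, False):
            model = build_model(FusionKind.LATE, CAMS[:1], SHAPES,
                                BackboneConfig(conv_filters=(8, 8, 8),
                                               dense=(16,), seed=1))
            train(model, data, data,
                  TrainConfig(epochs=12, batch_size=8, seed=1,
                              class_weighting=weighted))
            fused, _ = predict_proba(model, data)
            pred = np.argmax(fused, axis=1)
            recalls[weighted] = (pred[y == 1] == 1).mean()
        assert recalls[True] >= recalls[False]

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        data = _dataset(rng, n=16, separable=True)
        losses = []
        for _ in range(2):
            model = build_model(FusionKind.EARLY, CAMS, SHAPES,
                                BackboneConfig(conv_filters=(4, 4, 4),
                                               dense=(8,), seed=3))
            hist = train(model, data, data,
                         TrainConfig(epochs=3, batch_size=8, seed=3))
            losses.append(hist["early"]["train_loss"].tolist())
        assert losses[0] == losses[1]

    def test_empty_training_set_rejected(self):
        rng = np.random.default_rng(8)
        data = _dataset(rng, n=8)
        empty = data.take(np.array([], dtype=int))
        model = build_model(FusionKind.LATE, CAMS[:1], SHAPES)
        with pytest.raises(ValueError):
            train(model, empty, data)


class TestClassifierSurface:
    def test_fit_returns_results_with_summary(self):
        rng = np.random.default_rng(9)
        data = _dataset(rng, n=40, separable=True)
        clf = FusionClassifier(data, kind=FusionKind.LATE,
                               backbone=BackboneConfig(conv_filters=(4, 4, 4),
                                                       dense=(8,), seed=0))
        res = clf.fit(TrainConfig(epochs=2, batch_size=8, seed=0))
        text = res.summary()
        assert "LATE fusion" in text and "trainable parameters" in text
        report = res.evaluate(data)
        assert set(report.bands) == {0, 1, 2}

    def test_holdout_is_cow_disjoint(self):
        rng = np.random.default_rng(10)
        data = _dataset(rng, n=40)
        tr, val = FusionClassifier._holdout(data, seed=0)
        assert not (set(tr.cow_ids) & set(val.cow_ids))
        assert len(tr) + len(val) == len(data)
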