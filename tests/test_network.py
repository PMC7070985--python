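"""Network specs, reference convolution, parameter counting, training."""

import numpy as np
import pytest

from hdsemg3d.cubes import CubeDataset
from hdsemg3d.network import (
    COUNT_CONVENTIONS, Kernel3D, Model, NetworkSpec, ShapeError,
    TrainingConfig, build_2d_cnn, build_3d_cnn, conv3d_reference,
    count_parameters, lr_schedule, propagate_shapes, train,
)
from hdsemg3d.network.layers import Conv3D


class TestReferenceConv:
    def test_zero_kernel_bias_one_gives_constant(self):
        u = np.random.default_rng(0).standard_normal((1, 5, 5, 5))
        k = Kernel3D(np.zeros((3, 3, 3, 1)), bias=1.0)
        out = conv3d_reference(u, [k])
        np.testing.assert_allclose(out, 1.0)

    def test_valid_output_shape(self):
        u = np.zeros((1, 10, 8, 16))
        k = Kernel3D(np.zeros((3, 3, 3, 1)))
        assert conv3d_reference(u, [k]).shape == (1, 8, 6, 14)

    def test_matches_flipped_kernel_full_correlation(self, rng):
        """Independent oracle: scipy correlate restricted to valid region."""
        from scipy.signal import correlate

        u = rng.standard_normal((1, 5, 5, 5))
        w = rng.standard_normal((3, 3, 3, 1))
        out = conv3d_reference(u, [Kernel3D(w, bias=0.25)])
        oracle = correlate(u[0], w[..., 0], mode="valid") + 0.25
        np.testing.assert_allclose(out[0], oracle, atol=1e-10)

    def test_multi_input_cubes_sum(self, rng):
        u = rng.standard_normal((3, 4, 4, 4))
        w = rng.standard_normal((2, 2, 2, 3))
        out = conv3d_reference(u, [Kernel3D(w)])
        # summing single-cube responses must equal the multi-cube response
        parts = [conv3d_reference(u[m:m + 1], [Kernel3D(w[..., m:m + 1])])
                 for m in range(3)]
        np.testing.assert_allclose(out, sum(parts), atol=1e-10)

    def test_kernel_larger_than_input(self):
        with pytest.raises(ValueError, match="larger"):
            conv3d_reference(np.zeros((1, 2, 2, 2)),
                             [Kernel3D(np.zeros((3, 3, 3, 1)))])

    def test_relu_activation_applied(self, rng):
        u = rng.standard_normal((1, 4, 4, 4))
        w = rng.standard_normal((3, 3, 3, 1))
        lin = conv3d_reference(u, [Kernel3D(w)])
        act = conv3d_reference(u, [Kernel3D(w)], activation="relu")
        np.testing.assert_allclose(act, np.maximum(lin, 0.0))


class TestFrameworkVsReference:
    def test_layer_matches_reference_on_random_case(self, rng):
        x = rng.standard_normal((1, 6, 5, 7, 2)).astype(np.float32)
        layer = Conv3D(2, 3, (3, 3, 3), (0, 1, 1), rng)
        out = layer.forward(x, training=False)
        kernels = [Kernel3D(layer.params["W"][..., j],
                            float(layer.params["b"][j])) for j in range(3)]
        ref = conv3d_reference(np.moveaxis(x[0], -1, 0), kernels,
                               padding=(0, 1, 1))
        np.testing.assert_allclose(np.moveaxis(out[0], -1, 0), ref, atol=1e-5)


class TestArchitectureSpecs:
    def test_3d_temporal_trace_l10(self):
        spec = build_3d_cnn((10, 8, 16, 1), pool_s=2, G=8)
        temporal = [s[0] for s in propagate_shapes(spec)
                    if len(s) == 4]
        # conv/pool layers: 10 -> 8 -> 6 -> 3 -> 1 -> 1
        assert temporal[0] == 8 and temporal[3] == 6
        assert temporal[6] == 3 and temporal[7] == 1

    def test_3d_csl_geometry_valid(self):
        spec = build_3d_cnn((20, 7, 24, 1), pool_s=4, G=27)
        shapes = propagate_shapes(spec)
        assert shapes[0] == (18, 5, 22, 32)

    def test_temporal_collapse_raises(self):
        with pytest.raises(ShapeError):
            build_3d_cnn((3, 8, 16, 1), pool_s=2, G=8)

    @pytest.mark.parametrize("hw,expect", [
        ((8, 16), (6, 14)), ((7, 24), (5, 22))])
    def test_2d_spatial_trace(self, hw, expect):
        spec = build_2d_cnn((*hw, 1), G=8)
        shapes = [s for s in propagate_shapes(spec) if len(s) == 3]
        assert shapes[0][:2] == expect          # conv1 valid
        assert shapes[-1][:2] == expect         # conv2/conv3 padded

    def test_2d_3x3_input_single_pixel(self):
        spec = build_2d_cnn((3, 3, 1), G=2)
        assert propagate_shapes(spec)[0][:2] == (1, 1)

    def test_yaml_roundtrip(self):
        spec = build_3d_cnn((10, 8, 16, 1), pool_s=2, G=8)
        back = NetworkSpec.from_yaml(spec.to_yaml())
        assert back == spec

    def test_shape_propagation_matches_reference_conv_shapes(self, rng):
        """Layer-by-layer conv shapes agree with actually convolving."""
        spec = build_3d_cnn((12, 8, 16, 1), pool_s=2, G=4,
                            conv_channels=(2, 2, 2), dense_units=(8, 4))
        shapes = propagate_shapes(spec)
        conv_shapes = [s for s, lay in zip(shapes, spec.layers)
                       if lay.kind == "conv3d"]
        u = rng.standard_normal((1, 12, 8, 16))
        out = conv3d_reference(u, [Kernel3D(rng.standard_normal((3, 3, 3, 1)))
                                   for _ in range(2)])
        assert out.shape[1:] == conv_shapes[0][:3]


class TestCountParameters:
    def test_single_conv_layer_arithmetic(self):
        from hdsemg3d.network.spec import Conv3DSpec

        spec = NetworkSpec((10, 8, 16, 1), (Conv3DSpec(32, (3, 3, 3)),))
        assert count_parameters(spec, "none") == 32 * (27 + 1) == 896

    def test_dense_layer_arithmetic(self):
        from hdsemg3d.network.spec import DenseSpec, FlattenSpec

        spec = NetworkSpec((5376,), (DenseSpec(512),))
        assert count_parameters(spec, "none") == 5376 * 512 + 512 == 2753024

    @pytest.mark.parametrize("convention,bn_mode", [
        ("bn-channel", "channel"),
        ("bn-activation", "activation"),
    ])
    def test_count_matches_instantiated_model(self, rng, convention, bn_mode):
        """Analytic counts equal enumerating the live model's tensors."""
        spec = build_3d_cnn((10, 8, 16, 1), pool_s=2, G=8,
                            conv_channels=(4, 8, 8), dense_units=(16, 8))
        model = Model(spec, rng, bn_mode=bn_mode)
        assert count_parameters(spec, convention) == model.n_trainable_params()

    def test_channel_full_counts_statistics(self, rng):
        spec = build_2d_cnn((8, 16, 1), G=8, conv_channels=(4, 8, 8),
                            dense_units=(16, 8))
        model = Model(spec, rng, bn_mode="channel")
        assert count_parameters(spec, "bn-channel-full") == \
            model.n_params(include_statistics=True)

    def test_none_counts_only_weighted_layers(self, rng):
        spec = build_2d_cnn((8, 16, 1), G=8, conv_channels=(4, 8, 8),
                            dense_units=(16, 8))
        model = Model(spec, rng, bn_mode="channel")
        bn_params = sum(l.n_trainable() for l in model.layers
                        if type(l).__name__ == "BatchNorm")
        assert count_parameters(spec, "none") == \
            model.n_trainable_params() - bn_params

    def test_unknown_convention(self):
        spec = build_2d_cnn((8, 16, 1), G=8)
        with pytest.raises(ValueError, match="convention"):
            count_parameters(spec, "bogus")


class TestLRSchedule:
    def test_decreasing_losses_keep_rate(self):
        assert lr_schedule([1.0, 0.9, 0.8, 0.7], 0.1, patience=3) == 0.1

    def test_flat_plateau_halves(self):
        history = [0.5] + [0.6] * 10
        assert lr_schedule(history, 0.1, patience=10) == 0.05

    def test_three_plateaus_give_lr0_over_8(self):
        """Stepwise simulation: halving applied at each 10-epoch plateau."""
        lr = 0.1
        history = [0.5]
        for _ in range(3):
            history.extend([0.6] * 10)
            lr = lr_schedule(history, lr, patience=10)
        assert lr == pytest.approx(0.1 / 8)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lr_schedule([], 0.1)


def _separable_cubes(rng, n=200, l=10, G=2):
    X = rng.normal(0.5, 0.05, size=(n, l, 6, 8, 1)).astype(np.float32)
    y = rng.integers(0, G, n)
    for i in range(n):
        c = 2 + 4 * y[i]
        X[i, :, 2:5, c - 1:c + 1, 0] += 0.3
    return CubeDataset(np.clip(X, 0, 1), y, l=l, stride=l)


class TestTraining:
    def test_separable_problem_learned(self, rng):
        ds = _separable_cubes(rng)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(4, 8, 8), dense_units=(16, 8))
        model = train(spec, ds, TrainingConfig(max_epochs=25, seed=0,
                                               momentum=0.9))
        labels, _ = model.predict(ds)
        assert np.mean(labels == ds.labels) >= 0.99

    def test_seeded_runs_identical(self, rng):
        ds = _separable_cubes(rng, n=60)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        cfg = TrainingConfig(max_epochs=4, seed=7)
        m1 = train(spec, ds, cfg)
        m2 = train(spec, ds, cfg)
        assert m1.loss_history == m2.loss_history
        for k, v in m1.model.state_dict().items():
            np.testing.assert_array_equal(v, m2.model.state_dict()[k])

    def test_probabilities_sum_to_one(self, rng):
        ds = _separable_cubes(rng, n=40)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        model = train(spec, ds, TrainingConfig(max_epochs=2, seed=0))
        _, probs = model.predict(ds)
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_cube_identical_predictions(self, rng):
        ds = _separable_cubes(rng, n=40)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        model = train(spec, ds, TrainingConfig(max_epochs=2, seed=0))
        one = ds.cubes[:1]
        labels, probs = model.predict(np.repeat(one, 5, axis=0))
        assert len(set(labels.tolist())) == 1
        np.testing.assert_array_equal(probs, np.tile(probs[:1], (5, 1)))

    def test_missing_class_warns(self, rng):
        ds = _separable_cubes(rng, n=30)
        ds.labels[:] = 0
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        with pytest.warns(UserWarning, match="absent"):
            model = train(spec, ds, TrainingConfig(max_epochs=1, seed=0))
        assert any("absent" in line for line in model.log)

    def test_plateau_halves_rate_during_training(self, rng):
        """With a tiny patience, the recorded rate must halve after a
        non-improving stretch."""
        ds = _separable_cubes(rng, n=30)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        cfg = TrainingConfig(lr0=1e-6, max_epochs=8, halve_patience=2, seed=0)
        model = train(spec, ds, cfg)  # rate too small to improve anything
        assert min(model.lr_history) < cfg.lr0

    def test_model_save_load_roundtrip(self, tmp_path, rng):
        from hdsemg3d.network import TrainedModel

        ds = _separable_cubes(rng, n=30)
        spec = build_3d_cnn((10, 6, 8, 1), pool_s=2, G=2,
                            conv_channels=(2, 4, 4), dense_units=(8, 4))
        model = train(spec, ds, TrainingConfig(max_epochs=2, seed=0))
        model.save(tmp_path / "model.npz")
        back = TrainedModel.load(tmp_path / "model.npz")
        l1, p1 = model.predict(ds)
        l2, p2 = back.predict(ds)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(p1, p2, atol=1e-7)
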