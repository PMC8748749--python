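"""Network topology, shape laws, branch decomposition, gradients,
persistence."""

import numpy as np
import pytest
import yaml

from rrlsrn import NetworkConfig, build_network, predict_slice
from rrlsrn.losses import LossConfig, combined_loss_grad


def closed_form_parameter_count(cfg: NetworkConfig) -> int:
    """Independent layer-by-layer hand count: k*k*c_in*c_out + c_out."""
    k, c = cfg.conv_kernel, cfg.channels
    total = k * k * 1 * c + c  # first conv lifts 1 -> c
    total += (cfg.n_feature_convs - 1) * (k * k * c * c + c)
    kt = cfg.transpose_kernel
    total += kt * kt * c * 1 + 1  # residual-branch transposed conv
    if cfg.use_image_branch:
        total += kt * kt * 1 * 1 + 1
    return total


class TestTopology:
    def test_default_layer_census(self):
        model = build_network(NetworkConfig())
        assert model.layer_census() == {"conv": 13, "conv_transpose": 2}

    def test_census_without_image_branch(self):
        model = build_network(NetworkConfig(use_image_branch=False))
        assert model.layer_census() == {"conv": 13, "conv_transpose": 1}

    @pytest.mark.parametrize(
        "cfg",
        [
            NetworkConfig(),
            NetworkConfig(use_image_branch=False),
            NetworkConfig(n_feature_convs=5, channels=16),
        ],
    )
    def test_parameter_count_matches_closed_form(self, cfg):
        assert build_network(cfg).n_parameters == closed_form_parameter_count(cfg)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(transpose_kernel=5, upsample_stride=2)
        with pytest.raises(ValueError):
            NetworkConfig(scale=4, upsample_stride=2)
        with pytest.raises(ValueError):
            NetworkConfig(conv_kernel=4)


class TestForward:
    def test_output_is_twice_the_input(self, rng):
        model = build_network(NetworkConfig())
        out = model.forward(rng.random((2, 1, 64, 64)).astype(np.float32))
        assert out.shape == (2, 1, 128, 128)

    @pytest.mark.parametrize("hw", [(32, 32), (32, 48), (40, 128), (128, 96)])
    def test_shape_law_across_sizes(self, hw, rng):
        model = build_network(NetworkConfig(n_feature_convs=2, channels=4))
        h, w = hw
        out = model.forward(rng.random((h, w)))
        assert out.shape == (2 * h, 2 * w)

    def test_zero_weights_give_zero_output(self, rng):
        model = build_network(NetworkConfig())
        for layer in model.layers:
            layer["W"][:] = 0
            layer["b"][:] = 0
        out = model.forward(rng.random((1, 1, 32, 32)).astype(np.float32))
        assert np.all(out == 0)

    def test_branch_additivity_is_bit_exact(self, rng):
        model = build_network(NetworkConfig())
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        out, _, res, img = model.forward(x, want_cache=True)
        assert np.array_equal(out, res + img)

    def test_no_image_branch_output_is_residual_branch(self, rng):
        model = build_network(NetworkConfig(use_image_branch=False))
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        out, _, res, img = model.forward(x, want_cache=True)
        assert img is None
        assert np.array_equal(out, res)

    def test_translation_covariance_in_interior(self, rng):
        # shifting the input one pixel shifts the output two, away from borders
        model = build_network(NetworkConfig(init_seed=5))
        x = rng.random((80, 80))
        out = model.forward(x)
        out_shift = model.forward(np.roll(x, 1, axis=1))
        band = 30  # > receptive field radius at HR scale
        a = out[band:-band, band : -band - 2]
        b = out_shift[band:-band, band + 2 : -band]
        assert np.allclose(a, b, atol=1e-4)

    def test_input_smaller_than_kernel_rejected(self):
        model = build_network(NetworkConfig())
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 2)))


class TestPredictSlice:
    def test_output_is_clipped(self, rng):
        model = build_network(NetworkConfig(init_seed=0))
        # inflate weights so the raw output exceeds [0, 1]
        model.layers[-1]["b"][:] = 5.0
        out = predict_slice(model, rng.random((32, 32)))
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_deterministic_and_finite(self, rng):
        model = build_network(NetworkConfig(init_seed=3))
        x = rng.random((64, 64))
        a, b = predict_slice(model, x), predict_slice(model, x)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))


def test_backward_matches_finite_differences(rng):
    cfg = NetworkConfig(n_feature_convs=3, channels=4, init_seed=1)
    model = build_network(cfg, dtype=np.float64)
    x = rng.random((2, 1, 8, 8))
    t = rng.random((2, 1, 16, 16))
    lcfg = LossConfig(gdl_weight=0.5)
    out, cache, _, _ = model.forward(x, want_cache=True)
    _, dout = combined_loss_grad(out, t, lcfg)
    grads = model.backward(cache, dout)
    h = 1e-6
    for li, layer in enumerate(model.layers):
        for key in ("W", "b"):
            flat = layer[key].ravel()
            analytic = grads[li][key].ravel()
            for ix in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[ix]
                flat[ix] = old + h
                lp = combined_loss_grad(model.forward(x), t, lcfg)[0]
                flat[ix] = old - h
                lm = combined_loss_grad(model.forward(x), t, lcfg)[0]
                flat[ix] = old
                fd = (lp - lm) / (2 * h)
                assert analytic[ix] == pytest.approx(fd, abs=1e-4)


def test_checkpoint_round_trip(tmp_path, rng):
    from rrlsrn.network import RRLSRN

    model = build_network(NetworkConfig(n_feature_convs=4, channels=8, init_seed=2))
    x = rng.random((48, 48))
    path = tmp_path / "model.npz"
    model.save(path)
    clone = RRLSRN.load(path)
    assert clone.config == model.config
    assert np.array_equal(predict_slice(clone, x), predict_slice(model, x))


def test_config_round_trips_through_yaml():
    from dataclasses import asdict

    cfg = NetworkConfig(channels=32, leaky_slope=0.1, init_seed=9)
    restored = NetworkConfig(**yaml.safe_load(yaml.safe_dump(asdict(cfg))))
    assert restored == cfg
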