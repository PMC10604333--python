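"""Auto-encoder structure, encoding determinism and local SGD behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histofed.cae import (
    CAE,
    CAEConfig,
    ConfigError,
    build_cae,
    encode,
    train_local,
)
from histofed.types import PatchImage

from conftest import micro_config


def _patches(n, size, seed, label=1):
    rng = np.random.default_rng(seed)
    return [
        PatchImage(rng.uniform(0, 1, (size, size, 3)), patch_id=f"p{i}", label=label)
        for i in range(n)
    ]


class TestConfig:
    def test_default_spatial_trace_halves_at_stride_two(self):
        assert CAEConfig().spatial_trace() == [224, 224, 112, 56, 28]

    @pytest.mark.parametrize(
        "kw",
        [
            {"encoder_filters": (32, 64), "encoder_strides": (1, 2, 2)},
            {"decoder_filters": (128, 64, 32, 4)},  # must end in channels_in
            {"latent_dim": 0},
            {"kernel_size": 4},
            {"bottleneck_strides": (1, 1, 2, 1)},
            {"decoder_strides": (1, 2, 2, 2)},  # not the encoder reversed
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            CAEConfig(**kw)

    def test_skip_channel_mismatch_names_both_layers(self):
        with pytest.raises(ConfigError, match="encoder layer 1.*decoder"):
            CAEConfig(
                input_size=16,
                encoder_filters=(8, 16),
                encoder_strides=(1, 2),
                bottleneck_filters=(4, 16),
                bottleneck_strides=(1, 1),
                decoder_filters=(4, 3),
                decoder_strides=(2, 1),
                latent_dim=4,
                skip_enabled=True,
            )


class TestStructure:
    def test_reconstruction_matches_input_shape(self, micro_model, rng):
        x = rng.uniform(0, 1, (3, 8, 8, 3))
        recon, latent = micro_model.forward(x)
        assert recon.shape == x.shape
        assert latent.shape == (3, 3)
        assert recon.min() >= 0.0 and recon.max() <= 1.0  # sigmoid output

    def test_skip_toggle_preserves_parameter_count(self):
        with_skip = build_cae(micro_config(skip=True), seed=0)
        without = build_cae(micro_config(skip=False), seed=0)
        assert with_skip.n_parameters == without.n_parameters

    def test_residual_projection_added_only_on_channel_change(self):
        cfg = micro_config()
        assert build_cae(cfg, seed=0).res_proj is None  # 2 -> 2: plain identity
        cfg2 = CAEConfig(
            input_size=8,
            encoder_filters=(2, 2),
            encoder_strides=(1, 2),
            bottleneck_filters=(2, 4),
            bottleneck_strides=(1, 1),
            decoder_filters=(2, 3),
            decoder_strides=(2, 1),
            latent_dim=3,
        )
        assert build_cae(cfg2, seed=0).res_proj is not None

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_reconstruction_shape_and_latent_dim_for_random_valid_configs(self, data):
        """Shape contract holds across the valid configuration space."""
        n_enc = data.draw(st.integers(2, 3))
        strides = tuple(data.draw(st.sampled_from([1, 2])) for _ in range(n_enc))
        filters = tuple(data.draw(st.integers(1, 4)) for _ in range(n_enc))
        size = data.draw(st.sampled_from([7, 8, 12]))
        latent = data.draw(st.integers(1, 6))
        skip = data.draw(st.booleans())
        dec_filters = tuple(data.draw(st.integers(1, 4)) for _ in range(n_enc - 2)) + (
            filters[0],
            3,
        ) if n_enc >= 2 else (filters[0], 3)
        cfg = CAEConfig(
            input_size=size,
            encoder_filters=filters,
            encoder_strides=strides,
            bottleneck_filters=(2, filters[-1]),
            bottleneck_strides=(1, 1),
            decoder_filters=dec_filters,
            decoder_strides=tuple(reversed(strides)),
            latent_dim=latent,
            skip_enabled=skip,
        )
        model = build_cae(cfg, seed=1)
        x = np.random.default_rng(0).uniform(0, 1, (2, size, size, 3))
        recon, z = model.forward(x)
        assert recon.shape == x.shape
        assert z.shape == (2, latent)
        assert model.encode_batch(x).shape == (2, latent)


class TestEncode:
    def test_feature_vectors_preserve_order_and_metadata(self, micro_model):
        patches = _patches(5, 8, seed=3)
        feats = encode(micro_model, patches)
        assert [f.patch_id for f in feats] == [p.patch_id for p in patches]
        assert all(len(f) == 3 for f in feats)

    def test_deterministic_and_batch_order_invariant(self, micro_model):
        patches = _patches(7, 8, seed=4)
        a = encode(micro_model, patches, batch_size=3)
        b = encode(micro_model, patches, batch_size=7)
        again = encode(micro_model, patches, batch_size=3)
        for fa, fb, fc in zip(a, b, again):
            np.testing.assert_array_equal(fa.values, fc.values)
            np.testing.assert_allclose(fa.values, fb.values, rtol=1e-12)

    def test_wrong_patch_size_rejected(self, micro_model):
        with pytest.raises(ValueError, match="expected patches"):
            micro_model.encode_batch(np.zeros((1, 9, 9, 3)))


class TestTrainLocal:
    def test_zero_learning_rate_is_identity_on_weights(self, micro_model):
        w0 = micro_model.get_weights()
        patches = _patches(4, 8, seed=5)
        w1, trace = train_local(micro_model, w0, patches, epochs=2, batch_size=2,
                                lr=0.0, seed=0)
        assert len(trace) == 2
        for name in w0.names():
            np.testing.assert_array_equal(w0[name], w1[name])

    def test_loss_decreases_across_epochs_in_most_seeds(self):
        """Two epochs of SGD lower the reconstruction error on a 4-image set."""
        wins = 0
        for seed in range(10):
            model = build_cae(micro_config(), seed=seed)
            patches = _patches(4, 8, seed=100 + seed)
            _, trace = train_local(model, model.get_weights(), patches,
                                   epochs=2, batch_size=2, lr=0.05, seed=seed)
            wins += trace[-1] <= trace[0]
        assert wins >= 9

    def test_single_batch_update_matches_finite_difference_gradient(self, rng):
        """One SGD step equals -lr * dL/dw checked by central differences."""
        model = build_cae(micro_config(), seed=2)
        # move biases off zero so no ReLU pre-activation sits exactly on the kink
        for layer in model._param_layers():
            for name, arr in layer.params().items():
                if name.endswith("/b"):
                    arr += rng.normal(0, 0.05, arr.shape)
        x = rng.uniform(0.1, 0.9, (2, 8, 8, 3))
        loss, grads = model.loss_and_grads(x)
        params = {}
        for layer in model._param_layers():
            params.update(layer.params())
        eps = 1e-6
        for name, arr in params.items():
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = model.loss_and_grads(x)
                flat[idx] = orig - eps
                lm, _ = model.loss_and_grads(x)
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name].ravel()[idx]
                assert g == pytest.approx(fd, rel=1e-4, abs=1e-9), name

    def test_empty_dataset_rejected(self, micro_model):
        with pytest.raises(ValueError, match="empty"):
            train_local(micro_model, micro_model.get_weights(), [], 1, 1, 0.1)

    def test_training_is_bit_reproducible_given_seed(self):
        patches = _patches(6, 8, seed=8)
        results = []
        for _ in range(2):
            model = build_cae(micro_config(), seed=3)
            w, trace = train_local(model, model.get_weights(), patches,
                                   epochs=2, batch_size=4, lr=0.02, seed=42)
            results.append((w, trace))
        assert results[0][1] == results[1][1]
        for name in results[0][0].names():
            np.testing.assert_array_equal(results[0][0][name], results[1][0][name])
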