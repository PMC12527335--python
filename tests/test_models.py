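"""Architecture contracts: embedding dimensionality, structural
differences between variants, forward-pass shapes and determinism."""

import numpy as np
import pytest

from neuroembed.models import (DEFAULT_INPUT_SHAPE, AutoencoderConfig,
                               build_model, embedding_dim)

TINY = dict(input_shape=(16, 16, 16), n_blocks=3, channel_schedule=(4, 8, 16))


def shape_after_pools(shape, n):
    for _ in range(n):
        shape = tuple(s // 2 for s in shape)
    return shape


class TestConfig:
    def test_default_channel_schedule(self):
        cfg = AutoencoderConfig("U_AE")
        assert cfg.channel_schedule == (4, 8, 16, 32, 64, 128)
        assert cfg.n_blocks == 6

    def test_schedule_length_must_match_blocks(self):
        with pytest.raises(ValueError, match="length"):
            AutoencoderConfig("U_AE", n_blocks=4, channel_schedule=(4, 8, 16))

    def test_schedule_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            AutoencoderConfig("U_AE", n_blocks=3, channel_schedule=(4, 4, 8),
                              input_shape=(16, 16, 16))

    def test_latent_dim_conventional_rejected(self):
        with pytest.raises(ValueError, match="variational"):
            AutoencoderConfig("UNET", latent_dim=256, **{k: v for k, v in TINY.items()
                                                         if k != "latent_dim"})

    def test_variational_default_latent_2048(self):
        assert AutoencoderConfig("U_VAE").latent_dim == 2048
        assert AutoencoderConfig("VAE").latent_dim == 2048

    def test_too_small_input_rejected(self):
        """(8,8,8) collapses to zero after 6 halvings."""
        with pytest.raises(ValueError, match="collapses"):
            AutoencoderConfig("U_AE", input_shape=(8, 8, 8))


class TestEmbeddingDim:
    def test_default_conventional_within_range(self):
        """Full-grid conventional bottleneck: spatial (2,3,2) x 128
        channels = 1536, inside the 1,000-5,000 design window."""
        cfg = AutoencoderConfig("U_AE")
        assert cfg.bottleneck_shape == shape_after_pools(DEFAULT_INPUT_SHAPE, 6)
        assert embedding_dim(cfg) == 2 * 3 * 2 * 128 == 1536
        assert 1000 <= embedding_dim(cfg) <= 5000

    def test_default_variational_exactly_2048(self):
        assert embedding_dim(AutoencoderConfig("U_VAE")) == 2048
        assert embedding_dim(AutoencoderConfig("VAE")) == 2048

    def test_tiny_conventional_shape_oracle(self):
        """32**3 input, 3 blocks, schedule (4,8,16): 4*4*4*16 = 1024."""
        cfg = AutoencoderConfig("U_AE", input_shape=(32, 32, 32), n_blocks=3,
                                channel_schedule=(4, 8, 16))
        assert embedding_dim(cfg) == 1024

    @pytest.mark.parametrize("variant", ["UNET", "U_AE", "U_VAE", "VAE"])
    @pytest.mark.parametrize("shape,n_blocks,schedule,latent", [
        ((16, 16, 16), 3, (4, 8, 16), 24),
        ((16, 24, 16), 2, (4, 8), 10),
        ((18, 22, 16), 3, (2, 4, 8), 16),
    ])
    def test_measured_feature_length(self, variant, shape, n_blocks,
                                     schedule, latent):
        """embedding_dim equals the measured forward-pass feature length
        over a 12-config grid (property across all variants)."""
        cfg = AutoencoderConfig(variant, input_shape=shape, n_blocks=n_blocks,
                                channel_schedule=schedule,
                                latent_dim=latent if variant in ("U_VAE", "VAE") else None)
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(0).standard_normal(shape)
        result = model.forward(x)
        assert len(result.features) == embedding_dim(cfg)
        assert result.reconstruction.shape == shape


class TestForward:
    def test_inference_determinism(self):
        """Repeated inference passes are bit-identical (BN in eval mode,
        variational sampling disabled)."""
        for variant in ("U_AE", "U_VAE"):
            cfg = AutoencoderConfig(variant, latent_dim=16 if variant == "U_VAE" else None,
                                    **TINY)
            model = build_model(cfg, seed=0)
            x = np.random.default_rng(1).standard_normal((16, 16, 16))
            r1, r2 = model.forward(x), model.forward(x)
            assert np.array_equal(r1.features, r2.features)
            assert np.array_equal(r1.reconstruction, r2.reconstruction)

    def test_variational_features_are_mu(self):
        cfg = AutoencoderConfig("U_VAE", latent_dim=16, **TINY)
        model = build_model(cfg, seed=0)
        r = model.forward(np.random.default_rng(2).standard_normal((16, 16, 16)))
        assert np.allclose(r.features, r.latent.mu[0])
        assert np.allclose(r.latent.sample, r.latent.mu)  # no sampling at inference

    def test_shape_mismatch_names_expected(self):
        model = build_model(AutoencoderConfig("U_AE", **TINY), seed=0)
        with pytest.raises(ValueError, match=r"\(16, 16, 16\)"):
            model.forward_batch(np.zeros((1, 1, 8, 8, 8), dtype=np.float32))

    def test_unet_uae_differ_only_by_skip_params(self):
        """Same config, two variants: the parameter-name sets differ
        exactly by the skip-fusion path."""
        unet = build_model(AutoencoderConfig("UNET", **TINY), seed=0)
        uae = build_model(AutoencoderConfig("U_AE", **TINY), seed=0)
        diff = unet.parameter_names() - uae.parameter_names()
        assert diff and all(p.startswith("fuse_") for p in diff)
        assert uae.parameter_names() - unet.parameter_names() == set()

    def test_bottleneck_bypass_probe(self):
        """Zeroing the bottleneck features: the UNET reconstruction
        still depends on the input (skip connections bypass the
        bottleneck), the U_AE reconstruction does not."""
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal((1, 1, 16, 16, 16)).astype(np.float32)
        x2 = rng.standard_normal((1, 1, 16, 16, 16)).astype(np.float32)

        def recon_with_zero_bottleneck(model, x):
            cache = model.forward_batch(x)
            # re-run the decoder on a zeroed bottleneck, keeping skips
            cfg = model.config
            skips = []
            h = x
            for i in range(cfg.n_blocks):
                b = model.modules[f"enc_block_{i}"].forward(h)
                skips.append(b)
                h = model._pools[i].forward(b)
            y = np.zeros_like(model.modules["bottleneck"].forward(h))
            for i in range(cfg.n_blocks - 1, -1, -1):
                y = model.modules[f"up_{i}"].forward(y)
                y = model._pad_to(y, skips[i].shape[2:])
                if cfg.variant == "UNET":
                    y = model.modules[f"fuse_{i}"].forward(
                        np.concatenate([y, skips[i]], axis=1))
                y = model.modules[f"dec_block_{i}"].forward(y)
            return model.modules["out_conv"].forward(y)

        for variant, depends in (("UNET", True), ("U_AE", False)):
            model = build_model(AutoencoderConfig(variant, **TINY), seed=0)
            model.set_training(False)
            r1 = recon_with_zero_bottleneck(model, x1)
            r2 = recon_with_zero_bottleneck(model, x2)
            differs = not np.allclose(r1, r2, atol=1e-6)
            assert differs == depends, variant


class TestStructure:
    def test_parameter_count_monotone(self):
        """Deeper or wider configs never have fewer parameters."""
        base = build_model(AutoencoderConfig("U_AE", input_shape=(16, 16, 16),
                                             n_blocks=2, channel_schedule=(4, 8)),
                           seed=0).parameter_count()
        deeper = build_model(AutoencoderConfig("U_AE", input_shape=(16, 16, 16),
                                               n_blocks=3, channel_schedule=(4, 8, 16)),
                             seed=0).parameter_count()
        wider = build_model(AutoencoderConfig("U_AE", input_shape=(16, 16, 16),
                                              n_blocks=2, channel_schedule=(8, 16)),
                            seed=0).parameter_count()
        assert deeper >= base and wider >= base

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        from neuroembed.models import Autoencoder

        cfg = AutoencoderConfig("U_VAE", latent_dim=12, **TINY)
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(4).standard_normal((16, 16, 16))
        before = model.forward(x)
        model.save(str(tmp_path / "ckpt"))
        loaded = Autoencoder.load(str(tmp_path / "ckpt"))
        after = loaded.forward(x)
        assert np.array_equal(before.features, after.features)
        assert np.array_equal(before.reconstruction, after.reconstruction)
        assert loaded.config == cfg
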