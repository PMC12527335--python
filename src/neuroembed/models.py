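"""The four candidate 3D autoencoder architectures.

All four share the same convolutional skeleton: an encoder of
``n_blocks`` conv blocks (each block = twice [conv3d k3 s1 p1 ->
batchnorm -> ReLU]) with 2x2x2 max pooling after every block, a
bottleneck, and a mirrored decoder using transposed convolutions
(k2 s2).  The channel count expands along the default schedule
(4, 8, 16, 32, 64, 128).

Variants:

* ``UNET``  - conventional autoencoder WITH skip connections: each
  encoder block's pre-pool output is concatenated onto the matching
  decoder stage (channel concatenation, fused by a dedicated conv).
  Information can bypass the bottleneck.
* ``U_AE``  - identical minus the skip wiring; every bit of information
  must pass through the bottleneck.
* ``U_VAE`` - variational U_AE: two separate bottleneck conv blocks
  produce mu and log-variance volumes, each flattened and linearly
  projected to ``latent_dim`` (default 2048); a reparameterization step
  samples the latent during training (mu is used at inference).
* ``VAE``   - conv downsampling followed by a fully connected
  bottleneck straight to ``latent_dim``; no bottleneck conv block.

The embedding of a scan is the flattened bottleneck activation
(conventional variants) or the latent mean mu (variational variants).
No convolutional bottleneck shape factors to exactly 2,048 at the full
template grid, so the linear projection above is how the variational
variants reach their fixed 2,048-dimensional latent.
"""

from __future__ import annotations

import json
import os
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from . import nn

VARIANTS = ("UNET", "U_AE", "U_VAE", "VAE")
VARIATIONAL = ("U_VAE", "VAE")

DEFAULT_SCHEDULE = (4, 8, 16, 32, 64, 128)
DEFAULT_INPUT_SHAPE = (182, 218, 160)


@dataclass(frozen=True)
class AutoencoderConfig:
    variant: str
    input_shape: tuple = DEFAULT_INPUT_SHAPE
    n_blocks: int = 6
    channel_schedule: tuple = DEFAULT_SCHEDULE
    latent_dim: int | None = None
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        object.__setattr__(self, "channel_schedule", tuple(int(c) for c in self.channel_schedule))
        if len(self.input_shape) != 3:
            raise ValueError("input_shape must be a 3-tuple")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if len(self.channel_schedule) != self.n_blocks:
            raise ValueError("channel_schedule length must equal n_blocks")
        if any(b >= a for a, b in zip(self.channel_schedule[1:], self.channel_schedule)):
            raise ValueError("channel_schedule must be strictly increasing")
        if self.is_variational:
            if self.latent_dim is None:
                object.__setattr__(self, "latent_dim", 2048)
            if self.latent_dim < 1:
                raise ValueError("latent_dim must be positive")
        elif self.latent_dim is not None:
            raise ValueError("latent_dim applies only to variational variants")
        shape = self.input_shape
        for _ in range(self.n_blocks):
            shape = tuple(s // 2 for s in shape)
        if min(shape) < 1:
            raise ValueError(
                f"input_shape {self.input_shape} collapses to {shape} after "
                f"{self.n_blocks} poolings; need every dimension >= 2**n_blocks")

    @property
    def is_variational(self) -> bool:
        return self.variant in VARIATIONAL

    @property
    def bottleneck_shape(self) -> tuple:
        shape = self.input_shape
        for _ in range(self.n_blocks):
            shape = tuple(s // 2 for s in shape)
        return shape

    def to_dict(self) -> dict:
        return {"variant": self.variant, "input_shape": list(self.input_shape),
                "n_blocks": self.n_blocks,
                "channel_schedule": list(self.channel_schedule),
                "latent_dim": self.latent_dim, "dropout_rate": self.dropout_rate}

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderConfig":
        return cls(variant=d["variant"], input_shape=tuple(d["input_shape"]),
                   n_blocks=d["n_blocks"],
                   channel_schedule=tuple(d["channel_schedule"]),
                   latent_dim=d.get("latent_dim"),
                   dropout_rate=d.get("dropout_rate", 0.0))


def embedding_dim(config: AutoencoderConfig) -> int:
    """Exact number of features a forward pass produces.

    Conventional variants: product of the bottleneck spatial dimensions
    (input floored-halved n_blocks times) times the bottleneck channel
    count (last schedule entry).  Variational variants: latent_dim.
    """
    if config.is_variational:
        return int(config.latent_dim)
    return int(np.prod(config.bottleneck_shape) * config.channel_schedule[-1])


@dataclass
class LatentSample:
    """Variational latent: sample = mu + sigma * eps (eps ~ N(0,1)) in
    training; sample = mu at inference."""
    mu: np.ndarray
    sigma: np.ndarray
    sample: np.ndarray


@dataclass
class ForwardResult:
    features: np.ndarray
    reconstruction: np.ndarray
    latent: LatentSample | None = None


def _conv_block(c_in, c_out, rng, dropout=0.0, drop_rng=None):
    layers = []
    for cin in (c_in, c_out):
        layers += [nn.Conv3d(cin, c_out, rng), nn.BatchNorm3d(c_out), nn.ReLU()]
        if dropout > 0:
            layers.append(nn.Dropout(dropout, drop_rng))
    return nn.Sequential(*layers)


class Autoencoder:
    """One of the four variants; see module docstring.

    The training loop drives ``forward_batch``/``backward_batch`` on
    (N, 1, D, H, W) arrays; ``forward`` is the single-volume inference
    surface returning a :class:`ForwardResult`.
    """

    def __init__(self, config: AutoencoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._sample_rng = np.random.default_rng(seed + 1)
        self._drop_rng = np.random.default_rng(seed + 2)
        ch = config.channel_schedule
        dr = config.dropout_rate
        m = OrderedDict()
        c_prev = 1
        for i, c in enumerate(ch):
            m[f"enc_block_{i}"] = _conv_block(c_prev, c, rng, dr, self._drop_rng)
            c_prev = c
        cb = ch[-1]
        if config.variant in ("UNET", "U_AE"):
            m["bottleneck"] = _conv_block(cb, cb, rng, dr, self._drop_rng)
        elif config.variant == "U_VAE":
            m["bottleneck_mu"] = _conv_block(cb, cb, rng)
            m["bottleneck_logvar"] = _conv_block(cb, cb, rng)
        flat = int(np.prod(config.bottleneck_shape)) * cb
        if config.is_variational:
            m["fc_mu"] = nn.Linear(flat, config.latent_dim, rng)
            m["fc_logvar"] = nn.Linear(flat, config.latent_dim, rng)
            m["fc_decode"] = nn.Linear(config.latent_dim, flat, rng)
        for i in range(config.n_blocks - 1, -1, -1):
            c_up = ch[i + 1] if i + 1 < config.n_blocks else cb
            m[f"up_{i}"] = nn.ConvTranspose3d(c_up, ch[i], rng)
            if config.variant == "UNET":
                m[f"fuse_{i}"] = nn.Sequential(
                    nn.Conv3d(2 * ch[i], ch[i], rng), nn.BatchNorm3d(ch[i]), nn.ReLU())
            m[f"dec_block_{i}"] = _conv_block(ch[i], ch[i], rng, dr, self._drop_rng)
        m["out_conv"] = nn.Conv3d(ch[0], 1, rng)
        self.modules = m
        self._pools = [nn.MaxPool3d() for _ in range(config.n_blocks)]
        self.set_training(False)

    # ---- plumbing -------------------------------------------------

    def set_training(self, flag: bool):
        self.training = flag
        nn.set_training(list(self.modules.values()), flag)

    def named_parameters(self):
        refs = []
        for mname, module in self.modules.items():
            for j, leaf in enumerate(nn.iter_layers(module)):
                for pname in leaf.params:
                    refs.append((f"{mname}/{j}.{pname}", leaf, pname))
        return refs

    def parameter_names(self):
        return {path for path, _, _ in self.named_parameters()}

    def parameter_count(self) -> int:
        return int(sum(layer.params[n].size for _, layer, n in self.named_parameters()))

    def zero_grads(self):
        nn.zero_grads(list(self.modules.values()))

    # ---- forward / backward --------------------------------------

    def _check_shape(self, x):
        if x.shape[2:] != self.config.input_shape:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} does not match the model's "
                f"expected shape {self.config.input_shape}")

    @staticmethod
    def _pad_to(y, target):
        pads = [(0, t - s) for s, t in zip(y.shape[2:], target)]
        if any(p != (0, 0) for p in pads):
            y = np.pad(y, [(0, 0), (0, 0)] + pads)
        return y

    def forward_batch(self, x: np.ndarray) -> dict:
        """Full pass on (N, 1, D, H, W); caches intermediates for backward."""
        self._check_shape(x)
        cfg = self.config
        skips, skip_shapes = [], []
        h = x
        for i in range(cfg.n_blocks):
            b = self.modules[f"enc_block_{i}"].forward(h)
            skips.append(b if cfg.variant == "UNET" else None)
            skip_shapes.append(b.shape[2:])
            h = self._pools[i].forward(b)
        cache = {"skip_shapes": skip_shapes, "skips_kept": cfg.variant == "UNET"}
        n = x.shape[0]
        latent = None
        if cfg.variant in ("UNET", "U_AE"):
            z = self.modules["bottleneck"].forward(h)
            features = z.reshape(n, -1)
            y = z
        else:
            if cfg.variant == "U_VAE":
                mu_vol = self.modules["bottleneck_mu"].forward(h)
                lv_vol = self.modules["bottleneck_logvar"].forward(h)
                mu = self.modules["fc_mu"].forward(mu_vol.reshape(n, -1))
                logvar = self.modules["fc_logvar"].forward(lv_vol.reshape(n, -1))
            else:
                flat = h.reshape(n, -1)
                mu = self.modules["fc_mu"].forward(flat)
                logvar = self.modules["fc_logvar"].forward(flat)
            sigma = np.exp(0.5 * logvar)
            if self.training:
                eps = self._sample_rng.standard_normal(mu.shape).astype(mu.dtype)
            else:
                eps = np.zeros_like(mu)
            zs = mu + sigma * eps
            cache.update(sigma=sigma, eps=eps, enc_out_shape=h.shape)
            latent = LatentSample(mu=mu, sigma=sigma, sample=zs)
            features = mu
            y = self.modules["fc_decode"].forward(zs)
            y = y.reshape(n, cfg.channel_schedule[-1], *cfg.bottleneck_shape)
        cache["pre_pad_shapes"] = []
        for i in range(cfg.n_blocks - 1, -1, -1):
            y = self.modules[f"up_{i}"].forward(y)
            cache["pre_pad_shapes"].append(y.shape[2:])
            y = self._pad_to(y, skip_shapes[i])
            if cfg.variant == "UNET":
                y = self.modules[f"fuse_{i}"].forward(
                    np.concatenate([y, skips[i]], axis=1))
            y = self.modules[f"dec_block_{i}"].forward(y)
        recon = self.modules["out_conv"].forward(y)
        cache.update(features=features, recon=recon, latent=latent)
        return cache

    def backward_batch(self, cache: dict, drecon: np.ndarray,
                       dmu_extra: np.ndarray | None = None,
                       dlogvar_extra: np.ndarray | None = None):
        """Backprop given dL/d(reconstruction) and, for variational
        variants, extra dL/dmu and dL/dlogvar from the KLD term."""
        cfg = self.config
        dy = self.modules["out_conv"].backward(drecon)
        dskips = [None] * cfg.n_blocks
        pre_pad = cache["pre_pad_shapes"]
        # decoder ran i = n_blocks-1 .. 0, so backprop visits i = 0 .. n_blocks-1
        for i in range(cfg.n_blocks):
            dy = self.modules[f"dec_block_{i}"].backward(dy)
            if cfg.variant == "UNET":
                dcat = self.modules[f"fuse_{i}"].backward(dy)
                c = cfg.channel_schedule[i]
                dy, dskips[i] = dcat[:, :c], dcat[:, c:]
            pp = pre_pad[cfg.n_blocks - 1 - i]
            dy = dy[:, :, : pp[0], : pp[1], : pp[2]]
            dy = self.modules[f"up_{i}"].backward(dy)
        n = drecon.shape[0]
        if cfg.variant in ("UNET", "U_AE"):
            dz = dy
            dh = self.modules["bottleneck"].backward(dz)
        else:
            dzs = self.modules["fc_decode"].backward(dy.reshape(n, -1))
            sigma, eps = cache["sigma"], cache["eps"]
            dmu = dzs.copy()
            dlogvar = dzs * eps * 0.5 * sigma
            if dmu_extra is not None:
                dmu = dmu + dmu_extra.astype(dmu.dtype)
            if dlogvar_extra is not None:
                dlogvar = dlogvar + dlogvar_extra.astype(dlogvar.dtype)
            dflat_mu = self.modules["fc_mu"].backward(dmu)
            dflat_lv = self.modules["fc_logvar"].backward(dlogvar)
            if cfg.variant == "U_VAE":
                shape = (n, cfg.channel_schedule[-1], *cfg.bottleneck_shape)
                dh = (self.modules["bottleneck_mu"].backward(dflat_mu.reshape(shape))
                      + self.modules["bottleneck_logvar"].backward(dflat_lv.reshape(shape)))
            else:
                dh = (dflat_mu + dflat_lv).reshape(cache["enc_out_shape"])
        for i in range(cfg.n_blocks - 1, -1, -1):
            db = self._pools[i].backward(dh)
            if dskips[i] is not None:
                db = db + dskips[i]
            dh = self.modules[f"enc_block_{i}"].backward(db)
        return dh

    def forward(self, volume: np.ndarray) -> ForwardResult:
        """Inference pass on a single 3D volume (no sampling, no dropout)."""
        volume = np.asarray(volume, dtype=nn.DTYPE)
        if volume.ndim != 3:
            raise ValueError("forward expects a single-channel 3D volume")
        was_training = self.training
        self.set_training(False)
        try:
            cache = self.forward_batch(volume[None, None])
        finally:
            self.set_training(was_training)
        return ForwardResult(features=cache["features"][0].astype(np.float64),
                             reconstruction=cache["recon"][0, 0],
                             latent=cache["latent"])

    # ---- checkpointing -------------------------------------------

    def save(self, directory: str):
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=1)
        arrays = {}
        for path, layer, name in self.named_parameters():
            arrays[path.replace("/", "__")] = layer.params[name]
        for mname, module in self.modules.items():
            for j, leaf in enumerate(nn.iter_layers(module)):
                if isinstance(leaf, nn.BatchNorm3d):
                    arrays[f"{mname}__{j}.running_mean"] = leaf.running_mean
                    arrays[f"{mname}__{j}.running_var"] = leaf.running_var
        np.savez(os.path.join(directory, "weights.npz"), **arrays)

    @classmethod
    def load(cls, directory: str) -> "Autoencoder":
        with open(os.path.join(directory, "config.json")) as fh:
            config = AutoencoderConfig.from_dict(json.load(fh))
        model = cls(config)
        with np.load(os.path.join(directory, "weights.npz")) as data:
            for path, layer, name in model.named_parameters():
                layer.params[name] = data[path.replace("/", "__")].copy()
            for mname, module in model.modules.items():
                for j, leaf in enumerate(nn.iter_layers(module)):
                    if isinstance(leaf, nn.BatchNorm3d):
                        leaf.running_mean = data[f"{mname}__{j}.running_mean"].copy()
                        leaf.running_var = data[f"{mname}__{j}.running_var"].copy()
        return model


def build_model(config: AutoencoderConfig, seed: int = 0) -> Autoencoder:
    """Construct one of the four variants with seeded initialization."""
    return Autoencoder(config, seed=seed)
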