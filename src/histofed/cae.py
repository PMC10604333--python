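"""Custom convolutional auto-encoder used as the retrieval feature extractor.

The network is an encoder / residual-bottleneck / decoder stack trained to
reconstruct its input under mean squared error; after training, the decoder
is discarded and the encoder maps each patch to a single embedding vector
(200 features at full geometry) used for similarity search.

Architecture, at the default full geometry (224 x 224 x 3 input):

* encoder: four 3x3 convolutions with filters [32, 64, 128, 256] and strides
  [1, 2, 2, 2] (same padding, ReLU), spatial trace 224 -> 224 -> 112 -> 56 -> 28;
* bottleneck: a residual block of four stride-1 3x3 convolutions with filters
  [64, 32, 1, 256]; the block input is added back to its output (through a
  learned 1x1 projection when the channel counts differ), followed by global
  average pooling and a fully-connected layer to the ``latent_dim``-feature
  embedding;
* decoder: a fully-connected layer expands the embedding back to the
  bottleneck spatial grid, then four 3x3 transposed convolutions with filters
  [128, 64, 32, 3] and strides [2, 2, 2, 1] mirror the encoder trace back to
  the input shape; the output passes through a sigmoid so reconstructions
  stay in [0, 1];
* one additive skip connection carries the first encoder activation to the
  decoder activation entering the final transposed convolution (the two ends
  sit at the stride-1 extremes, so their shapes match by construction).

Training is plain mini-batch SGD on the reconstruction MSE, exactly the
per-batch update ``w <- w - eta * grad`` used by each federation client.
All randomness (init, shuffling) flows through explicit NumPy generators, so
every operation is bit-reproducible given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .types import FeatureVector, ModelWeights, PatchImage


class ConfigError(ValueError):
    """Raised when a CAEConfig violates its structural invariants."""


class TrainingDivergedError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""


@dataclass
class CAEConfig:
    """Structural hyperparameters of the auto-encoder.

    Defaults are the full histopathology geometry: 224-pixel patches and a
    200-feature embedding.  :meth:`reduced` gives a small geometry suitable
    for fast experiments and tests.
    """

    input_size: int = 224
    channels_in: int = 3
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256)
    encoder_strides: tuple[int, ...] = (1, 2, 2, 2)
    bottleneck_filters: tuple[int, ...] = (64, 32, 1, 256)
    bottleneck_strides: tuple[int, ...] = (1, 1, 1, 1)
    decoder_filters: tuple[int, ...] = (128, 64, 32, 3)
    decoder_strides: tuple[int, ...] = (2, 2, 2, 1)
    kernel_size: int = 3
    latent_dim: int = 200
    skip_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.encoder_filters = tuple(self.encoder_filters)
        self.encoder_strides = tuple(self.encoder_strides)
        self.bottleneck_filters = tuple(self.bottleneck_filters)
        self.bottleneck_strides = tuple(self.bottleneck_strides)
        self.decoder_filters = tuple(self.decoder_filters)
        self.decoder_strides = tuple(self.decoder_strides)
        self.validate()

    def validate(self) -> None:
        if len(self.encoder_filters) != len(self.encoder_strides):
            raise ConfigError("encoder_filters and encoder_strides differ in length")
        if len(self.decoder_filters) != len(self.decoder_strides):
            raise ConfigError("decoder_filters and decoder_strides differ in length")
        if len(self.bottleneck_filters) != len(self.bottleneck_strides):
            raise ConfigError("bottleneck_filters and bottleneck_strides differ in length")
        if self.decoder_filters[-1] != self.channels_in:
            raise ConfigError(
                f"decoder must end in channels_in={self.channels_in} filters, "
                f"got {self.decoder_filters[-1]}"
            )
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd for same-padding symmetry")
        if any(s != 1 for s in self.bottleneck_strides):
            raise ConfigError("residual bottleneck requires stride 1 throughout")
        # The decoder mirrors the encoder's spatial trace; that is only
        # well-defined when its stride schedule is the encoder's reversed.
        if tuple(reversed(self.decoder_strides)) != self.encoder_strides:
            raise ConfigError(
                "decoder_strides must be encoder_strides reversed "
                f"({self.decoder_strides} vs {self.encoder_strides})"
            )
        if min(self.encoder_filters + self.bottleneck_filters + self.decoder_filters) < 1:
            raise ConfigError("filter counts must be >= 1")
        if self.skip_enabled and self.decoder_filters_pre_last() != self.encoder_filters[0]:
            raise ConfigError(
                "skip endpoints mismatch: encoder layer 1 activation has "
                f"{self.encoder_filters[0]} channels but the decoder activation "
                f"before its last layer has {self.decoder_filters_pre_last()}"
            )

    def decoder_filters_pre_last(self) -> int:
        if len(self.decoder_filters) >= 2:
            return self.decoder_filters[-2]
        return self.encoder_filters[-1]  # degenerate single-layer decoder

    def spatial_trace(self) -> list[int]:
        """Per-layer encoder spatial sizes, input first."""
        sizes = [self.input_size]
        for s in self.encoder_strides:
            sizes.append(-(-sizes[-1] // s))
        return sizes

    @classmethod
    def reduced(cls, latent_dim: int = 16, input_size: int = 32, seed: int = 0) -> "CAEConfig":
        """Small geometry: 32-pixel patches, thin filters, 16-feature embedding."""
        return cls(
            input_size=input_size,
            encoder_filters=(8, 16, 16, 32),
            encoder_strides=(1, 2, 2, 2),
            bottleneck_filters=(8, 4, 1, 32),
            bottleneck_strides=(1, 1, 1, 1),
            decoder_filters=(16, 16, 8, 3),
            decoder_strides=(2, 2, 2, 1),
            latent_dim=latent_dim,
            seed=seed,
        )


class CAE:
    """The auto-encoder with hand-wired forward and reverse passes."""

    def __init__(self, config: CAEConfig, seed: int | None = None):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        k = config.kernel_size
        sizes = config.spatial_trace()
        self.sizes = sizes

        self.enc: list[nn.Conv2D] = []
        ci = config.channels_in
        for i, (co, s) in enumerate(zip(config.encoder_filters, config.encoder_strides)):
            self.enc.append(nn.Conv2D(f"enc{i + 1}", ci, co, k, s, rng))
            ci = co

        self.res: list[nn.Conv2D] = []
        res_in = ci
        for i, co in enumerate(config.bottleneck_filters):
            self.res.append(nn.Conv2D(f"res{i + 1}", ci, co, k, 1, rng))
            ci = co
        self.res_proj: nn.Conv2D | None = None
        if ci != res_in:
            # identity path needs a learned 1x1 projection to the block output
            self.res_proj = nn.Conv2D("res_proj", res_in, ci, 1, 1, rng)
        self._res_out_channels = ci

        self.gap = nn.GlobalAvgPool()
        self.fc_latent = nn.Dense("fc_latent", ci, config.latent_dim, rng)

        hb = sizes[-1]
        self._bottleneck_hw = (hb, hb)
        self._expand_channels = config.encoder_filters[-1]
        self.fc_expand = nn.Dense(
            "fc_expand", config.latent_dim, hb * hb * self._expand_channels, rng
        )

        self.dec: list[nn.ConvTranspose2D] = []
        ci = self._expand_channels
        targets = sizes[-2::-1]  # mirror of the encoder trace
        n_dec = len(config.decoder_filters)
        for i, (co, s) in enumerate(zip(config.decoder_filters, config.decoder_strides)):
            out_hw = (targets[i], targets[i])
            scale = 1.0 if i == n_dec - 1 else 2.0  # gentler init into the sigmoid
            self.dec.append(
                nn.ConvTranspose2D(f"dec{i + 1}", ci, co, k, s, out_hw, rng, scale)
            )
            ci = co

        self._relu_pool: list[nn.ReLU] = []
        self.out_act = nn.Sigmoid()

    # -- parameter plumbing -------------------------------------------------

    def _param_layers(self) -> list[nn.Layer]:
        layers: list[nn.Layer] = [*self.enc, *self.res]
        if self.res_proj is not None:
            layers.append(self.res_proj)
        layers += [self.fc_latent, self.fc_expand, *self.dec]
        return layers

    def get_weights(self) -> ModelWeights:
        entries = {}
        for layer in self._param_layers():
            entries.update({k: v.copy() for k, v in layer.params().items()})
        return ModelWeights(entries)

    def set_weights(self, weights: ModelWeights) -> None:
        own = {}
        for layer in self._param_layers():
            own.update(layer.params())
        if sorted(own) != weights.names():
            raise ValueError(
                "weight schema mismatch: model expects "
                f"{sorted(own)[:3]}... got {weights.names()[:3]}..."
            )
        for name, arr in own.items():
            src = weights[name]
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {arr.shape}")
            arr[...] = src

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._param_layers() for p in layer.params().values())

    # -- forward / backward -------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        n_exp = self.config.input_size
        if x.shape[1:] != (n_exp, n_exp, self.config.channels_in):
            raise ValueError(
                f"expected patches of shape ({n_exp}, {n_exp}, "
                f"{self.config.channels_in}), got {x.shape[1:]}"
            )
        return x

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full pass; returns (reconstruction, latent)."""
        x = self._check_batch(x)
        self._acts = {}
        h = x
        self._enc_relus = []
        for i, conv in enumerate(self.enc):
            h = conv.forward(h)
            relu = nn.ReLU()
            h = relu.forward(h)
            self._enc_relus.append(relu)
            if i == 0:
                self._skip_act = h
        res_in = h
        self._res_relus = []
        for conv in self.res[:-1]:
            h = conv.forward(h)
            relu = nn.ReLU()
            h = relu.forward(h)
            self._res_relus.append(relu)
        h = self.res[-1].forward(h)
        identity = res_in if self.res_proj is None else self.res_proj.forward(res_in)
        h = h + identity
        self._res_out_relu = nn.ReLU()
        h = self._res_out_relu.forward(h)

        pooled = self.gap.forward(h)
        latent = self.fc_latent.forward(pooled)

        d = self.fc_expand.forward(latent)
        self._expand_relu = nn.ReLU()
        d = self._expand_relu.forward(d)
        hb, wb = self._bottleneck_hw
        d = d.reshape(d.shape[0], hb, wb, self._expand_channels)
        self._dec_relus = []
        for i, tconv in enumerate(self.dec):
            if i == len(self.dec) - 1 and self.config.skip_enabled:
                d = d + self._skip_act
            d = tconv.forward(d)
            if i < len(self.dec) - 1:
                relu = nn.ReLU()
                d = relu.forward(d)
                self._dec_relus.append(relu)
        recon = self.out_act.forward(d)
        return recon, latent

    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        """Encoder-only pass; returns the (N, latent_dim) embedding matrix."""
        x = self._check_batch(x)
        h = x
        for conv in self.enc:
            h = np.maximum(conv.forward(h), 0.0)
        res_in = h
        for conv in self.res[:-1]:
            h = np.maximum(conv.forward(h), 0.0)
        h = self.res[-1].forward(h)
        identity = res_in if self.res_proj is None else self.res_proj.forward(res_in)
        h = np.maximum(h + identity, 0.0)
        return self.fc_latent.forward(self.gap.forward(h))

    def loss_and_grads(self, x: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Reconstruction MSE on the batch and its gradient for every parameter."""
        x = self._check_batch(x)
        recon, _ = self.forward(x)
        loss = nn.mse(x, recon)
        dy = nn.mse_grad_wrt_output(x, recon)

        d = self.out_act.backward(dy)
        dskip = None
        for i in range(len(self.dec) - 1, -1, -1):
            if i < len(self.dec) - 1:
                d = self._dec_relus[i].backward(d)
            d = self.dec[i].backward(d)
            if i == len(self.dec) - 1 and self.config.skip_enabled:
                dskip = d  # gradient flowing into the skip source
        hb, wb = self._bottleneck_hw
        d = d.reshape(d.shape[0], hb * wb * self._expand_channels)
        d = self._expand_relu.backward(d)
        dlatent = self.fc_expand.backward(d)

        dpooled = self.fc_latent.backward(dlatent)
        dres = self.gap.backward(dpooled)
        dres = self._res_out_relu.backward(dres)
        dres_identity = dres
        h = self.res[-1].backward(dres)
        for i in range(len(self.res) - 2, -1, -1):
            h = self._res_relus[i].backward(h)
            h = self.res[i].backward(h)
        if self.res_proj is None:
            dres_in = dres_identity
        else:
            dres_in = self.res_proj.backward(dres_identity)
        h = h + dres_in

        for i in range(len(self.enc) - 1, -1, -1):
            if i == 0 and self.config.skip_enabled and dskip is not None:
                h = h + dskip
            h = self._enc_relus[i].backward(h)
            h = self.enc[i].backward(h)

        grads = {}
        for layer in self._param_layers():
            grads.update(layer.grads())
        return loss, grads


def build_cae(config: CAEConfig, seed: int | None = None) -> CAE:
    """Construct the auto-encoder with deterministic weight initialisation."""
    return CAE(config, seed=seed)


def mse_loss(i: np.ndarray, o: np.ndarray) -> float:
    """Mean squared error between an input batch and its reconstruction."""
    return nn.mse(i, o)


def encode(model: CAE, patches: Sequence[PatchImage], batch_size: int = 32) -> list[FeatureVector]:
    """Embed patches in order; deterministic and batch-order invariant."""
    out: list[FeatureVector] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        z = model.encode_batch(np.stack([p.pixels for p in chunk]))
        for p, v in zip(chunk, z):
            out.append(
                FeatureVector(v, patch_id=p.patch_id, label=p.label,
                              magnification=p.magnification)
            )
    return out


def train_local(
    model: CAE,
    weights: ModelWeights,
    data: Sequence[PatchImage],
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ModelWeights, list[float]]:
    """One client's local update: E epochs of plain SGD on reconstruction MSE.

    The dataset is reshuffled each epoch with the supplied generator (or a
    fresh one from ``seed``) and split into batches of ``batch_size`` (the
    last batch may be smaller).  Returns the updated weights and the
    per-epoch mean batch loss.  Passing an already-advanced ``rng`` lets a
    federation continue one client's shuffle stream across rounds, which is
    what makes a single-client federation bit-identical to plain local
    training.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    if epochs < 1 or batch_size < 1:
        raise ValueError("epochs and batch_size must be >= 1")
    if lr < 0:
        raise ValueError("learning rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    model.set_weights(weights)
    x_all = np.stack([p.pixels for p in data])
    params = {}
    for layer in model._param_layers():
        params.update(layer.params())

    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(x_all))
        batch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            loss, grads = model.loss_and_grads(x_all[idx])
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss!r} at epoch {len(trace) + 1}, "
                    f"batch starting {start}; reduce the learning rate"
                )
            for name, g in grads.items():
                params[name] -= lr * g
            batch_losses.append(loss)
        trace.append(float(np.mean(batch_losses)))
    return model.get_weights(), trace
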