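"""The patch-based fully convolutional encoder-decoder network.

Architecture summary (input ``(3, D, D)``, defaults in parentheses):

* **Stem** — a 4x4/stride-4 "patchify" convolution embedding non-overlapping
  patches into K (96) channels, followed by channels-first LayerNorm.
* **Encoder** — four stages of ConvNeXt blocks (depths 3/3/9/3). Each block
  is: 7x7 depthwise conv -> LayerNorm -> 1x1 conv expanding by 4 -> GELU ->
  1x1 conv projecting back -> per-channel layer-scale gamma -> residual add.
  Stages 1-3 are preceded by LayerNorm + a 2x2/stride-2 downsampling conv.
* **Decoder** — five stages. Each upsamples x2 (parameter-free nearest by
  default, optionally a learned 2x2 transposed conv), concatenates the
  matching encoder skip (stages 0-3; the stem skip is itself upsampled x2
  to match stage 3), then applies two [3x3 conv -> BatchNorm -> ReLU]
  blocks. Decoder convs carry no bias (BatchNorm supplies the affine term).
* **Head** — a single biased 3x3 convolution producing one logit map at the
  input resolution. No sigmoid is applied inside the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import ConfigurationError, ModelConfig
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "FeatureShape", "SegmentationModel", "build_model",
    "encoder_feature_shapes", "count_trainable_parameters",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class FeatureShape:
    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.channels, self.height, self.width) <= 0:
            raise ValueError("FeatureShape fields must be positive")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.channels, self.height, self.width)


class ConvNeXtBlock(nn.Module):
    """Inverted-bottleneck residual block with depthwise spatial mixing."""

    def __init__(self, dim: int, expansion: int, layer_scale_init: float,
                 rng: np.random.Generator):
        super().__init__()
        self.dwconv = nn.Conv2d(dim, dim, 7, padding=3, groups=dim, rng=rng)
        self.norm = nn.ChannelLayerNorm(dim)
        self.pwconv1 = nn.Conv2d(dim, expansion * dim, 1, rng=rng)
        self.pwconv2 = nn.Conv2d(expansion * dim, dim, 1, rng=rng)
        self.gamma = nn.Parameter(np.full(dim, layer_scale_init))

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = self.norm(y)
        y = F.gelu(self.pwconv1(y))
        y = self.pwconv2(y)
        y = y * self.gamma.reshape(1, -1, 1, 1)
        return x + y


class Downsample(nn.Module):
    """LayerNorm followed by a 2x2/stride-2 convolution (between stages)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.ChannelLayerNorm(cin)
        self.conv = nn.Conv2d(cin, cout, 2, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.norm(x))


class DecoderBlock(nn.Module):
    """3x3 conv -> BatchNorm -> ReLU (conv bias omitted)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.bn(self.conv(x)))


class DecoderStage(nn.Module):
    """Upsample x2, optionally concatenate a skip, then two decoder blocks."""

    def __init__(self, cin: int, skip_channels: int, cout: int,
                 upsample_mode: str, rng: np.random.Generator):
        super().__init__()
        self.upsample_mode = upsample_mode
        if upsample_mode == "transposed_conv":
            self.up = nn.ConvTranspose2x2(cin, cin, rng=rng)
        self.block1 = DecoderBlock(cin + skip_channels, cout, rng=rng)
        self.block2 = DecoderBlock(cout, cout, rng=rng)

    def _up(self, x: Tensor) -> Tensor:
        if self.upsample_mode == "transposed_conv":
            return self.up(x)
        return F.upsample_nearest2x(x)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self._up(x)
        if skip is not None:
            x = F.concat_channels(x, skip)
        return self.block2(self.block1(x))


class SegmentationModel(nn.Module):
    """Full encoder-decoder network; ``forward`` returns raw logits."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dims = config.stage_dims
        self.stem_conv = nn.Conv2d(config.input_channels, config.embed_dim,
                                   config.patch_size, stride=config.patch_size,
                                   rng=rng)
        self.stem_norm = nn.ChannelLayerNorm(config.embed_dim)
        self.downsamples = nn.ModuleList(
            Downsample(dims[i], dims[i + 1], rng) for i in range(3))
        self.stages = nn.ModuleList(
            nn.ModuleList(
                ConvNeXtBlock(dims[i], config.expansion_ratio,
                              config.layer_scale_init, rng)
                for _ in range(config.stage_depths[i]))
            for i in range(4))
        dec = config.decoder_channels
        skips = (dims[2], dims[1], dims[0], config.embed_dim, 0)
        ins = (dims[3], dec[0], dec[1], dec[2], dec[3])
        self.decoder = nn.ModuleList(
            DecoderStage(ins[i], skips[i], dec[i], config.upsample_mode, rng)
            for i in range(5))
        self.head = nn.Conv2d(dec[4], 1, 3, padding=1, bias=True, rng=rng)
        # foreground-prior init: start the head at ~12% foreground odds so
        # early training is not dominated by suppressing the background
        self.head.bias.data[:] = -2.0

    # -- forward -----------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4:
            raise ValueError(f"expected a (n, c, h, w) batch, got shape {x.shape}")
        n, c, h, w = x.shape
        if c != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} input channels, got {c}")
        if h % 32 or w % 32:
            raise ValueError(f"spatial size {h}x{w} not divisible by 32")

    def forward_features(self, x: Tensor) -> dict[str, Tensor]:
        """Run the encoder and return named intermediate feature maps."""
        self._check_input(x)
        feats: dict[str, Tensor] = {}
        y = self.stem_norm(self.stem_conv(x))
        feats["stem"] = y
        for i in range(4):
            if i > 0:
                y = self.downsamples[i - 1](y)
            for block in self.stages[i]:
                y = block(y)
            feats[f"stage{i}"] = y
        return feats

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        feats = self.forward_features(x)
        stem_up = F.upsample_nearest2x(feats["stem"])
        skips = [feats["stage2"], feats["stage1"], feats["stage0"], stem_up, None]
        y = feats["stage3"]
        for stage, skip in zip(self.decoder, skips):
            y = stage(y, skip)
        return self.head(y)


def build_model(config: ModelConfig | None = None, *, seed: int = 0) -> SegmentationModel:
    """Construct the network with reproducible seeded initialisation.

    Conv weights use truncated-normal init (sigma=0.02), biases start at
    zero, norm scales at one, and layer-scale gammas at
    ``config.layer_scale_init``.
    """
    if config is None:
        config = ModelConfig()
    if not isinstance(config, ModelConfig):
        raise ConfigurationError("config must be a ModelConfig")
    return SegmentationModel(config, seed=seed)


def encoder_feature_shapes(config: ModelConfig) -> list[FeatureShape]:
    """Stem and per-stage encoder output shapes, computed without weights."""
    d, p = config.input_size, config.patch_size
    shapes = [FeatureShape(config.embed_dim, d // p, d // p)]
    for i, dim in enumerate(config.stage_dims):
        red = p * 2 ** i
        shapes.append(FeatureShape(dim, d // red, d // red))
    return shapes


def count_trainable_parameters(model: SegmentationModel) -> int:
    """Exact count of trainable scalars (kernels, biases, norm affines,
    layer-scale gammas)."""
    return model.num_parameters()


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path: str | Path) -> Path:
    """Write weights (`.npz`) plus a JSON sidecar with the full ModelConfig,
    making the checkpoint self-describing."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))
    return path


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    model = SegmentationModel(config, seed=0)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    model.eval()
    return model
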