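"""Configuration dataclasses for the model, losses, augmentation and training.

Every dataclass validates its own invariants in ``__post_init__`` and can be
round-tripped through plain dicts (and hence YAML) via ``to_dict``/``from_dict``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the patch-based encoder-decoder.

    The defaults reproduce the published network: a stride-4 patchify stem
    embedding 4x4 patches into 96 channels, four ConvNeXt-style stages of
    depths 3/3/9/3 with channel widths doubling per stage, and a five-stage
    convolutional decoder with skip connections.
    """

    input_channels: int = 3
    input_size: int = 512
    patch_size: int = 4
    embed_dim: int = 96
    stage_depths: tuple[int, ...] = (3, 3, 9, 3)
    stage_dims: tuple[int, ...] = (96, 192, 384, 768)
    expansion_ratio: int = 4
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    layer_scale_init: float = 1e-6
    upsample_mode: str = "interpolate"
    pretrained_encoder: bool = False

    def __post_init__(self):
        self.stage_depths = tuple(self.stage_depths)
        self.stage_dims = tuple(self.stage_dims)
        self.decoder_channels = tuple(self.decoder_channels)
        if len(self.stage_depths) != 4 or len(self.stage_dims) != 4:
            raise ConfigurationError(
                "stage_depths and stage_dims must each have length 4")
        if len(self.decoder_channels) != 5:
            raise ConfigurationError("decoder_channels must have length 5")
        if self.input_size % 32 != 0:
            raise ConfigurationError(
                f"input_size must be divisible by 32, got {self.input_size}")
        if self.input_size % self.patch_size != 0:
            raise ConfigurationError(
                "input_size must be divisible by patch_size")
        if self.stage_dims[0] != self.embed_dim:
            raise ConfigurationError("stage_dims[0] must equal embed_dim")
        for i in range(3):
            if self.stage_dims[i + 1] != 2 * self.stage_dims[i]:
                raise ConfigurationError(
                    "stage_dims must double at each stage "
                    f"(stage_dims[{i + 1}] != 2*stage_dims[{i}])")
        if self.upsample_mode not in ("interpolate", "transposed_conv"):
            raise ConfigurationError(
                f"unknown upsample_mode {self.upsample_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage_depths", "stage_dims", "decoder_channels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class LossParams:
    """Hyperparameters of the Tversky/focal compound loss.

    ``beta`` trades false positives against false negatives in the Tversky
    index (0.5 recovers soft Dice); ``gamma`` is the focal focusing exponent
    (0 recovers binary cross-entropy).
    """

    beta: float = 0.5
    gamma: float = 2.0
    smooth: float = 1e-6
    prob_clamp: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigurationError("beta must lie in [0, 1]")
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if self.smooth <= 0 or self.prob_clamp <= 0:
            raise ConfigurationError("smooth and prob_clamp must be positive")


@dataclass
class AugmentConfig:
    """Training-time augmentation recipe.

    Three mutually exclusive exposure transforms gated at p=0.5, three blurs
    gated at p=0.5, a horizontal flip at p=0.5, and an always-on random
    affine (shift/scale/rotation). Geometric transforms are applied jointly
    to image and mask; intensity transforms touch the image only.
    """

    exposure_p: float = 0.5
    clahe_clip: float = 4.0
    clahe_tile: int = 4
    clahe_p: float = 0.9
    gamma_limits: tuple[float, float] = (60.0, 120.0)
    gamma_p: float = 0.9
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    brightness_contrast_p: float = 0.9
    blur_p: float = 0.5
    blur_limit: int = 4
    motion_blur_limit: int = 4
    median_blur_limit: int = 3
    hflip_p: float = 0.5
    affine_p: float = 1.0
    shift_limit: float = 0.2
    scale_limit: float = 0.2
    rotate_limit: float = 20.0
    target_size: int = 512
    seed: int = 0

    def __post_init__(self):
        for name in ("exposure_p", "clahe_p", "gamma_p",
                     "brightness_contrast_p", "blur_p", "hflip_p", "affine_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if min(self.blur_limit, self.motion_blur_limit,
               self.median_blur_limit) < 0:
            raise ConfigurationError("blur limits must be nonnegative")
        self.gamma_limits = tuple(self.gamma_limits)


@dataclass
class SyntheticSpec:
    """Statistical targets for the synthetic radiograph generator.

    Defaults mirror the public pneumothorax benchmark statistics: 22.2%
    positive prevalence, right/left/bilateral laterality mix of
    55.3/36.8/7.8%, and lesion areas with mean 1.37% and SD 1.57% of image
    pixels (positives only).
    """

    image_size: int = 512
    prevalence: float = 0.222
    laterality_probs: tuple[float, float, float] = (0.553, 0.368, 0.078)
    size_mean: float = 1.37
    size_sd: float = 1.57
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        self.laterality_probs = tuple(self.laterality_probs)
        total = sum(self.laterality_probs)
        # printed percentages may sum to 99.9/100.1; renormalise quietly
        if abs(total - 1.0) > 1e-2:
            raise ConfigurationError("laterality_probs must sum to 1")
        self.laterality_probs = tuple(p / total for p in self.laterality_probs)
        if self.size_mean <= 0 or self.size_sd <= 0:
            raise ConfigurationError("size_mean and size_sd must be positive")


# hospital-transfer preset: larger lesions, right-shifted laterality
TMC_PRESET = dict(laterality_probs=(0.611, 0.354, 0.035),
                  size_mean=3.23, size_sd=3.84)


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, plateau LR decay, checkpoint selection)."""

    learning_rate: float = 5e-4
    batch_size: int = 8
    max_epochs: int = 50
    loss: str = "mixed"
    loss_params: LossParams = field(default_factory=LossParams)
    lr_factor: float = 0.5
    lr_patience: int = 3
    min_lr: float = 1e-6
    shuffle_each_epoch: bool = True
    augment_train: bool = True
    augment_val: bool = False
    seed: int = 0
    train_manifest: Optional[str] = None
    val_manifest: Optional[str] = None
    checkpoint_dir: str = "checkpoints"
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")
        if self.loss not in ("tversky", "mixed"):
            raise ConfigurationError("loss must be 'tversky' or 'mixed'")
        if isinstance(self.loss_params, dict):
            self.loss_params = LossParams(**self.loss_params)
        if isinstance(self.model, dict):
            self.model = ModelConfig.from_dict(self.model)
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)


def load_train_config(path: str | Path) -> TrainConfig:
    """Read a YAML file with ``model:``, ``loss:``, ``augment:``, ``train:``
    and ``data:`` blocks into a :class:`TrainConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = dict(raw.get("train", {}))
    loss_block = raw.get("loss", {})
    if "name" in loss_block:
        kwargs["loss"] = loss_block.pop("name")
    if loss_block:
        kwargs["loss_params"] = LossParams(**loss_block)
    if "model" in raw:
        kwargs["model"] = ModelConfig.from_dict(raw["model"])
    if "augment" in raw:
        kwargs["augment"] = AugmentConfig(**raw["augment"])
    data = raw.get("data", {})
    kwargs.setdefault("train_manifest", data.get("train_manifest"))
    kwargs.setdefault("val_manifest", data.get("val_manifest"))
    valid = {f.name for f in fields(TrainConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return TrainConfig(**kwargs)
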