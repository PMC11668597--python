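"""Training-time augmentation pipeline and model-input standardisation.

The recipe applies, per sample:

* one of three exposure transforms (CLAHE, random gamma, random
  brightness/contrast), gated first by the group probability (0.5) and then
  by the chosen technique's own probability (0.9 each);
* one of three blurs (box, motion, median), group probability 0.5, each
  technique p=1;
* a horizontal flip with p=0.5;
* an always-on random affine (shift <=0.2, scale <=0.2, rotation <=20 deg).

Geometric transforms are applied identically to image and mask (bilinear
for the image, nearest for the mask, reflect border handling), intensity
transforms to the image only, so masks always stay binary. Within each
group the technique is chosen uniformly at random. Every draw is fully
determined by ``(config.seed, draw_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import exposure as _skexp
from skimage.transform import AffineTransform, resize as _sk_resize, warp

from .config import AugmentConfig

__all__ = ["AugmentConfig", "AugmentPlan", "Augmenter", "build_augmenter",
           "standardize_input", "IMAGENET_MEAN", "IMAGENET_STD"]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class AugmentPlan:
    """A concrete, fully sampled set of transforms for one draw."""

    exposure: Optional[tuple] = None   # ("clahe",) | ("gamma", g) | ("bc", b, c)
    blur: Optional[tuple] = None       # ("standard", k) | ("motion", k, ang) | ("median", k)
    hflip: bool = False
    affine: Optional[tuple] = None     # (tx, ty, scale, angle_deg)


class Augmenter:
    """Seeded sampler/applier of the augmentation recipe."""

    def __init__(self, config: AugmentConfig | None = None):
        self.config = config or AugmentConfig()

    # -- sampling ----------------------------------------------------------
    def plan(self, draw_seed: int) -> AugmentPlan:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, draw_seed]))
        plan = AugmentPlan()
        if rng.random() < cfg.exposure_p:
            choice = rng.integers(3)
            if choice == 0 and rng.random() < cfg.clahe_p:
                plan.exposure = ("clahe",)
            elif choice == 1 and rng.random() < cfg.gamma_p:
                g = rng.uniform(*cfg.gamma_limits) / 100.0
                plan.exposure = ("gamma", g)
            elif choice == 2 and rng.random() < cfg.brightness_contrast_p:
                b = rng.uniform(-cfg.brightness_limit, cfg.brightness_limit)
                c = rng.uniform(-cfg.contrast_limit, cfg.contrast_limit)
                plan.exposure = ("bc", b, c)
        if rng.random() < cfg.blur_p:
            choice = rng.integers(3)
            if choice == 0 and cfg.blur_limit >= 3:
                plan.blur = ("standard", int(rng.integers(3, cfg.blur_limit + 1)))
            elif choice == 1 and cfg.motion_blur_limit >= 3:
                plan.blur = ("motion", int(rng.integers(3, cfg.motion_blur_limit + 1)),
                             float(rng.uniform(0.0, 180.0)))
            elif choice == 2 and cfg.median_blur_limit >= 3:
                plan.blur = ("median", int(rng.integers(3, cfg.median_blur_limit + 1)))
        plan.hflip = bool(rng.random() < cfg.hflip_p)
        if rng.random() < cfg.affine_p:
            plan.affine = (float(rng.uniform(-cfg.shift_limit, cfg.shift_limit)),
                           float(rng.uniform(-cfg.shift_limit, cfg.shift_limit)),
                           float(1.0 + rng.uniform(-cfg.scale_limit, cfg.scale_limit)),
                           float(rng.uniform(-cfg.rotate_limit, cfg.rotate_limit)))
        return plan

    # -- application -------------------------------------------------------
    def apply(self, image: np.ndarray, mask: np.ndarray,
              draw_seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Augment an 8-bit grayscale image and its binary mask."""
        if image.shape[:2] != mask.shape[:2]:
            raise ValueError(
                f"image {image.shape} and mask {mask.shape} sizes differ")
        plan = self.plan(draw_seed)
        img = np.asarray(image, dtype=np.float64)
        msk = np.asarray(mask, dtype=np.uint8)
        if plan.exposure is not None:
            img = self._apply_exposure(img, plan.exposure)
        if plan.blur is not None:
            img = self._apply_blur(img, plan.blur)
        if plan.hflip:
            img = img[:, ::-1]
            msk = msk[:, ::-1]
        if plan.affine is not None:
            img, msk = self._apply_affine(img, msk, plan.affine)
        return (np.clip(np.rint(img), 0, 255).astype(np.uint8),
                msk.astype(np.uint8))

    def _apply_exposure(self, img: np.ndarray, spec: tuple) -> np.ndarray:
        if spec[0] == "clahe":
            cfg = self.config
            h, w = img.shape
            kernel = (max(1, h // cfg.clahe_tile), max(1, w // cfg.clahe_tile))
            out = _skexp.equalize_adapthist(
                np.clip(img, 0, 255).astype(np.uint8), kernel_size=kernel,
                clip_limit=cfg.clahe_clip / 100.0)
            return out * 255.0
        if spec[0] == "gamma":
            return ((np.clip(img, 0, 255) / 255.0) ** spec[1]) * 255.0
        # brightness/contrast: out = img*(1+c) + 255*b
        _, b, c = spec
        return img * (1.0 + c) + 255.0 * b

    @staticmethod
    def _apply_blur(img: np.ndarray, spec: tuple) -> np.ndarray:
        if spec[0] == "standard":
            return ndimage.uniform_filter(img, size=spec[1], mode="reflect")
        if spec[0] == "median":
            return ndimage.median_filter(img, size=spec[1], mode="reflect")
        _, k, angle = spec
        kernel = _motion_kernel(k, angle)
        return ndimage.convolve(img, kernel, mode="reflect")

    @staticmethod
    def _apply_affine(img: np.ndarray, msk: np.ndarray,
                      params: tuple) -> tuple[np.ndarray, np.ndarray]:
        tx, ty, scale, angle = params
        if tx == ty == angle == 0.0 and scale == 1.0:
            return img, msk  # exact identity passthrough
        h, w = img.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=np.deg2rad(angle), scale=scale)
              + AffineTransform(translation=center + [tx * w, ty * h]))
        img_out = warp(img, tf.inverse, order=1, mode="reflect",
                       preserve_range=True)
        msk_out = warp(msk.astype(np.float64), tf.inverse, order=0,
                       mode="reflect", preserve_range=True)
        return img_out, msk_out.astype(np.uint8)


def _motion_kernel(size: int, angle_deg: float) -> np.ndarray:
    """A normalised line kernel of the given length and orientation."""
    kernel = np.zeros((size, size))
    c = (size - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    for t in np.linspace(-c, c, 4 * size):
        r = int(round(c + t * np.sin(theta)))
        col = int(round(c + t * np.cos(theta)))
        if 0 <= r < size and 0 <= col < size:
            kernel[r, col] = 1.0
    return kernel / kernel.sum()


def build_augmenter(config: AugmentConfig | None = None) -> Augmenter:
    """Construct a seeded transform sampler from the recipe config."""
    return Augmenter(config)


def standardize_input(image: np.ndarray, size: int = 512,
                      imagenet: bool = False) -> np.ndarray:
    """Resize to ``size`` square, replicate grayscale to 3 channels, and
    scale to [0, 1] (or normalise by ImageNet statistics when a pretrained
    encoder is active). Returns a (3, size, size) float array."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:  # (H, W, C) -> channel mean to grayscale
        arr = arr.mean(axis=2)
    if arr.shape != (size, size):
        arr = _sk_resize(arr, (size, size), order=1, preserve_range=True,
                         anti_aliasing=False)
    arr = arr / 255.0
    chans = np.repeat(arr[None, :, :], 3, axis=0)
    if imagenet:
        chans = (chans - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
    return chans
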