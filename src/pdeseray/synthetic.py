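"""Synthetic chest-radiograph generator with pneumothorax-like lesions.

Emulates the statistical structure of the public benchmark so every other
module is testable without downloading data: configurable positive
prevalence (default 22.2%), right/left/bilateral laterality mix, and lesion
areas drawn from a log-normal distribution moment-matched to a target mean
and SD in percent-of-image-pixels (defaults 1.37 / 1.57, positives only),
truncated to [0.05%, 25%].

Images are crude but structured: two darker lung-field ellipses on a
vertical intensity gradient, a brighter mediastinal band, sinusoidal rib
banding and additive Gaussian noise. A lesion is a thin crescent — the set
difference of the lung ellipse and a downward-offset copy of itself,
echoing the displaced pleural line of a real pneumothorax — rendered as a
lucent band plus a bright pleural edge. Masks are binary, confined to the
lung fields, and exactly reproducible per ``(seed, index)``.

Laterality follows radiographic display convention: the patient's *right*
lung appears on the *left* of the image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .config import TMC_PRESET, SyntheticSpec
from .data_io import SampleRecord, rle_encode, write_manifest

__all__ = ["SyntheticSpec", "TMC_PRESET", "generate_sample",
           "generate_dataset", "lung_geometry", "lung_bounds",
           "lognormal_params"]

AREA_TRUNC = (0.05, 25.0)  # percent of image pixels
_MAX_ATTEMPTS = 100


def lung_geometry(size: int) -> dict[str, tuple[float, float, float, float]]:
    """Lung-field ellipses as (cx, cy, semi_x, semi_y) in pixels.

    ``"right"`` is the patient's right lung (viewer's left half).
    """
    return {
        "right": (0.30 * size, 0.55 * size, 0.17 * size, 0.30 * size),
        "left": (0.70 * size, 0.55 * size, 0.17 * size, 0.30 * size),
    }


def lung_bounds(size: int, side: str) -> tuple[int, int, int, int]:
    """Bounding box (row0, row1, col0, col1), exclusive upper, of a lung field."""
    cx, cy, a, b = lung_geometry(size)[side]
    return (int(np.floor(cy - b)), int(np.ceil(cy + b)) + 1,
            int(np.floor(cx - a)), int(np.ceil(cx + a)) + 1)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a target mean and SD (same units)."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _crescent_geometry(size: int, side: str, outer_scale: float):
    """Per-column pixel row ranges of the (scaled) lung ellipse."""
    cx, cy, a, b = lung_geometry(size)[side]
    a, b = a * outer_scale, b * outer_scale
    cols = np.arange(max(0, int(np.ceil(cx - a))),
                     min(size - 1, int(np.floor(cx + a))) + 1)
    half = b * np.sqrt(np.clip(1.0 - ((cols - cx) / a) ** 2, 0.0, None))
    lo = np.ceil(cy - half).astype(int)
    hi = np.floor(cy + half).astype(int)
    keep = hi >= lo
    return cols[keep], lo[keep], hi[keep], cy, half[keep]


def _crescent_count(geom, delta: float) -> int:
    """Pixel count of the crescent (ellipse minus its copy shifted down by
    ``delta``) — monotone increasing in ``delta``."""
    _, lo, hi, cy, half = geom
    inner_lo = np.ceil(cy + delta - half).astype(int)
    top = np.minimum(hi, inner_lo - 1)
    return int(np.clip(top - lo + 1, 0, None).sum())


def _crescent_mask(size: int, geom, delta: float) -> np.ndarray:
    cols, lo, hi, cy, half = geom
    inner_lo = np.ceil(cy + delta - half).astype(int)
    top = np.minimum(hi, inner_lo - 1)
    mask = np.zeros((size, size), dtype=bool)
    for c, l, t in zip(cols, lo, top):
        if t >= l:
            mask[max(l, 0):t + 1, c] = True
    return mask


def _fit_crescent(size: int, side: str, target_px: int, outer_scale: float,
                  iters: int = 30) -> np.ndarray | None:
    """Binary-search the offset so the crescent hits ``target_px`` pixels.

    The crescent is the set difference of the lung ellipse and a
    downward-offset copy of itself, so its area grows monotonically with
    the offset; returns None when even the full ellipse is too small.
    """
    _, _, _, b = lung_geometry(size)[side]
    geom = _crescent_geometry(size, side, outer_scale)
    hi = 2.0 * b * outer_scale + 2.0
    if _crescent_count(geom, hi) < target_px:
        return None
    lo = 0.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if _crescent_count(geom, mid) < target_px:
            lo = mid
        else:
            hi = mid
    return _crescent_mask(size, geom, hi)


def _draw_area_pct(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    mu, sigma = lognormal_params(spec.size_mean, spec.size_sd)
    for _ in range(_MAX_ATTEMPTS):
        pct = float(np.exp(rng.normal(mu, sigma)))
        if AREA_TRUNC[0] <= pct <= AREA_TRUNC[1]:
            return pct
    return float(np.clip(pct, *AREA_TRUNC))


def _render_thorax(size: int, rng: np.random.Generator) -> np.ndarray:
    """Background anatomy: gradient, mediastinum, lung fields, rib bands."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    img = 70.0 + 40.0 * (yy / size)
    # bright mediastinal band
    img += 60.0 * np.exp(-(((xx - size / 2.0) / (0.09 * size)) ** 2))
    n_ribs = 9
    for side, (cx, cy, a, b) in lung_geometry(size).items():
        lung = _ellipse_mask(size, cx, cy, a, b)
        img[lung] -= 45.0
        ribs = 12.0 * np.sin(2.0 * np.pi * yy * n_ribs / size
                             + rng.uniform(0, 2 * np.pi))
        img[lung] += ribs[lung]
    img += rng.normal(0.0, 5.0, size=img.shape)
    return img


def _render_lesion(img: np.ndarray, crescent: np.ndarray) -> None:
    """Lucent (darker) pneumothorax band with a bright pleural edge."""
    img[crescent] -= 18.0
    # pleural line: lower fringe of the crescent (boundary with the lung)
    edge = crescent & ~np.roll(crescent, -2, axis=0)
    img[edge] += 55.0


def generate_sample(spec: SyntheticSpec, index: int, *,
                    render_image: bool = True
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """One synthetic radiograph: (uint8 image, binary mask, label).

    Deterministic per (spec.seed, index). The image texture and the
    label/lesion draws use independent child RNG streams, so masks and
    labels are bit-identical whether or not the (slower) image rendering is
    requested (``render_image=False`` returns a blank image). Raises
    RuntimeError when a drawn lesion area cannot be fitted after 100
    attempts.
    """
    size = spec.image_size
    img_stream, rng = (np.random.default_rng(s) for s in
                       np.random.SeedSequence([spec.seed, index]).spawn(2))
    img = (_render_thorax(size, img_stream) if render_image
           else np.zeros((size, size)))
    mask = np.zeros((size, size), dtype=np.uint8)
    label = int(rng.random() < spec.prevalence)
    if label:
        sides = ["right", "left", "both"][
            int(rng.choice(3, p=spec.laterality_probs))]
        sides = ["right", "left"] if sides == "both" else [sides]
        total_px = None
        for attempt in range(_MAX_ATTEMPTS):
            pct = _draw_area_pct(rng, spec)
            total_px = max(1, int(round(pct / 100.0 * size * size)))
            if len(sides) == 1:
                targets = [total_px]
            else:
                w = rng.uniform(0.3, 0.7)
                targets = [max(1, int(round(w * total_px))),
                           max(1, total_px - int(round(w * total_px)))]
            pieces = []
            for side, target in zip(sides, targets):
                outer_scale = rng.uniform(0.9, 1.0)
                piece = _fit_crescent(size, side, target, outer_scale)
                if piece is None:
                    break
                pieces.append(piece)
            if len(pieces) == len(sides):
                for piece in pieces:
                    mask |= piece.astype(np.uint8)
                break
        else:
            raise RuntimeError(
                f"could not fit a lesion of {total_px} px after "
                f"{_MAX_ATTEMPTS} attempts")
        if render_image:
            _render_lesion(img, mask.astype(bool))
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, mask, label


def generate_dataset(spec: SyntheticSpec, n: int, out_dir: str | Path,
                     *, write_images: bool = True) -> list[SampleRecord]:
    """Generate ``n`` samples, write PNGs + a manifest CSV, return records.

    With ``write_images=False`` only the manifest is written (masks are
    fully described by their RLE), which is handy for statistics-only runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    records = []
    for i in range(n):
        image, mask, label = generate_sample(spec, i, render_image=write_images)
        image_id = f"synth_{i:05d}"
        image_path = out_dir / f"{image_id}.png"
        if write_images:
            Image.fromarray(image, mode="L").save(image_path)
        records.append(SampleRecord(
            image_id=image_id, image_path=str(image_path),
            rle=rle_encode(mask), mask_height=spec.image_size,
            mask_width=spec.image_size, label=label))
    write_manifest(records, out_dir / "manifest.csv")
    return records
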