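"""Mask run-length codec, raw-image preprocessing, manifests and splits.

RLE dialect
-----------
The competition-compatible form used by the public pneumothorax benchmark:
the mask is flattened in **column-major** (Fortran) order, runs are written
as space-separated ``start length`` pairs with **1-based absolute** starts,
sorted ascending, and an empty mask is encoded as the sentinel ``"-1"``.
``rle_decode(rle_encode(m)) == m`` for every binary mask, and encoding is
canonical (re-encoding a decoded string reproduces it exactly).

A ``relative_starts=True`` compatibility flag accepts the variant dialect in
which each start (after the first) is an offset from the end of the
previous run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EMPTY_RLE", "rle_encode", "rle_decode", "preprocess_raw_image",
    "stratified_kfold", "stratified_split", "SampleRecord", "read_manifest",
    "write_manifest", "load_image", "load_dicom_pixels", "save_mask_png",
    "MANIFEST_COLUMNS",
]

EMPTY_RLE = "-1"
MANIFEST_COLUMNS = ["image_id", "image_path", "rle", "mask_height",
                    "mask_width", "label", "fold", "split"]


# -- RLE codec -------------------------------------------------------------

def rle_encode(mask) -> str:
    """Encode a binary mask into the canonical run-length string."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary")
    flat = arr.astype(np.uint8).flatten(order="F")
    if not flat.any():
        return EMPTY_RLE
    padded = np.concatenate([[0], flat, [0]])
    changes = np.flatnonzero(np.diff(padded))
    starts = changes[0::2] + 1  # 1-based
    lengths = changes[1::2] - changes[0::2]
    return " ".join(f"{s} {l}" for s, l in zip(starts, lengths))


def rle_decode(rle: str, height: int, width: int, *,
               relative_starts: bool = False) -> np.ndarray:
    """Decode a run-length string into a (height, width) uint8 mask."""
    mask = np.zeros(height * width, dtype=np.uint8)
    rle = (rle or "").strip()
    if rle in ("", EMPTY_RLE):
        return mask.reshape(height, width, order="F")
    try:
        tokens = [int(t) for t in rle.split()]
    except ValueError as exc:
        raise ValueError(f"malformed RLE token in {rle!r}") from exc
    if len(tokens) % 2:
        raise ValueError("RLE must contain an even number of tokens")
    pos = 0
    for start, length in zip(tokens[0::2], tokens[1::2]):
        if relative_starts:
            pos += start
            begin = pos
            pos += length
        else:
            begin = start
        if length < 0 or begin < 1 or begin - 1 + length > mask.size:
            raise ValueError(
                f"run ({start}, {length}) exceeds a {height}x{width} mask")
        mask[begin - 1:begin - 1 + length] = 1
    return mask.reshape(height, width, order="F")


# -- raw image preprocessing ----------------------------------------------

def preprocess_raw_image(raw, out_size: int = 2048) -> np.ndarray:
    """Bicubic-resize a raw intensity grid to ``out_size`` square and
    min-max normalise to 8-bit [0, 255]. A constant image maps to all zeros."""
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D intensity grid")
    if arr.shape != (out_size, out_size):
        arr = _sk_resize(arr, (out_size, out_size), order=3,
                         preserve_range=True, anti_aliasing=False)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.zeros((out_size, out_size), dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale (or RGB, converted) PNG as a 2-D array."""
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            im = im.convert("L")
        return np.asarray(im)


def load_dicom_pixels(path: str | Path) -> np.ndarray:
    """Thin adapter extracting the raw 2-D pixel grid from a DICOM file."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    return np.asarray(ds.pixel_array)


def save_mask_png(mask, path: str | Path) -> None:
    arr = np.asarray(mask).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(str(path))


# -- stratified splitting --------------------------------------------------

def stratified_kfold(labels: Sequence[int], k: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` folds with per-class balance
    (counts per fold differ by at most one within each class)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has fewer than k={k} members")
    folds = np.empty(len(labels), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[idx] = fold
    return folds


def stratified_split(labels: Sequence[int], test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test split preserving class balance.

    Per class, the test set receives round-half-up(count * test_fraction)
    samples; a class that would receive zero test samples triggers a
    warning, not an error.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        if n_test == 0:
            warnings.warn(f"class {cls!r} receives zero test samples",
                          stacklevel=2)
        test_idx.append(rng.permutation(idx)[:n_test])
    test = np.sort(np.concatenate(test_idx)).astype(int)
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


# -- manifest --------------------------------------------------------------

@dataclass
class SampleRecord:
    """One radiograph: image location, RLE-encoded mask, and metadata."""

    image_id: str
    image_path: str
    rle: str = EMPTY_RLE
    mask_height: int = 1024
    mask_width: int = 1024
    label: int = 0
    fold: Optional[int] = None
    split: Optional[str] = None

    def __post_init__(self):
        self.rle = (self.rle or EMPTY_RLE).strip() or EMPTY_RLE
        expected = 0 if self.rle == EMPTY_RLE else 1
        if int(self.label) != expected:
            raise ValueError(
                f"record {self.image_id}: label {self.label} inconsistent "
                f"with rle {'empty' if expected == 0 else 'non-empty'}")
        if self.split is not None and self.split not in ("train", "val", "test"):
            raise ValueError(f"invalid split {self.split!r}")

    def decode_mask(self) -> np.ndarray:
        return rle_decode(self.rle, self.mask_height, self.mask_width)


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({"image_id": r.image_id, "image_path": r.image_path,
                     "rle": r.rle, "mask_height": r.mask_height,
                     "mask_width": r.mask_width, "label": int(r.label),
                     "fold": "" if r.fold is None else int(r.fold),
                     "split": r.split or ""})
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a manifest CSV, enforcing the label/rle consistency invariant.

    Raises a validation error listing offending rows; an empty file returns
    an empty list with a warning.
    """
    try:
        df = pd.read_csv(path, dtype={"rle": str, "image_id": str},
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"manifest {path} is empty", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"manifest {path} has no rows", stacklevel=2)
        return []
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(SampleRecord(
                image_id=str(row.image_id), image_path=str(row.image_path),
                rle=str(row.rle), mask_height=int(row.mask_height),
                mask_width=int(row.mask_width), label=int(row.label),
                fold=None if row.fold == "" else int(float(row.fold)),
                split=(str(row.split) or None) if row.split != "" else None))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("manifest validation failed:\n" + "\n".join(errors))
    return records
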