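"""Training loop, cross-validation, prediction and dataset evaluation.

Training follows the published recipe: Adam at an initial learning rate of
5e-4, reduce-on-plateau decay (factor 0.5, patience 3, floor 1e-6,
monitored on validation loss), batch size 8, up to 50 epochs with
per-epoch shuffling, and "early stopping" implemented as selection of the
checkpoint with the lowest validation loss over the run. Everything —
initialisation, shuffling, augmentation draws — is determined by the
config seed.

Prediction runs the full chain: standardise input -> forward -> pixelwise
sigmoid -> threshold at 0.5 -> the 3,500-activated-pixel detection rule on
the 512x512 mask.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import Augmenter, standardize_input
from .config import TrainConfig
from .data_io import SampleRecord, read_manifest, rle_encode, save_mask_png, load_image
from .losses import mixed_loss, tversky_loss
from .metrics import (DETECTION_MIN_PIXELS, EvalReport, binarize, detect,
                      evaluate_dataset, resize_mask_nearest)
from .model import SegmentationModel, build_model, load_checkpoint, save_checkpoint
from .nn import Adam, ReduceLROnPlateau
from .nn import functional as F
from .nn.tensor import Tensor
from .data_io import stratified_kfold

__all__ = ["train", "cross_validate", "predict", "evaluate",
           "TrainHistory", "EpochRecord"]


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float
    checkpoint: str | None = None


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based index of the epoch with the lowest validation loss."""
        losses = [e.val_loss for e in self.epochs]
        return int(np.argmin(losses)) + 1

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,val_loss,lr"]
        lines += [f"{e.epoch},{e.train_loss:.6f},{e.val_loss:.6f},{e.lr:.2e}"
                  for e in self.epochs]
        Path(path).write_text("\n".join(lines) + "\n")


def _loss_fn(config: TrainConfig):
    base = mixed_loss if config.loss == "mixed" else tversky_loss
    params = config.loss_params
    return lambda probs, truth: base(probs, truth, params)


def _prepare_sample(record: SampleRecord, size: int,
                    augmenter: Augmenter | None,
                    draw_seed: int) -> tuple[np.ndarray, np.ndarray]:
    image = load_image(record.image_path)
    mask = record.decode_mask()
    if mask.shape != image.shape:
        mask = resize_mask_nearest(mask, image.shape[0])
    if augmenter is not None:
        image, mask = augmenter.apply(image, mask, draw_seed)
    x = standardize_input(image, size=size)
    m = resize_mask_nearest(mask, size)
    return x, m


def _batches(n: int, batch_size: int):
    for start in range(0, n, batch_size):
        yield range(start, min(start + batch_size, n))


def _run_epoch(model: SegmentationModel, records: list[SampleRecord],
               config: TrainConfig, loss_fn, optimizer: Adam | None,
               augmenter: Augmenter | None, epoch: int,
               order: np.ndarray) -> float:
    size = config.model.input_size
    losses, weights = [], []
    for batch in _batches(len(order), config.batch_size):
        idxs = order[list(batch)]
        xs, ms = [], []
        for j, idx in enumerate(idxs):
            draw_seed = epoch * 1_000_000 + int(idx)
            x, m = _prepare_sample(records[idx], size, augmenter, draw_seed)
            xs.append(x)
            ms.append(m)
        x = Tensor(np.stack(xs))
        truth = np.stack(ms)[:, None, :, :].astype(np.float64)
        logits = model(x)
        probs = F.sigmoid(logits)
        loss = loss_fn(probs, truth)
        value = loss.item()
        if math.isnan(value) or math.isinf(value):
            raise RuntimeError(
                f"non-finite loss ({value}) at epoch {epoch + 1}; aborting")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(value)
        weights.append(len(idxs))
    return float(np.average(losses, weights=weights))


def train(config: TrainConfig,
          train_records: list[SampleRecord] | None = None,
          val_records: list[SampleRecord] | None = None,
          ) -> tuple[Path | None, TrainHistory]:
    """Train a model; returns (best checkpoint path, per-epoch history).

    Records may be passed directly or read from the manifests named in the
    config. The checkpoint written is the one with the lowest validation
    loss seen so far ("early stopping" as checkpoint selection).
    """
    if train_records is None:
        if not config.train_manifest:
            raise ValueError("no training manifest or records provided")
        train_records = read_manifest(config.train_manifest)
    if not train_records:
        raise ValueError("training manifest is empty")
    if val_records is None:
        val_records = (read_manifest(config.val_manifest)
                       if config.val_manifest else train_records)

    model = build_model(config.model, seed=config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.lr_factor,
                                  patience=config.lr_patience,
                                  min_lr=config.min_lr)
    loss_fn = _loss_fn(config)
    train_aug = Augmenter(config.augment) if config.augment_train else None
    val_aug = Augmenter(config.augment) if config.augment_val else None
    rng = np.random.default_rng(config.seed)
    ckpt_dir = Path(config.checkpoint_dir)
    history = TrainHistory()
    best_val, best_path = np.inf, None
    val_order = np.arange(len(val_records))

    for epoch in range(config.max_epochs):
        order = (rng.permutation(len(train_records))
                 if config.shuffle_each_epoch else np.arange(len(train_records)))
        model.train()
        train_loss = _run_epoch(model, train_records, config, loss_fn,
                                optimizer, train_aug, epoch, order)
        model.eval()
        val_loss = _run_epoch(model, val_records, config, loss_fn, None,
                              val_aug, epoch, val_order)
        record = EpochRecord(epoch=epoch + 1, train_loss=train_loss,
                             val_loss=val_loss, lr=optimizer.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_path = save_checkpoint(model, ckpt_dir / "best.npz")
            record.checkpoint = str(best_path)
        history.epochs.append(record)
        scheduler.step(val_loss)
        print(f"epoch {epoch + 1:3d}  train {train_loss:.4f}  "
              f"val {val_loss:.4f}  lr {optimizer.lr:.2e}")
    return best_path, history


def cross_validate(config: TrainConfig, k: int = 5,
                   records: list[SampleRecord] | None = None
                   ) -> list[TrainHistory]:
    """Stratified k-fold cross-validation returning one history per fold."""
    if records is None:
        records = read_manifest(config.train_manifest)
    labels = [r.label for r in records]
    folds = stratified_kfold(labels, k=k, seed=config.seed)
    histories = []
    base_dir = Path(config.checkpoint_dir)
    for fold in range(k):
        fold_cfg = TrainConfig(**{**config.__dict__,
                                  "checkpoint_dir": str(base_dir / f"fold{fold}")})
        tr = [r for r, f in zip(records, folds) if f != fold]
        va = [r for r, f in zip(records, folds) if f == fold]
        print(f"fold {fold}: {len(tr)} train / {len(va)} val")
        _, hist = train(fold_cfg, train_records=tr, val_records=va)
        histories.append(hist)
    return histories


def predict(model_or_checkpoint, image, *, threshold: float = 0.5,
            min_pixels: int = DETECTION_MIN_PIXELS,
            out_dir: str | Path | None = None
            ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Full inference chain on one radiograph.

    Returns (probability map, binary mask, detection verdict); optionally
    writes the mask PNG, its RLE, and a JSON verdict to ``out_dir``.
    """
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, SegmentationModel)
             else load_checkpoint(model_or_checkpoint))
    model.eval()
    if isinstance(image, (str, Path)):
        image = load_image(image)
    x = standardize_input(image, size=model.config.input_size)
    logits = model(Tensor(x[None]))
    probs = F.sigmoid(logits).data[0, 0]
    mask = binarize(probs, threshold)
    verdict = detect(mask, min_pixels)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mask_png(mask, out_dir / "mask.png")
        (out_dir / "prediction.json").write_text(json.dumps({
            "pneumothorax_detected": bool(verdict),
            "activated_pixels": int(resize_mask_nearest(mask, 512).sum()),
            "rle": rle_encode(mask)}, indent=2))
    return probs, mask, verdict


def evaluate(model_or_checkpoint, manifest: str | Path | list[SampleRecord],
             *, threshold: float = 0.5,
             min_pixels: int = DETECTION_MIN_PIXELS,
             report_path: str | Path | None = None) -> EvalReport:
    """Evaluate a checkpoint against a ground-truth manifest."""
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, SegmentationModel)
             else load_checkpoint(model_or_checkpoint))
    model.eval()
    records = (manifest if isinstance(manifest, list)
               else read_manifest(manifest))
    size = model.config.input_size
    prob_maps, truths = [], []
    t0 = time.perf_counter()
    for record in records:
        image = load_image(record.image_path)
        x = standardize_input(image, size=size)
        logits = model(Tensor(x[None]))
        prob_maps.append(F.sigmoid(logits).data[0, 0])
        truths.append(resize_mask_nearest(record.decode_mask(), size))
    elapsed = time.perf_counter() - t0
    report = evaluate_dataset(prob_maps, truths, threshold=threshold,
                              min_pixels=min_pixels)
    print(f"mean inference latency: {elapsed / max(len(records), 1):.4f} s/image")
    if report_path is not None:
        report.to_json(report_path)
    return report
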