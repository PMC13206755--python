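"""Training loop: AdamW on the combined Dice + cross-entropy loss with
validation-DSC checkpoint selection.

The published recipe: learning rate 1e-3, weight decay 1e-3, batch size 32,
seed 112316, a large epoch cap, and the weights with the highest validation
DSC kept as final.  The loop is deterministic given the seed (all sampling
and augmentation randomness flows from one generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrainConfig
from .dataprep import AugmentationStrategy, augment, zscore_normalize
from .losses import total_loss
from .metrics import mean_foreground_dsc
from .model import SegmentationModel, save_model
from .nn import AdamW, softmax


@dataclass
class SegmentationDataset:
    """In-memory dataset: images (N,H,W,3) in [0,1] + label masks (N,H,W)."""

    images: np.ndarray
    masks: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.masks = np.asarray(self.masks)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be (N,H,W,3)")
        if self.masks.shape != self.images.shape[:3]:
            raise ValueError("masks must be (N,H,W) matching images")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class FitResult:
    best_epoch: int
    best_val_dsc: float
    history: pd.DataFrame
    checkpoint_path: Path | None


def _to_model_batch(images_hwc: np.ndarray) -> np.ndarray:
    """Z-score each image per channel and move channels first."""
    out = np.empty((images_hwc.shape[0], 3) + images_hwc.shape[1:3], dtype=np.float32)
    for i, img in enumerate(images_hwc):
        out[i] = zscore_normalize(img).transpose(2, 0, 1)
    return out


def predict_dataset(model: SegmentationModel, dataset: SegmentationDataset,
                    batch_size: int = 8) -> list[np.ndarray]:
    """Label masks for every image (eval mode, no augmentation)."""
    preds = []
    for lo in range(0, len(dataset), batch_size):
        batch = _to_model_batch(dataset.images[lo:lo + batch_size])
        _, labels = model.predict(batch)
        preds.extend(labels)
    return preds


def validation_dsc(model: SegmentationModel, dataset: SegmentationDataset) -> float:
    preds = predict_dataset(model, dataset)
    return mean_foreground_dsc(preds, list(dataset.masks), model.cfg.num_classes)


def fit(model: SegmentationModel, train_set: SegmentationDataset,
        val_set: SegmentationDataset, config: TrainConfig,
        out_dir: str | Path | None = None) -> FitResult:
    """Train ``model``; keep the weights with the highest validation DSC.

    Writes (when ``out_dir`` is given) a CSV training log and the best
    checkpoint.  Raises on empty datasets and aborts on non-finite loss.
    """
    config.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    strategy = AugmentationStrategy.named(config.augmentation_strategy)
    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    history: list[dict] = []
    best_dsc, best_epoch = -1.0, -1
    checkpoint_path = None
    step = 0
    n = len(train_set)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        ep_dice = ep_ce = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            imgs = train_set.images[idx]
            msks = train_set.masks[idx]
            if strategy.name != "none":
                pairs = [augment(im, mk, strategy, rng) for im, mk in zip(imgs, msks)]
                imgs = np.stack([p[0] for p in pairs])
                msks = np.stack([p[1] for p in pairs])
            x = _to_model_batch(imgs)
            logits = model(x)
            probs = softmax(logits, axis=1)
            loss_val, loss = total_loss(probs, msks.astype(np.int64))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (dice={loss_val.dice}, "
                    f"ce={loss_val.ce}); aborting"
                )
            model.zero_grad()
            loss.backward()
            optimizer.step()
            ep_dice += loss_val.dice
            ep_ce += loss_val.ce
            n_batches += 1
            step += 1
        row = {
            "epoch": epoch, "step": step,
            "train_dice": ep_dice / n_batches, "train_ce": ep_ce / n_batches,
            "train_total": (ep_dice + ep_ce) / n_batches, "val_dsc_mean": np.nan,
        }
        if epoch % config.validation_interval == 0 or epoch == config.max_epochs:
            val = validation_dsc(model, val_set)
            row["val_dsc_mean"] = val
            if val > best_dsc:
                best_dsc, best_epoch = val, epoch
                if out_dir is not None:
                    save_model(model, out_dir, name="best")
                    checkpoint_path = out_dir / "best.npz"
        history.append(row)
        if (config.early_stop_dsc is not None
                and best_dsc >= config.early_stop_dsc):
            break
    hist = pd.DataFrame(history)
    if out_dir is not None:
        hist.to_csv(out_dir / "training_log.csv", index=False)
        if checkpoint_path is None:  # no validation epoch improved: save last
            save_model(model, out_dir, name="best")
            checkpoint_path = out_dir / "best.npz"
    return FitResult(best_epoch=best_epoch, best_val_dsc=best_dsc,
                     history=hist, checkpoint_path=checkpoint_path)
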