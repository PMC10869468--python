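"""Five-fold cross-validation training of the patch segmenter.

Folds are made at the subject level; augmentation is applied to each fold's
training subjects only, after the split, so no augmented copy of a
validation subject ever leaks into training.  Per-fold metrics follow the
epoch-averaged convention: validation loss / IoU / DICE are computed after
every epoch and averaged over the fold's epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .augment import AugmentationParams, augment_dataset
from .model import UNet3DSegmenter, UNetConfig
from .roi import PatchSpec, extract_patch
from .volume_io import LabelMask, Volume

__all__ = ["TrainConfig", "FoldResult", "make_folds", "train_fold", "cross_validate"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters: batch 16, 50 epochs, initial lr 0.001,
    five folds, Adam — overridable per run.

    ``crop_size``/``finetune_full_epochs`` enable random-sub-crop training
    with a final full-patch phase (see
    :class:`pituseg.model.UNet3DSegmenter`); the epoch budget then counts
    crop epochs plus fine-tune epochs."""

    batch_size: int = 16
    epochs: int = 50
    learning_rate: float = 1e-3
    n_folds: int = 5
    seed: int = 0
    optimizer_name: str = "adam"
    crop_size: int | None = None
    finetune_full_epochs: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FoldResult:
    """Epoch-averaged validation metrics for one cross-validation fold."""

    fold_index: int
    averaged_loss: float
    averaged_iou: float
    averaged_dice: float
    model: UNet3DSegmenter | None = None
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "averaged_loss": self.averaged_loss,
            "averaged_iou": self.averaged_iou,
            "averaged_dice": self.averaged_dice,
            "history": self.history,
        }


def make_folds(subject_ids: list, n_folds: int, seed: int) -> list[tuple[list, list]]:
    """Subject-level partition into ``n_folds`` shuffled folds.

    Every subject lands in exactly one validation fold; fold sizes differ
    by at most one; deterministic in ``seed``.
    """
    ids = list(subject_ids)
    if n_folds > len(ids):
        raise ValueError(f"n_folds={n_folds} exceeds number of subjects {len(ids)}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        ([ids[i] for i in tr], [ids[i] for i in va])
        for tr, va in kf.split(np.zeros(len(ids)))
    ]


def _to_patch_arrays(pairs, spec: PatchSpec):
    X = np.stack([extract_patch(v, spec) for v, _ in pairs]).astype(np.float32)
    y = np.stack([extract_patch(m, spec) for _, m in pairs]).astype(np.uint8)
    return X, y


def train_fold(
    train_pairs,
    val_pairs,
    model_config: UNetConfig,
    train_config: TrainConfig,
    fold_index: int = 0,
) -> FoldResult:
    """Train one fold on 32^3 (patch, mask-patch) arrays and average the
    per-epoch validation metrics.

    ``train_pairs``/``val_pairs`` are (X, y) array pairs on the patch grid;
    augmentation, if any, must already be applied to the training side only.
    """
    Xt, yt = train_pairs
    Xv, yv = val_pairs
    if len(Xt) == 0 or len(Xv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    est = UNet3DSegmenter(
        depth=model_config.depth,
        base_filters=model_config.base_filters,
        epochs=train_config.epochs,
        batch_size=train_config.batch_size,
        learning_rate=train_config.learning_rate,
        loss_smooth=model_config.loss_smooth,
        threshold=model_config.threshold,
        crop_size=train_config.crop_size,
        finetune_full_epochs=train_config.finetune_full_epochs,
        random_state=train_config.seed + fold_index,
    )
    est.fit(Xt, yt, validation_data=(Xv, yv))
    hist = est.validation_history_
    return FoldResult(
        fold_index=fold_index,
        averaged_loss=float(np.mean([h["loss"] for h in hist])),
        averaged_iou=float(np.mean([h["iou"] for h in hist])),
        averaged_dice=float(np.mean([h["dice"] for h in hist])),
        model=est,
        history=hist,
    )


def cross_validate(
    dataset: list[tuple[Volume, LabelMask]],
    spec: PatchSpec,
    model_config: UNetConfig | None = None,
    train_config: TrainConfig | None = None,
    augment_params: AugmentationParams | None = None,
) -> tuple[list[FoldResult], UNet3DSegmenter]:
    """Run subject-level k-fold cross-validation and select a checkpoint.

    Returns one :class:`FoldResult` per fold plus the fitted model of the
    fold with the lowest averaged validation loss (ties broken by highest
    averaged DICE).
    """
    model_config = model_config or UNetConfig()
    train_config = train_config or TrainConfig()
    folds = make_folds(list(range(len(dataset))), train_config.n_folds, train_config.seed)
    # augmentation operates on a context patch around the ROI (margin for
    # translations/rotations to pull in real tissue) rather than the whole
    # head volume; the training patch is the central crop afterwards
    ctx_margin = 8
    ctx_spec = PatchSpec(center=spec.center, size=spec.size + 2 * ctx_margin)
    core_spec = PatchSpec(center=(ctx_spec.size // 2,) * 3, size=spec.size)
    results = []
    for k, (train_ids, val_ids) in enumerate(folds):
        train_subset = [dataset[i] for i in train_ids]
        if augment_params is not None:
            ctx_pairs = [
                (
                    Volume(data=extract_patch(v, ctx_spec), spacing=v.spacing),
                    LabelMask(data=extract_patch(m, ctx_spec), spacing=m.spacing),
                )
                for v, m in train_subset
            ]
            train_subset = augment_dataset(ctx_pairs, augment_params)
            Xt, yt = _to_patch_arrays(train_subset, core_spec)
        else:
            Xt, yt = _to_patch_arrays(train_subset, spec)
        Xv, yv = _to_patch_arrays([dataset[i] for i in val_ids], spec)
        results.append(train_fold((Xt, yt), (Xv, yv), model_config, train_config, k))
    best = min(results, key=lambda r: (r.averaged_loss, -r.averaged_dice))
    return results, best.model


def save_fold_results(results: list[FoldResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
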