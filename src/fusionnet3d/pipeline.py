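"""Training, prediction, and evaluation orchestration.

The optimization recipe is plain stochastic gradient descent on the
voxelwise cross-entropy, with an exponentially decaying learning rate
``lr(epoch) = lr0 * decay**epoch`` (defaults: lr0 0.01, decay 0.8 per
epoch, 20 epochs, batch size 5).  Cohorts are split subject-wise into
train/validation/test before any augmentation (augmentation never crosses
the split), the per-epoch validation metric is the mean Dice over the
three tumor subregions, and both the best-validation and final weights
are checkpointed with the architecture config embedded.

Also here: modality-subset selection and the 15-subset sweep harness, and
slice-overlay rendering (NC red, ET yellow, ED green on the grayscale
image).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augmentation import expand_training_set
from .data import (MODALITIES, ModalityStack, Sample, TUMOR_CLASSES,
                   LABEL_NAMES, NC, ED, ET)
from .loss import softmax_cross_entropy_with_grad
from .metrics import subject_metrics, evaluate_cohort, MetricReport, dice, confusion
from .model import (FusionNetConfig, FusionNet, build_fusionnet,
                    save_checkpoint, load_checkpoint)

__all__ = [
    "TrainConfig", "split_cohort", "lr_schedule", "train",
    "select_modalities", "evaluate", "sweep_modalities",
    "all_modality_subsets", "render_overlay", "extract_slice",
]

logger = logging.getLogger("fusionnet3d")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    lr0: float = 0.01
    decay: float = 0.8
    epochs: int = 20
    batch_size: int = 5
    seed: int = 0
    split: tuple[int, int, int] = (500, 31, 80)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def lr_schedule(lr0: float, decay: float, epoch: int) -> float:
    """Exponentially decayed learning rate: ``lr0 * decay**epoch``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * decay ** epoch


def split_cohort(subject_ids, split, seed: int, out_path=None):
    """Seed-deterministic disjoint train/validation/test partition.

    ``split`` gives the subject counts, which must sum to the cohort size.
    The partition can be written to JSON before training starts.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    n_train, n_val, n_test = split
    if n_train + n_val + n_test != len(ids):
        raise ValueError(f"split {split} sums to {n_train + n_val + n_test}, "
                         f"but cohort has {len(ids)} subjects")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    parts = (shuffled[:n_train],
             shuffled[n_train:n_train + n_val],
             shuffled[n_train + n_val:])
    if out_path is not None:
        Path(out_path).write_text(json.dumps(
            {"train": parts[0], "val": parts[1], "test": parts[2],
             "seed": seed}, indent=2))
    return parts


def select_modalities(stack: ModalityStack, subset) -> ModalityStack:
    """Channel subset in canonical (FLAIR, T1, ceT1, T2) order."""
    return stack.select(subset)


def all_modality_subsets() -> list[tuple[str, ...]]:
    """The 15 nonempty modality combinations, largest first."""
    out = []
    for k in range(len(MODALITIES), 0, -1):
        out.extend(itertools.combinations(MODALITIES, k))
    return out


def _batch_arrays(samples: list[Sample]):
    x = np.stack([s.stack.data for s in samples]).astype(np.float32)
    y = np.stack([s.labels.data for s in samples]).astype(np.int64)
    return x, y


def _validation_dice(model: FusionNet, val_samples) -> dict:
    per_class = {c: [] for c in TUMOR_CLASSES}
    for s in val_samples:
        _, pred = model.predict(s.stack)
        for c in TUMOR_CLASSES:
            per_class[c].append(dice(confusion(pred, s.labels, c)))
    out = {}
    for c in TUMOR_CLASSES:
        vals = np.asarray(per_class[c], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[LABEL_NAMES[c]] = float(defined.mean()) if len(defined) else float("nan")
    out["mean"] = float(np.nanmean(list(out.values())))
    return out


def train(model_config: FusionNetConfig, train_config: TrainConfig,
          train_samples, val_samples=(), out_dir=None,
          model: FusionNet | None = None, start_epoch: int = 0,
          log_every: int = 1):
    """Run SGD on the voxelwise cross-entropy.

    Returns ``(model, history)`` where ``history`` is one dict per epoch
    (learning rate, mean train loss, per-subregion validation Dice).  When
    ``out_dir`` is given, best-validation (mean subregion Dice) and final
    checkpoints plus a JSON log are written there.  Passing ``model`` and
    ``start_epoch`` resumes deterministically: the batch order of epoch
    *k* depends only on ``seed`` and *k*.
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("empty training set")
    for s in train_samples:
        if s.stack.data.shape[0] != model_config.in_channels:
            raise ValueError(f"sample {s.subject_id!r} has "
                             f"{s.stack.data.shape[0]} channels; model expects "
                             f"{model_config.in_channels}")
        if s.stack.shape != (model_config.input_edge,) * 3:
            raise ValueError(f"sample {s.subject_id!r} grid {s.stack.shape} "
                             f"!= model edge {model_config.input_edge}")
    if model is None:
        model = build_fusionnet(model_config, seed=train_config.seed)
        logger.info("initialized %d parameters (He-normal, seed %d)",
                    model.num_parameters(), train_config.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    history: list[dict] = []
    best_dice = -np.inf
    bs = train_config.batch_size
    for epoch in range(start_epoch, train_config.epochs):
        lr = lr_schedule(train_config.lr0, train_config.decay, epoch)
        order = np.random.default_rng(train_config.seed + epoch).permutation(
            len(train_samples))
        losses = []
        for i in range(0, len(order), bs):
            batch = [train_samples[j] for j in order[i:i + bs]]
            x, y = _batch_arrays(batch)
            logits = model.forward_logits(x, train=True)
            loss, grad = softmax_cross_entropy_with_grad(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss {loss} at epoch {epoch}, "
                                   f"batch {i // bs}; aborting")
            model.backward(grad)
            nn.sgd_step(model.params(), lr)
            losses.append(loss)
        entry = {"epoch": epoch, "lr": lr,
                 "train_loss": float(np.mean(losses))}
        if val_samples:
            vd = _validation_dice(model, val_samples)
            entry.update({f"val_dice_{k}": v for k, v in vd.items()})
            if vd["mean"] > best_dice:
                best_dice = vd["mean"]
                entry["best"] = True
                if out_dir is not None:
                    save_checkpoint(model, out_dir / "best.npz",
                                    extra={"epoch": epoch,
                                           "val_dice_mean": vd["mean"]})
        history.append(entry)
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d lr %.5f loss %.4f %s", epoch, lr,
                        entry["train_loss"],
                        f"val_dice {entry.get('val_dice_mean', float('nan')):.3f}"
                        if val_samples else "")
    if out_dir is not None:
        save_checkpoint(model, out_dir / "final.npz",
                        extra={"epoch": train_config.epochs - 1,
                               "train_config": asdict(train_config)})
        (out_dir / "history.json").write_text(json.dumps(history, indent=2))
    return model, history


def evaluate(model: FusionNet, samples, whole_tumor: bool = False) -> MetricReport:
    """Predict every sample and aggregate the six metrics over the cohort."""
    reports = []
    for s in samples:
        _, pred = model.predict(s.stack)
        reports.append(subject_metrics(pred, s.labels, s.labels.spacing,
                                       whole_tumor=whole_tumor))
    return evaluate_cohort(reports)


def run_experiment(cohort, model_config: FusionNetConfig,
                   train_config: TrainConfig, out_dir=None, augment=True,
                   whole_tumor: bool = True):
    """Split -> (augment train only) -> train -> evaluate on the test split.

    The end-to-end desk-scale path: returns ``(model, history, report)``.
    """
    ids = [s.subject_id for s in cohort]
    by_id = {s.subject_id: s for s in cohort}
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    tr, va, te = split_cohort(
        ids, train_config.split, train_config.seed,
        out_path=None if out_dir is None else Path(out_dir) / "split.json")
    train_set = [by_id[i] for i in tr]
    if augment:
        train_set = expand_training_set(train_set)
    model, history = train(model_config, train_config, train_set,
                           val_samples=[by_id[i] for i in va],
                           out_dir=out_dir)
    report = evaluate(model, [by_id[i] for i in te], whole_tumor=whole_tumor)
    return model, history, report


def sweep_modalities(cohort, model_config: FusionNetConfig,
                     train_config: TrainConfig, subsets=None,
                     out_csv=None) -> pd.DataFrame:
    """Train one model per modality subset and tabulate test metrics.

    Produces one row per (subset, subregion) with the six metrics as
    mean±sd plus machine-readable columns — the shape of a
    modality-combination results table (15 subsets x 3 subregions).
    """
    subsets = [tuple(s) for s in (subsets or all_modality_subsets())]
    frames = []
    for subset in subsets:
        sub_cohort = [s.with_(stack=select_modalities(s.stack, subset))
                      for s in cohort]
        cfg_kw = {**asdict(model_config), "in_channels": len(subset)}
        _, _, report = run_experiment(sub_cohort, FusionNetConfig(**cfg_kw),
                                      train_config, whole_tumor=False)
        frame = report.to_csv(None, method="/".join(subset))
        frames.append(frame.rename(columns={"method": "modalities"}))
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


# --------------------------------------------------------------------- #
# overlay rendering
# --------------------------------------------------------------------- #
_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}

#: overlay colors: necrotic core red, enhancing tumor yellow, edema green
OVERLAY_COLORS = {NC: (1.0, 0.0, 0.0), ET: (1.0, 1.0, 0.0), ED: (0.0, 1.0, 0.0)}


def extract_slice(volume: np.ndarray, plane: str, index: int) -> np.ndarray:
    """2D slice of a 3D volume along an anatomical plane."""
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}")
    axis = _PLANE_AXIS[plane]
    if not (0 <= index < volume.shape[axis]):
        raise IndexError(f"slice index {index} out of range "
                         f"[0, {volume.shape[axis]}) for {plane} plane")
    return np.take(volume, index, axis=axis)


def render_overlay(volume: np.ndarray, labels: np.ndarray, plane: str,
                   index: int, path=None, alpha: float = 0.45) -> np.ndarray:
    """Grayscale slice with label overlays (NC red, ET yellow, ED green).

    Returns the RGB array (H, W, 3) in [0, 1]; writes a PNG if ``path``
    is given.
    """
    img = extract_slice(np.asarray(volume, dtype=np.float64), plane, index)
    lab = extract_slice(np.asarray(labels), plane, index)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    for class_id, color in OVERLAY_COLORS.items():
        m = lab == class_id
        rgb[m] = (1 - alpha) * rgb[m] + alpha * np.asarray(color)
    rgb = np.clip(rgb, 0.0, 1.0)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        plt.imsave(path, np.rot90(rgb))
    return rgb
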