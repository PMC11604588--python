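"""Voxelwise multi-class cross-entropy.

Every voxel is treated as an independent classification task; the loss is
the negative log-likelihood of the true class, averaged over all voxels of
the volume:

    L = -(1 / (H*W*D)) * sum_{h,w,d} sum_c  y[h,w,d,c] * log(yhat[h,w,d,c])

with one-hot ground truth ``y`` and predicted class probabilities ``yhat``.
Predicted probabilities are clamped below at 1e-12 before the log so a
degenerate zero probability yields a large finite loss rather than inf.
The loss is unweighted: class imbalance is addressed through the data, not
through per-class weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cross_entropy", "one_hot", "softmax_cross_entropy_with_grad"]

PROB_FLOOR = 1e-12
_PROB_TOL = 1e-5


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """One-hot encode an integer label volume along a trailing class axis."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes})")
    return np.eye(num_classes, dtype=np.float64)[labels]


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean voxelwise cross-entropy.

    Parameters
    ----------
    y_true : one-hot array, class axis last; entries in {0, 1} summing to 1
        per voxel.
    y_pred : predicted probabilities, same shape.

    Returns
    -------
    float — nonnegative, finite.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: y_true {y_true.shape} vs "
                         f"y_pred {y_pred.shape}")
    if y_pred.min() < -_PROB_TOL or y_pred.max() > 1 + _PROB_TOL:
        raise ValueError("predicted probabilities outside [0, 1]")
    onehot_sums = y_true.sum(axis=-1)
    if not np.allclose(onehot_sums, 1.0) or not np.isin(y_true, (0.0, 1.0)).all():
        raise ValueError("y_true must be one-hot over the last axis")
    n_voxels = y_true.size // y_true.shape[-1]
    logp = np.log(np.clip(y_pred, PROB_FLOOR, None))
    return float(-(y_true * logp).sum() / n_voxels)


def softmax_cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray):
    """Training-path fused op: mean cross-entropy over a batch of volumes
    plus its gradient with respect to the logits.

    ``logits`` is (N, C, D, H, W); ``labels`` is (N, D, H, W) integer.  The
    loss is averaged over all voxels of all batch items, matching the
    per-volume average of :func:`cross_entropy`.
    """
    logits = np.asarray(logits)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n, c = logits.shape[:2]
    n_vox = labels.size  # N * D * H * W
    p_true = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.clip(p_true, PROB_FLOOR, None)).sum() / n_vox)
    onehot = (labels[:, None] == np.arange(c)[None, :, None, None, None])
    grad = (probs - onehot).astype(logits.dtype, copy=False)
    grad /= n_vox
    return loss, grad
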