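"""Zero-padding to the cubic network input and the five-transform
augmentation scheme.

Native volumes (e.g. 240x240x155) are zero-padded to a cube — intensities
padded with zeros, labels with background, content centered with the extra
voxel on the high side for odd margins — so that 240x240x155 becomes
256x256x256 with margins (8,8), (8,8), (50,51).

Augmentation applies five pure index permutations jointly to every
modality channel and the label map: horizontal flip, vertical flip, and
90/180/270-degree rotations.  "Horizontal" and "vertical" act on the two
in-plane (axial) axes of the canonical volume; the slice axis is never
touched, and labels are permuted, never interpolated.  Expanding a set of
originals with all five transforms multiplies the sample count by six
(e.g. 500 originals -> 3000 training samples).

Expansion is materialized eagerly by default (fixed training-set size);
:func:`iter_expanded` is the streaming alternative.
"""

from __future__ import annotations

import numpy as np

from .data import Sample, ModalityStack, SegmentationMap, BACKGROUND

__all__ = ["TRANSFORMS", "pad_to_cube", "crop_to_original",
           "apply_transform", "expand_training_set", "iter_expanded"]

#: the five non-identity transforms
TRANSFORMS = ("hflip", "vflip", "rot90", "rot180", "rot270")

#: in-plane (axial) spatial axes the flips/rotations act on
_PLANE = (0, 1)


def _margins(shape, target_edge):
    out = []
    for axis, size in enumerate(shape):
        if size > target_edge:
            raise ValueError(f"axis {axis} has length {size} > target edge "
                             f"{target_edge}; cannot pad")
        lo = (target_edge - size) // 2
        out.append((lo, target_edge - size - lo))  # extra voxel on high side
    return tuple(out)


def pad_volume(vol: np.ndarray, target_edge: int, value=0) -> np.ndarray:
    """Pad the trailing three axes of ``vol`` to a centered cube."""
    spatial = vol.shape[-3:]
    margins = _margins(spatial, target_edge)
    pad = ((0, 0),) * (vol.ndim - 3) + margins
    return np.pad(vol, pad, constant_values=value)


def pad_to_cube(sample: Sample, target_edge: int) -> Sample:
    """Zero-pad intensities and background-pad labels to a cube; the
    applied margins are recorded in ``meta["pad_margins"]`` so the original
    content can be recovered bitwise."""
    margins = _margins(sample.stack.shape, target_edge)
    stack = ModalityStack(pad_volume(sample.stack.data, target_edge, 0.0),
                          sample.stack.modalities, sample.stack.spacing)
    labels = SegmentationMap(pad_volume(sample.labels.data, target_edge,
                                        BACKGROUND),
                             sample.labels.spacing)
    meta = dict(sample.meta)
    meta["pad_margins"] = margins
    return sample.with_(stack=stack, labels=labels, meta=meta)


def crop_to_original(sample: Sample) -> Sample:
    """Invert :func:`pad_to_cube` using the recorded margins."""
    margins = sample.meta.get("pad_margins")
    if margins is None:
        raise ValueError("sample has no recorded pad margins")
    sl = tuple(slice(lo, size - hi) for (lo, hi), size
               in zip(margins, sample.stack.shape))
    meta = {k: v for k, v in sample.meta.items() if k != "pad_margins"}
    stack = ModalityStack(sample.stack.data[(slice(None),) + sl],
                          sample.stack.modalities, sample.stack.spacing)
    labels = SegmentationMap(sample.labels.data[sl], sample.labels.spacing)
    return sample.with_(stack=stack, labels=labels, meta=meta)


def _transform_volume(vol: np.ndarray, tag: str) -> np.ndarray:
    """Apply one named transform to the trailing three axes."""
    off = vol.ndim - 3
    ax0, ax1 = _PLANE[0] + off, _PLANE[1] + off
    if tag == "hflip":
        return np.flip(vol, axis=ax0)
    if tag == "vflip":
        return np.flip(vol, axis=ax1)
    if tag in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[tag]
        if k % 2 == 1 and vol.shape[ax0] != vol.shape[ax1]:
            raise ValueError(f"{tag} requires a square in-plane shape; got "
                             f"{vol.shape[ax0]}x{vol.shape[ax1]}")
        return np.rot90(vol, k=k, axes=(ax0, ax1))
    raise ValueError(f"unknown transform {tag!r}; valid: {TRANSFORMS}")


def apply_transform(sample: Sample, tag: str) -> Sample:
    """Apply one of the five transforms jointly to stack and labels."""
    stack_data = np.ascontiguousarray(_transform_volume(sample.stack.data, tag))
    label_data = np.ascontiguousarray(_transform_volume(sample.labels.data, tag))
    return sample.with_(
        stack=ModalityStack(stack_data, sample.stack.modalities,
                            sample.stack.spacing),
        labels=SegmentationMap(label_data, sample.labels.spacing),
        transform_tag=tag,
    )


def iter_expanded(samples):
    """Yield each original followed by its five transforms (streaming mode)."""
    for s in samples:
        if s.transform_tag != "original":
            raise ValueError(f"sample {s.subject_id!r} is already transformed "
                             f"({s.transform_tag})")
        yield s
        for tag in TRANSFORMS:
            yield apply_transform(s, tag)


def expand_training_set(samples) -> list[Sample]:
    """Materialize the 6x augmented training set (originals + 5 transforms).

    Raises on duplicate (subject_id, transform_tag) pairs.
    """
    out = list(iter_expanded(samples))
    keys = {(s.subject_id, s.transform_tag) for s in out}
    if len(keys) != len(out):
        raise ValueError("duplicate subject_id + transform_tag pairs in "
                         "expanded training set")
    return out
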