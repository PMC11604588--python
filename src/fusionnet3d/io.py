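"""NIfTI input/output for samples.

A subject is stored as one 4D NIfTI (X, Y, Z, channel) intensity stack,
one 3D integer label NIfTI, and a sidecar JSON with provenance (subject
id, transform tag, modalities, seed, pad margins).  Voxel spacing is
carried in the NIfTI affine (diagonal, RAS-aligned).  Label maps using
BraTS-style {0,1,2,4} codes are remapped to contiguous {0,1,2,3} at load
time; ``save_sample(..., brats_labels=True)`` restores them on save.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .data import (ModalityStack, SegmentationMap, Sample,
                   remap_brats_labels, restore_brats_labels)

__all__ = ["save_sample", "load_sample"]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_sample(sample: Sample, directory, brats_labels: bool = False) -> Path:
    """Write ``<id>_stack.nii``, ``<id>_labels.nii`` and ``<id>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = f"{sample.subject_id}_{sample.transform_tag}"
    aff = _affine(sample.stack.spacing)
    stack_img = nib.Nifti1Image(
        np.moveaxis(sample.stack.data, 0, -1).astype(np.float32), aff)
    nib.save(stack_img, directory / f"{base}_stack.nii")
    labels = sample.labels.data.astype(np.int16)
    if brats_labels:
        labels = restore_brats_labels(labels)
    nib.save(nib.Nifti1Image(labels, aff), directory / f"{base}_labels.nii")
    sidecar = {
        "subject_id": sample.subject_id,
        "transform_tag": sample.transform_tag,
        "modalities": list(sample.stack.modalities),
        "spacing": list(sample.stack.spacing),
        "brats_labels": brats_labels,
        "meta": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in sample.meta.items()},
    }
    (directory / f"{base}.json").write_text(json.dumps(sidecar, indent=2))
    return directory / base


def load_sample(base_path) -> Sample:
    """Load a sample written by :func:`save_sample`; ``base_path`` is the
    path prefix without the ``_stack.nii`` suffix."""
    base = Path(base_path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    stack_img = nib.load(f"{base}_stack.nii")
    labels_img = nib.load(f"{base}_labels.nii")
    spacing = tuple(sidecar["spacing"])
    data = np.moveaxis(np.asarray(stack_img.dataobj, dtype=np.float32), -1, 0)
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    if sidecar.get("brats_labels"):
        labels = remap_brats_labels(labels)
    meta = {k: (tuple(map(tuple, v)) if k == "pad_margins" else v)
            for k, v in sidecar.get("meta", {}).items()}
    if "radii" in meta and isinstance(meta["radii"], list):
        meta["radii"] = tuple(meta["radii"])
    return Sample(
        stack=ModalityStack(data, tuple(sidecar["modalities"]), spacing),
        labels=SegmentationMap(labels, spacing),
        subject_id=sidecar["subject_id"],
        transform_tag=sidecar["transform_tag"],
        meta=meta,
    )
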