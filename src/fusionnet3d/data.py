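"""Core containers: multimodal intensity stacks, label maps, samples.

Label convention: contiguous integer codes 0=background, 1=necrotic core
(NC), 2=peritumoral edema (ED), 3=enhancing tumor (ET).  BraTS-style label
maps, which code ET as 4, are remapped to this contiguous scheme at load
time and back at save time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: canonical modality order — every channel subset is emitted in this order
MODALITIES = ("FLAIR", "T1", "ceT1", "T2")

LABEL_NAMES = ("background", "NC", "ED", "ET")
BACKGROUND, NC, ED, ET = 0, 1, 2, 3
TUMOR_CLASSES = (NC, ED, ET)

#: BraTS encodes {0, 1, 2, 4}; 4 (enhancing tumor) maps to contiguous 3
BRATS_TO_CONTIGUOUS = {0: 0, 1: 1, 2: 2, 4: 3}
CONTIGUOUS_TO_BRATS = {v: k for k, v in BRATS_TO_CONTIGUOUS.items()}


def remap_brats_labels(labels: np.ndarray) -> np.ndarray:
    """Map BraTS-style {0,1,2,4} codes to contiguous {0,1,2,3}."""
    out = labels.copy()
    out[labels == 4] = 3
    bad = ~np.isin(labels, list(BRATS_TO_CONTIGUOUS))
    if bad.any():
        raise ValueError(f"unknown label values {np.unique(labels[bad])}")
    return out


def restore_brats_labels(labels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`remap_brats_labels`."""
    out = labels.copy()
    out[labels == 3] = 4
    return out


@dataclass
class ModalityStack:
    """Co-registered 3D intensity volumes, one channel per MRI modality.

    ``data`` has shape ``(C, X, Y, Z)``; ``modalities`` names the channels in
    canonical order; ``spacing`` is the voxel size in mm per spatial axis.
    """

    data: np.ndarray
    modalities: tuple[str, ...]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.modalities = tuple(self.modalities)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be (C, X, Y, Z); got {self.data.shape}")
        if self.data.shape[0] != len(self.modalities):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.modalities)} modality names")
        unknown = [m for m in self.modalities if m not in MODALITIES]
        if unknown:
            raise ValueError(f"unknown modalities {unknown}; valid: {list(MODALITIES)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def select(self, subset) -> "ModalityStack":
        """Return the channel subset, reordered canonically (FLAIR, T1, ceT1, T2)."""
        subset = set(subset)
        unknown = subset - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}; "
                             f"valid names: {list(MODALITIES)}")
        missing = subset - set(self.modalities)
        if missing:
            raise ValueError(f"modalities {sorted(missing)} not present in stack")
        keep = [m for m in MODALITIES if m in subset]
        idx = [self.modalities.index(m) for m in keep]
        return ModalityStack(self.data[idx], tuple(keep), self.spacing)


@dataclass
class SegmentationMap:
    """Integer label volume on the same grid as its stack."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be an integer array")
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D; got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.data == class_id


TRANSFORM_TAGS = ("original", "hflip", "vflip", "rot90", "rot180", "rot270")


@dataclass
class Sample:
    """One subject: intensity stack + label map + provenance."""

    stack: ModalityStack
    labels: SegmentationMap
    subject_id: str
    transform_tag: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValueError(f"transform_tag {self.transform_tag!r} not one of "
                             f"{TRANSFORM_TAGS}")
        if self.stack.shape != self.labels.shape:
            raise ValueError(f"stack grid {self.stack.shape} != "
                             f"label grid {self.labels.shape}")

    def with_(self, **kw) -> "Sample":
        return replace(self, **kw)
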