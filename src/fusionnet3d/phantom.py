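"""Synthetic multimodal glioma phantoms.

Each phantom is three nested ellipsoidal shells around a jittered center —
necrotic core (NC) innermost, enhancing tumor (ET) around it, peritumoral
edema (ED) outermost — embedded in a uniform "brain" background.  Each
modality channel assigns a mean intensity per region from an intensity
table that reproduces the qualitative contrast of the four MRI sequences:
FLAIR and T2 are brightest in edema, contrast-enhanced T1 (ceT1) is
brightest in the enhancing rim with a dark necrotic core, and plain T1 has
low tumor contrast.  Piecewise-constant intensities are optionally blurred
(Gaussian, mimicking diffuse subregion borders) and corrupted with additive
Gaussian noise.

Intensities live on an arbitrary 0–1 scale; there is no scanner-physics
simulation — the generator targets the statistical structure a
segmentation network needs (nested geometry, modality-specific contrast,
noise), not radiological realism.  Ellipsoid axis ratios are drawn from
[0.7, 1.3] so flips and rotations of a phantom are genuinely distinct
volumes.  Generation is bitwise reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import (MODALITIES, ModalityStack, SegmentationMap, Sample,
                   BACKGROUND, NC, ED, ET)

__all__ = ["PhantomSpec", "default_intensity_table", "default_radii",
           "generate", "generate_cohort", "REGIONS"]

REGIONS = ("brain", "ED", "ET", "NC")

_LABEL_TO_REGION = {BACKGROUND: "brain", NC: "NC", ED: "ED", ET: "ET"}

#: mean intensity per modality and region (arbitrary 0–1 scale)
_DEFAULT_TABLE = {
    #         brain   ED    ET    NC
    "FLAIR": {"brain": 0.30, "ED": 0.85, "ET": 0.55, "NC": 0.40},
    "T1":    {"brain": 0.50, "ED": 0.45, "ET": 0.55, "NC": 0.45},
    "ceT1":  {"brain": 0.35, "ED": 0.40, "ET": 0.90, "NC": 0.15},
    "T2":    {"brain": 0.35, "ED": 0.90, "ET": 0.55, "NC": 0.60},
}


def default_intensity_table() -> dict:
    """Fixed table realizing the qualitative modality contrasts: edema
    bright on FLAIR/T2, enhancing rim bright and necrotic core dark on
    ceT1, low tumor contrast on plain T1."""
    return {m: dict(r) for m, r in _DEFAULT_TABLE.items()}


def default_radii(edge: int) -> tuple[float, float, float]:
    """(r_ED, r_ET, r_NC) scaled to the volume edge: 20/12/6 voxels at
    edge 64."""
    return (0.3125 * edge, 0.1875 * edge, 0.09375 * edge)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``radii`` are the nominal shell radii (r_ED > r_ET > r_NC, voxels);
    per-axis semi-axes are ``r * ratio`` with ratios drawn once per subject
    from [0.7, 1.3].  ``center_jitter`` displaces the tumor center uniformly
    per axis.  ``noise_sd`` and ``smoothing_sd`` control additive Gaussian
    noise and Gaussian pre-blur of the piecewise-constant intensities.
    """

    edge: int = 64
    modalities: tuple[str, ...] = MODALITIES
    radii: tuple[float, float, float] | None = None
    center_jitter: float = 4.0
    intensity_table: dict = field(default_factory=default_intensity_table)
    noise_sd: float = 0.05
    smoothing_sd: float = 1.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.radii is None:
            self.radii = default_radii(self.edge)
        r_ed, r_et, r_nc = self.radii
        if not (r_ed > r_et > r_nc > 0):
            raise ValueError(f"radii must satisfy r_ED > r_ET > r_NC > 0; "
                             f"got {self.radii}")
        if r_ed >= self.edge / 2:
            raise ValueError(f"outer radius {r_ed} must be < edge/2 = "
                             f"{self.edge / 2}")
        if self.noise_sd < 0 or self.smoothing_sd < 0:
            raise ValueError("noise_sd and smoothing_sd must be >= 0")
        self.modalities = tuple(self.modalities)
        unknown = [m for m in self.modalities if m not in MODALITIES]
        if unknown:
            raise ValueError(f"unknown modalities {unknown}")
        for m in self.modalities:
            row = self.intensity_table.get(m, {})
            missing = [r for r in REGIONS if r not in row]
            if missing:
                raise ValueError(f"intensity table for {m} missing regions "
                                 f"{missing}")


def _labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    e = spec.edge
    center = e / 2.0 + rng.uniform(-spec.center_jitter, spec.center_jitter,
                                   size=3)
    ratios = rng.uniform(0.7, 1.3, size=3)
    grid = np.indices((e, e, e), dtype=np.float64) + 0.5
    # normalized ellipsoidal radius shared by all three shells -> nesting
    rho = np.sqrt(sum(((grid[i] - center[i]) / ratios[i]) ** 2
                      for i in range(3)))
    r_ed, r_et, r_nc = spec.radii
    labels = np.full((e, e, e), BACKGROUND, dtype=np.int16)
    labels[rho <= r_ed] = ED
    labels[rho <= r_et] = ET
    labels[rho <= r_nc] = NC
    return labels


def generate(spec: PhantomSpec) -> Sample:
    """Generate one phantom subject (bitwise deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    channels = []
    for m in spec.modalities:
        row = spec.intensity_table[m]
        lut = np.array([row[_LABEL_TO_REGION[l]] for l in range(4)],
                       dtype=np.float64)
        vol = lut[labels]
        if spec.smoothing_sd > 0:
            vol = ndimage.gaussian_filter(vol, spec.smoothing_sd)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
        channels.append(vol.astype(np.float32))
    stack = ModalityStack(np.stack(channels), spec.modalities, spec.spacing)
    return Sample(stack=stack,
                  labels=SegmentationMap(labels, spec.spacing),
                  subject_id=f"phantom-{spec.seed}",
                  meta={"seed": spec.seed, "radii": tuple(spec.radii)})


def generate_cohort(n: int, master_seed: int = 0, **spec_kwargs) -> list[Sample]:
    """n independent phantoms; per-subject seeds derive deterministically
    from ``master_seed`` via numpy's SeedSequence spawning."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    cohort = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = PhantomSpec(seed=seed, **spec_kwargs)
        sample = generate(spec)
        cohort.append(sample.with_(subject_id=f"phantom-{i:03d}"))
    return cohort
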