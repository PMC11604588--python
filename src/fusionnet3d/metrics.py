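"""Six-metric segmentation evaluation: recall, precision, Dice, LFPR, AVD, ASSD.

Each tumor subregion (necrotic core NC, peritumoral edema ED, enhancing
tumor ET) is evaluated one-vs-rest per subject from voxel confusion counts

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    Dice      = 2 TP / (TP + FN + TP + FP)
    LFPR      = FP / (FP + TN)        (lesion false positive rate)

plus two difference-based measures:

    AVD  = (1/N) sum_i |V_pred,i - V_true,i| / V_true,i
    ASSD = 1/2 ( mean_{p in P} d(p, G) + mean_{g in G} d(g, P) )

where P, G are the surfaces (6-connectivity boundary voxels, coordinates in
physical units) of prediction and truth, and d(., S) is the Euclidean
distance to the nearest point of S.

Undefined-value conventions (how degenerate cases are reported): a metric
whose denominator is empty is *undefined* and propagated as NaN, then
excluded from cohort means; an empty prediction against nonempty truth
scores 0 for recall/precision/Dice and NaN for ASSD.  Cohort aggregation is
mean +/- population standard deviation over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .data import SegmentationMap, TUMOR_CLASSES, LABEL_NAMES

__all__ = [
    "ConfusionCounts", "VolumePair", "SurfacePointSet",
    "confusion", "recall", "precision", "dice", "lfpr",
    "avd", "surface", "assd", "subject_metrics",
    "evaluate_cohort", "MetricReport", "METRIC_NAMES",
]

METRIC_NAMES = ("recall", "precision", "dice", "lfpr", "avd", "assd")

#: 6-connectivity structuring element (face neighbors only)
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class voxel counts for one subject."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class VolumePair:
    """Predicted and ground-truth region volumes (same units)."""

    v_pred: float
    v_true: float

    def __post_init__(self):
        if self.v_pred < 0 or self.v_true < 0:
            raise ValueError("volumes must be nonnegative")


@dataclass
class SurfacePointSet:
    """Boundary-voxel coordinates of a binary mask, in physical units."""

    points: np.ndarray  # (n, 3)

    @property
    def empty(self) -> bool:
        return len(self.points) == 0


def _as_labels(x) -> np.ndarray:
    return x.data if isinstance(x, SegmentationMap) else np.asarray(x)


def confusion(pred, truth, class_id: int) -> ConfusionCounts:
    """One-vs-rest voxel confusion counts for ``class_id``."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: prediction {p.shape} vs truth {t.shape}")
    pm, tm = p == class_id, t == class_id
    tp = int(np.count_nonzero(pm & tm))
    fp = int(np.count_nonzero(pm & ~tm))
    fn = int(np.count_nonzero(~pm & tm))
    tn = pm.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def recall(cc: ConfusionCounts) -> float:
    """TP/(TP+FN); undefined (NaN) when the class is absent from the truth."""
    denom = cc.tp + cc.fn
    return cc.tp / denom if denom else float("nan")


def precision(cc: ConfusionCounts) -> float:
    """TP/(TP+FP); an empty prediction scores 0."""
    denom = cc.tp + cc.fp
    return cc.tp / denom if denom else 0.0


def dice(cc: ConfusionCounts) -> float:
    """2TP/(2TP+FP+FN); undefined when both masks are empty."""
    denom = 2 * cc.tp + cc.fp + cc.fn
    return 2 * cc.tp / denom if denom else float("nan")


def lfpr(cc: ConfusionCounts) -> float:
    """FP/(FP+TN); undefined when the truth covers the whole volume."""
    denom = cc.fp + cc.tn
    return cc.fp / denom if denom else float("nan")


def avd(pairs) -> float:
    """Average relative volume difference over regions with nonzero truth.

    Pairs whose true volume is zero are excluded; if nothing remains the
    result is undefined (NaN).
    """
    kept = [p if isinstance(p, VolumePair) else VolumePair(*p) for p in pairs]
    kept = [p for p in kept if p.v_true > 0]
    if not kept:
        return float("nan")
    return float(np.mean([abs(p.v_pred - p.v_true) / p.v_true for p in kept]))


def surface(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> SurfacePointSet:
    """Boundary voxels of a binary mask: mask voxels with at least one of
    their 6 face neighbors outside the mask (the volume border counts as
    outside).  Coordinates are voxel centers scaled by ``spacing``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SurfacePointSet(points=np.empty((0, 3)))
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT,
                                      border_value=0)
    pts = np.argwhere(mask & ~interior).astype(np.float64)
    return SurfacePointSet(points=pts * np.asarray(spacing, dtype=np.float64))


def assd(pred_mask, true_mask, spacing=(1.0, 1.0, 1.0),
         method: str = "kdtree") -> float:
    """Average symmetric surface distance between two masks.

    Undefined (NaN) if either mask is empty.  ``method="brute"`` uses an
    all-pairs distance computation (the independent cross-check path).
    """
    pred_mask, true_mask = np.asarray(pred_mask), np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"grid mismatch: {pred_mask.shape} vs {true_mask.shape}")
    P = surface(pred_mask, spacing)
    G = surface(true_mask, spacing)
    if P.empty or G.empty:
        return float("nan")
    if method == "kdtree":
        d_pg = cKDTree(G.points).query(P.points)[0]
        d_gp = cKDTree(P.points).query(G.points)[0]
    elif method == "brute":
        diff = P.points[:, None, :] - G.points[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(-1))
        d_pg, d_gp = dmat.min(axis=1), dmat.min(axis=0)
    else:
        raise ValueError("method must be 'kdtree' or 'brute'")
    return float(0.5 * (d_pg.mean() + d_gp.mean()))


def _one_region(pm: np.ndarray, tm: np.ndarray, spacing) -> dict:
    cc = confusion(pm, tm, True)
    v_pred, v_true = cc.tp + cc.fp, cc.tp + cc.fn
    rvd = abs(v_pred - v_true) / v_true if v_true > 0 else float("nan")
    return {
        "recall": recall(cc),
        "precision": precision(cc),
        "dice": dice(cc),
        "lfpr": lfpr(cc),
        "avd": rvd,
        "assd": assd(pm, tm, spacing),
    }


def subject_metrics(pred, truth, spacing=(1.0, 1.0, 1.0),
                    classes=TUMOR_CLASSES, whole_tumor: bool = False) -> dict:
    """All six metrics for one subject, per tumor subregion.

    The AVD entry is this subject's relative volume difference
    ``|V_pred - V_true| / V_true`` (NaN when the true volume is zero); the
    cohort AVD of the tables is the mean of these over subjects.  With
    ``whole_tumor=True`` an extra ``"WT"`` entry evaluates the union of the
    three subregions as one binary region.
    """
    p, t = _as_labels(pred), _as_labels(truth)
    if isinstance(truth, SegmentationMap):
        spacing = truth.spacing
    out = {c: _one_region(p == c, t == c, spacing) for c in classes}
    if whole_tumor:
        out["WT"] = _one_region(p > 0, t > 0, spacing)
    return out


@dataclass
class MetricReport:
    """Cohort evaluation: per-subject values plus mean +/- SD aggregation.

    ``per_subject`` is long-form (subject, subregion, metric, value);
    ``summary`` is indexed by subregion with ``<metric>_mean``,
    ``<metric>_sd`` and ``<metric>_excluded`` columns.  Undefined values
    are NaN and excluded from the aggregates; the SD is the population
    (divide-by-n) formula.
    """

    per_subject: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path, method: str = "FusionNet") -> pd.DataFrame:
        """One row per (method, subregion): human-readable ``mean±sd`` per
        metric plus machine-readable mean and sd columns."""
        rows = []
        for subregion, r in self.summary.iterrows():
            row = {"method": method, "subregion": subregion}
            for m in METRIC_NAMES:
                mean, sd = r[f"{m}_mean"], r[f"{m}_sd"]
                row[m] = ("nan" if np.isnan(mean)
                          else f"{mean:.2f}±{sd:.2f}")
                row[f"{m}_mean"], row[f"{m}_sd"] = mean, sd
            rows.append(row)
        frame = pd.DataFrame(rows)
        if path is not None:
            frame.to_csv(path, index=False)
        return frame


def evaluate_cohort(subject_reports, class_names=None) -> MetricReport:
    """Aggregate per-subject metric dicts (from :func:`subject_metrics`).

    Undefined entries are excluded from each metric's mean/SD; their counts
    are reported.  If every entry of a metric is undefined, its aggregate
    is NaN.
    """
    if not subject_reports:
        raise ValueError("need at least one subject report")
    if class_names is None:
        class_names = {c: LABEL_NAMES[c] for c in TUMOR_CLASSES}
    records = []
    for i, rep in enumerate(subject_reports):
        for c, values in rep.items():
            name = class_names.get(c, str(c))
            for m, v in values.items():
                records.append({"subject": i, "subregion": name,
                                "metric": m, "value": v})
    per_subject = pd.DataFrame(records)
    rows = {}
    for (name, m), grp in per_subject.groupby(["subregion", "metric"]):
        vals = grp["value"].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        row = rows.setdefault(name, {})
        row[f"{m}_mean"] = defined.mean() if len(defined) else float("nan")
        row[f"{m}_sd"] = defined.std() if len(defined) else float("nan")
        row[f"{m}_excluded"] = int(np.isnan(vals).sum())
    summary = pd.DataFrame.from_dict(rows, orient="index")
    order = [n for n in class_names.values() if n in summary.index]
    order += [n for n in summary.index if n not in order]
    summary = summary.loc[order]
    cols = [f"{m}_{s}" for m in METRIC_NAMES for s in ("mean", "sd", "excluded")]
    return MetricReport(per_subject=per_subject, summary=summary[cols])
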