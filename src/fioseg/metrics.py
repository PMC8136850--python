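"""Two-class segmentation evaluation: global accuracy, IoU, boundary-F1.

Masks use the {1 = normal tissue, 2 = tumor} label convention throughout,
with tumor (class 2) as the positive class of the confusion table.  Three
measures are computed per image pair:

* global accuracy ``GA = (TP + TN) / (TP + TN + FP + FN)``;
* per-class Jaccard index ``IoU = TP / (TP + FP + FN)``;
* boundary-F1 (``BF``): the harmonic mean of boundary precision and
  recall, where a boundary pixel counts as matched when a boundary pixel
  of the other mask lies within a Euclidean distance tolerance.

The pixelwise F1 (Dice) ``2 TP / (2 TP + FP + FN)`` is also provided; it
relates to the Jaccard index by ``Dice = 2 IoU / (1 + IoU)``.  Reported
"BF score" columns use the boundary-matching variant: pixelwise F1 tracks
IoU closely, whereas boundary-F1 is far more sensitive to contour error,
which is what the measure is meant to capture.

Set-level averaging follows the class-then-image convention: global
accuracy accumulates pixel counts over the whole set, while mean IoU and
mean BF average the per-image class means over images, skipping classes
absent from an image.  Tables of percentages are aggregated with half-up
rounding at two decimals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "NORMAL",
    "TUMOR",
    "ConfusionCounts",
    "ImageMetrics",
    "confusion_counts",
    "global_accuracy",
    "class_iou",
    "pixel_f1",
    "boundary_f1",
    "boundary_pixels",
    "default_bf_tolerance",
    "evaluate_image",
    "evaluate_set",
    "metrics_table",
    "aggregate_tables",
    "round_half_up",
    "read_mask",
    "write_mask",
    "METRIC_COLUMNS",
]

NORMAL = 1
TUMOR = 2
_CLASSES = (NORMAL, TUMOR)

#: Column layout of a metrics table: three measures, before/after condition.
METRIC_COLUMNS = pd.MultiIndex.from_product(
    [["Global Accuracy", "Mean IoU", "Mean BF"], ["Before", "After"]],
    names=["metric", "condition"],
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts with tumor (class 2) as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ImageMetrics:
    """Per-image (or per-set) evaluation summary; all values in [0, 1].

    Absent classes carry NaN in the per-class dicts and are skipped by the
    class means.
    """

    global_accuracy: float
    iou_per_class: dict[int, float]
    mean_iou: float
    bf_per_class: dict[int, float]
    mean_bf: float


def _check_mask(mask: NDArray, name: str) -> NDArray[np.int64]:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name}: expected a nonempty 2-D mask, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, _CLASSES).all():
        raise ValueError(f"{name}: labels must be in {{1, 2}}, found {vals.tolist()}")
    return arr.astype(np.int64)


def confusion_counts(pred: NDArray, truth: NDArray) -> ConfusionCounts:
    """Count TP/TN/FP/FN pixels between two {1,2} masks of equal shape."""
    p = _check_mask(pred, "pred")
    t = _check_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    pp, tt = p == TUMOR, t == TUMOR
    tp = int(np.count_nonzero(pp & tt))
    tn = int(np.count_nonzero(~pp & ~tt))
    fp = int(np.count_nonzero(pp & ~tt))
    fn = int(np.count_nonzero(~pp & tt))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def global_accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified pixels regardless of class."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def _swap_for_class(c: ConfusionCounts, positive_class: int) -> ConfusionCounts:
    if positive_class == TUMOR:
        return c
    if positive_class == NORMAL:
        return ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
    raise ValueError(f"unknown class {positive_class}")


def class_iou(c: ConfusionCounts, positive_class: int = TUMOR) -> float:
    """Jaccard index TP/(TP+FP+FN) for the requested class; NaN if absent."""
    s = _swap_for_class(c, positive_class)
    union = s.tp + s.fp + s.fn
    if union == 0:
        return math.nan
    return s.tp / union


def pixel_f1(c: ConfusionCounts, positive_class: int = TUMOR) -> float:
    """Pixelwise F1 (Dice) 2TP/(2TP+FP+FN); NaN if the class is absent."""
    s = _swap_for_class(c, positive_class)
    denom = 2 * s.tp + s.fp + s.fn
    if denom == 0:
        return math.nan
    return 2 * s.tp / denom


def boundary_pixels(mask: NDArray, positive_class: int) -> NDArray[np.bool_]:
    """Inner 4-connectivity boundary of the class region.

    A region pixel is boundary if any of its four neighbours has a
    different label, or if it lies on the image border.
    """
    region = _check_mask(mask, "mask") == positive_class
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(region, structure=cross, border_value=0)
    return region & ~eroded


def default_bf_tolerance(shape: tuple[int, int]) -> float:
    """Distance tolerance: 0.75% of the image diagonal, ceil to a pixel."""
    diag = math.hypot(shape[0], shape[1])
    return float(math.ceil(0.0075 * diag))


def boundary_f1(
    pred: NDArray,
    truth: NDArray,
    positive_class: int = TUMOR,
    tolerance: float | None = None,
) -> float:
    """Boundary-matching F1 for one class at a pixel-distance tolerance.

    Precision is the fraction of predicted boundary pixels lying within
    ``tolerance`` (Euclidean) of some truth boundary pixel; recall is the
    symmetric fraction.  Returns NaN when both boundaries are empty and 0
    when exactly one is.
    """
    p = _check_mask(pred, "pred")
    t = _check_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if tolerance is None:
        tolerance = default_bf_tolerance(p.shape)
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")

    bp = boundary_pixels(p, positive_class)
    bt = boundary_pixels(t, positive_class)
    np_, nt = int(bp.sum()), int(bt.sum())
    if np_ == 0 and nt == 0:
        return math.nan
    if np_ == 0 or nt == 0:
        return 0.0

    # distance from every pixel to the nearest boundary pixel of the other mask
    dist_to_truth = ndimage.distance_transform_edt(~bt)
    dist_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float(np.count_nonzero(dist_to_truth[bp] <= tolerance)) / np_
    recall = float(np.count_nonzero(dist_to_pred[bt] <= tolerance)) / nt
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_image(
    pred: NDArray,
    truth: NDArray,
    tolerance: float | None = None,
) -> ImageMetrics:
    """Evaluate one prediction/truth pair; class means skip absent classes."""
    c = confusion_counts(pred, truth)
    ious = {k: class_iou(c, k) for k in _CLASSES}
    bfs = {k: boundary_f1(pred, truth, k, tolerance) for k in _CLASSES}
    return ImageMetrics(
        global_accuracy=global_accuracy(c),
        iou_per_class=ious,
        mean_iou=float(np.nanmean(list(ious.values()))),
        bf_per_class=bfs,
        mean_bf=float(np.nanmean(list(bfs.values()))),
    )


def evaluate_set(
    pairs: Sequence[tuple[NDArray, NDArray]] | Iterable[tuple[NDArray, NDArray]],
    tolerance: float | None = None,
    iou_averaging: Literal["image", "dataset"] = "image",
) -> ImageMetrics:
    """Evaluate a set of pairs.

    Global accuracy is computed from confusion counts accumulated over all
    pixels of all images.  With the default image averaging, mean IoU and
    mean BF are the unweighted average over images of the per-image
    class-averaged values; ``"dataset"`` instead accumulates the IoU
    confusion counts over the whole set before forming the class ratios
    (BF always averages per image, being defined per contour pair).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    acc = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    per_image_iou: list[float] = []
    per_image_bf: list[float] = []
    class_bf_acc: dict[int, list[float]] = {k: [] for k in _CLASSES}
    for pred, truth in pairs:
        m = evaluate_image(pred, truth, tolerance)
        c = confusion_counts(pred, truth)
        for f in acc:
            acc[f] += getattr(c, f)
        per_image_iou.append(m.mean_iou)
        per_image_bf.append(m.mean_bf)
        for k in _CLASSES:
            class_bf_acc[k].append(m.bf_per_class[k])
    total = ConfusionCounts(**acc)
    class_iou_acc = {k: class_iou(total, k) for k in _CLASSES}
    if iou_averaging == "dataset":
        mean_iou = float(np.nanmean(list(class_iou_acc.values())))
    else:
        mean_iou = float(np.nanmean(per_image_iou))
    return ImageMetrics(
        global_accuracy=global_accuracy(total),
        iou_per_class=class_iou_acc,
        mean_iou=mean_iou,
        bf_per_class={k: float(np.nanmean(v)) for k, v in class_bf_acc.items()},
        mean_bf=float(np.nanmean(per_image_bf)),
    )


# ---------------------------------------------------------------------------
# Metrics tables (per-model rows, before/after sub-columns) and aggregation
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as in hand-rounded tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_table(rows: dict[str, dict[tuple[str, str], float]]) -> pd.DataFrame:
    """Build a metrics table (percent values) from per-model row dicts.

    ``rows`` maps a model name to ``{(metric, condition): percent}`` with
    metric in {"Global Accuracy", "Mean IoU", "Mean BF"} and condition in
    {"Before", "After"}.  Missing cells become NaN.
    """
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["metric", "condition"])
    df = df.reindex(columns=METRIC_COLUMNS.intersection(df.columns))
    df.index.name = "model"
    return df


def _decimal_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: Decimal(repr(float(v))))


def aggregate_tables(
    tables: Sequence[pd.DataFrame],
    add_average_row: bool = True,
    average_label: str = "Average",
) -> pd.DataFrame:
    """Element-wise mean of metrics tables, plus a column-average row.

    All tables must share row keys and columns.  Cells are averaged in
    exact decimal arithmetic and reported to 2 decimal places, half-up;
    the appended average row is the column mean over the (rounded) model
    rows, rounded the same way.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    first = tables[0]
    for t in tables[1:]:
        if not t.index.equals(first.index) or not t.columns.equals(first.columns):
            raise ValueError("tables must share row keys and columns")
    dec = _decimal_frame(first)
    for t in tables[1:]:
        dec = dec + _decimal_frame(t)
    n = Decimal(len(tables))
    q = Decimal("0.01")
    mean = dec.map(lambda v: (v / n).quantize(q, rounding=ROUND_HALF_UP))
    if add_average_row:
        avg = {
            col: (sum(mean[col]) / Decimal(len(mean))).quantize(q, rounding=ROUND_HALF_UP)
            for col in mean.columns
        }
        mean.loc[average_label] = pd.Series(avg)
    out = mean.map(float)
    out.index.name = first.index.name
    return out


# ---------------------------------------------------------------------------
# Mask I/O ({1,2} convention on 8-bit grayscale files)
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, mapping: Literal["labels", "binary"] = "labels") -> NDArray[np.int64]:
    """Read an 8-bit grayscale mask file.

    ``mapping="labels"`` expects pixel values literally in {1, 2};
    ``mapping="binary"`` maps 0 -> 1 (normal) and any nonzero -> 2 (tumor),
    accepting the common {0, 255} and {0, 1} encodings.
    """
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int64)
    if mapping == "binary":
        return np.where(arr > 0, TUMOR, NORMAL).astype(np.int64)
    vals = np.unique(arr)
    if not np.isin(vals, _CLASSES).all():
        raise ValueError(
            f"{path}: mask values {vals.tolist()} are not in {{1, 2}}; "
            "use mapping='binary' for 0/255 masks"
        )
    return arr


def write_mask(path: str | Path, mask: NDArray) -> None:
    """Write a {1,2} mask as an 8-bit grayscale PNG, preserving the coding."""
    arr = _check_mask(mask, "mask").astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
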