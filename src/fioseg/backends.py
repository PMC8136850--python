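"""Two-class segmentation backends and the batch / one-by-one drivers.

Two backend kinds are provided:

* ``classical`` — a deterministic pipeline: collapse channels, median
  smoothing, Otsu global threshold with the dark side taken as the tumor
  candidate (hypoechoic assumption, invertible via a polarity flag),
  morphological opening/closing, and a largest-connected-component filter
  with an area floor.
* ``learned`` — a tiny learned per-pixel classifier (a small scikit-learn
  MLP over multi-scale Gaussian / local-variance texture features and
  normalised coordinates) trained on phantom pairs with fixed seeds, with
  the same morphological cleanup applied to its pixel predictions.

Both are pure functions of their inputs at inference time, so the batch
and one-by-one invocation modes are guaranteed to produce identical masks;
:func:`segment_with` runs either mode and is the single entry point the
experiment pipeline uses.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage
from skimage import filters, morphology

from .metrics import NORMAL, TUMOR, read_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SegmenterSpec",
    "InferenceMode",
    "TinyLearnedSegmenter",
    "segment_classical",
    "train_tiny_learned",
    "segment_with",
    "save_learned",
    "load_learned",
]

InferenceMode = Literal["batch", "one_by_one"]


@dataclass(frozen=True)
class SegmenterSpec:
    """Configuration of one segmentation backend.

    Classical parameters: ``smoothing_radius`` (median filter disk),
    ``morphology_radius`` (opening/closing disk), ``min_area`` (component
    floor in pixels), ``dark_is_tumor`` (polarity).  Learned parameters:
    ``hidden_layers``, ``epochs``, ``learning_rate``, ``train_seed``,
    ``pixels_per_image`` (training subsample size).
    """

    name: str
    kind: Literal["classical", "learned"] = "classical"
    smoothing_radius: int = 2
    morphology_radius: int = 2
    min_area: int = 30
    dark_is_tumor: bool = True
    hidden_layers: tuple[int, ...] = (32, 16)
    epochs: int = 200
    learning_rate: float = 1e-3
    train_seed: int = 0
    pixels_per_image: int = 400

    def __post_init__(self) -> None:
        if self.kind not in ("classical", "learned"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.smoothing_radius < 0 or self.morphology_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def _to_plane(image: NDArray) -> NDArray[np.float64]:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a 2-D or (H, W, C) image, got shape {np.shape(image)}")
    return arr


def _cleanup(candidate: NDArray[np.bool_], spec: SegmenterSpec) -> NDArray[np.int64]:
    """Morphological opening/closing then largest-component area filter."""
    if spec.morphology_radius > 0:
        selem = morphology.disk(spec.morphology_radius).astype(bool)
        candidate = ndimage.binary_opening(candidate, structure=selem)
        candidate = ndimage.binary_closing(candidate, structure=selem)
    labeled, ncomp = ndimage.label(candidate)
    if ncomp == 0:
        return np.full(candidate.shape, NORMAL, dtype=np.int64)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, ncomp + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < spec.min_area:
        return np.full(candidate.shape, NORMAL, dtype=np.int64)
    return np.where(labeled == best, TUMOR, NORMAL).astype(np.int64)


def segment_classical(image: NDArray, spec: SegmenterSpec) -> NDArray[np.int64]:
    """Deterministic Otsu-based segmentation of one image into {1,2}."""
    if spec.kind != "classical":
        raise ValueError(f"spec {spec.name!r} is not a classical backend")
    plane = _to_plane(image)
    if spec.smoothing_radius > 0:
        plane = filters.median(plane, morphology.disk(spec.smoothing_radius))
    if plane.max() == plane.min():
        return np.full(plane.shape, NORMAL, dtype=np.int64)
    thresh = filters.threshold_otsu(plane)
    candidate = plane < thresh if spec.dark_is_tumor else plane > thresh
    return _cleanup(candidate, spec)


# ---------------------------------------------------------------------------
# Tiny learned backend
# ---------------------------------------------------------------------------

_FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


def _pixel_features(image: NDArray) -> NDArray[np.float64]:
    """Per-pixel feature stack: intensity, multi-scale Gaussian means,
    local standard deviations, and normalised image coordinates."""
    plane = _to_plane(image) / 255.0
    h, w = plane.shape
    feats = [plane]
    for s in _FEATURE_SIGMAS:
        sm = ndimage.gaussian_filter(plane, s)
        feats.append(sm)
        var = ndimage.gaussian_filter(plane**2, s) - sm**2
        feats.append(np.sqrt(np.clip(var, 0, None)))
    yy, xx = np.mgrid[0:h, 0:w]
    feats.append(yy / max(h - 1, 1))
    feats.append(xx / max(w - 1, 1))
    return np.stack(feats, axis=-1).reshape(h * w, -1)


@dataclass
class TinyLearnedSegmenter:
    """Handle for a trained per-pixel classifier (< 10k parameters)."""

    spec: SegmenterSpec
    model: object | None  # fitted sklearn MLPClassifier, None if untrained
    train_iou: float = float("nan")
    seeds: dict = field(default_factory=dict)

    @property
    def is_trained(self) -> bool:
        return self.model is not None

    def sanity_check(self, min_train_iou: float = 0.2) -> bool:
        """Reject handles whose training-set tumor IoU is near chance."""
        return self.is_trained and self.train_iou >= min_train_iou

    def predict(self, image: NDArray) -> NDArray[np.int64]:
        plane = _to_plane(image)
        if not self.is_trained:
            return np.full(plane.shape, NORMAL, dtype=np.int64)
        feats = _pixel_features(image)
        pred = np.asarray(self.model.predict(feats)).reshape(plane.shape)
        return _cleanup(pred == TUMOR, self.spec)


def _load_manifest_pairs(
    manifest: str | Path | Sequence[tuple[NDArray, NDArray]],
) -> list[tuple[NDArray, NDArray]]:
    if not isinstance(manifest, (str, Path)):
        return list(manifest)
    from PIL import Image as PILImage

    manifest = Path(manifest)
    root = manifest.parent
    rows = pd.read_csv(manifest)
    pairs = []
    for _, row in rows.iterrows():
        subset, name = row["subset"], row["filename"]
        img = np.asarray(PILImage.open(root / f"Original_{subset}" / name))
        mask = read_mask(root / f"Ground_Truth_{subset}" / name)
        pairs.append((img, mask))
    return pairs


def train_tiny_learned(
    manifest: str | Path | Sequence[tuple[NDArray, NDArray]],
    spec: SegmenterSpec,
) -> TinyLearnedSegmenter:
    """Train the tiny per-pixel segmenter on phantom (image, mask) pairs.

    ``manifest`` is either a dataset manifest CSV path (as written by
    ``generate_dataset``) or an in-memory sequence of pairs.  Training
    subsamples ``spec.pixels_per_image`` pixels per image with a seeded
    generator, so results are reproducible given (dataset, seeds).  A spec
    with ``epochs == 0`` yields an untrained handle that predicts all
    normal tissue and fails :meth:`TinyLearnedSegmenter.sanity_check`.
    """
    if spec.kind != "learned":
        raise ValueError(f"spec {spec.name!r} is not a learned backend")
    pairs = _load_manifest_pairs(manifest)
    if len(pairs) < 20:
        raise ValueError(f"need >= 20 training pairs, got {len(pairs)}")
    if spec.epochs == 0:
        logger.warning("epochs=0: returning an untrained handle")
        return TinyLearnedSegmenter(spec=spec, model=None, train_iou=0.0)

    from sklearn.neural_network import MLPClassifier

    rng = np.random.default_rng(spec.train_seed)
    X_parts, y_parts = [], []
    for img, mask in pairs:
        feats = _pixel_features(img)
        labels = np.asarray(mask).reshape(-1)
        k = min(spec.pixels_per_image, labels.size)
        # balanced subsample: half tumor, half normal where possible
        tumor_idx = np.flatnonzero(labels == TUMOR)
        normal_idx = np.flatnonzero(labels == NORMAL)
        take_t = min(k // 2, tumor_idx.size)
        take_n = min(k - take_t, normal_idx.size)
        sel = np.concatenate(
            [rng.choice(tumor_idx, take_t, replace=False),
             rng.choice(normal_idx, take_n, replace=False)]
        )
        X_parts.append(feats[sel])
        y_parts.append(labels[sel])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)

    model = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        max_iter=spec.epochs,
        learning_rate_init=spec.learning_rate,
        random_state=spec.train_seed,
        early_stopping=False,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, y)

    handle = TinyLearnedSegmenter(
        spec=spec, model=model, seeds={"train_seed": spec.train_seed}
    )
    # training-set tumor IoU on the subsample, for the sanity check
    yhat = model.predict(X)
    inter = np.count_nonzero((yhat == TUMOR) & (y == TUMOR))
    union = np.count_nonzero((yhat == TUMOR) | (y == TUMOR))
    handle.train_iou = inter / union if union else 0.0
    logger.info("trained %s: subsample tumor IoU %.3f", spec.name, handle.train_iou)
    return handle


def save_learned(handle: TinyLearnedSegmenter, path: str | Path) -> None:
    """Serialise a learned handle (spec, weights, seed record) to one file."""
    with open(path, "wb") as fh:
        pickle.dump(handle, fh)


def load_learned(path: str | Path) -> TinyLearnedSegmenter:
    with open(path, "rb") as fh:
        handle = pickle.load(fh)
    if not isinstance(handle, TinyLearnedSegmenter):
        raise ValueError(f"{path} does not contain a learned segmenter")
    return handle


# ---------------------------------------------------------------------------
# Invocation modes
# ---------------------------------------------------------------------------

def _segment_one(segmenter: SegmenterSpec | TinyLearnedSegmenter, image: NDArray) -> NDArray[np.int64]:
    if isinstance(segmenter, TinyLearnedSegmenter):
        return segmenter.predict(image)
    if segmenter.kind == "classical":
        return segment_classical(image, segmenter)
    raise ValueError("a learned spec must be trained first (use train_tiny_learned)")


def segment_with(
    segmenter: SegmenterSpec | TinyLearnedSegmenter,
    images: Sequence[NDArray] | Iterable[NDArray],
    mode: InferenceMode = "batch",
) -> list[NDArray[np.int64]]:
    """Segment a sequence of images in batch or one-by-one mode.

    Batch mode materialises the whole collection and processes it as one
    datastore; one-by-one mode feeds a single image per call.  Every
    backend here is a pure function of (image, segmenter), so the two
    modes return identical masks — no batch-dependent state exists.
    Output order matches input order.
    """
    if mode not in ("batch", "one_by_one"):
        raise ValueError(f"unknown mode {mode!r}")
    images = list(images)
    if not images:
        raise ValueError("empty image sequence")
    if mode == "batch":
        return [_segment_one(segmenter, img) for img in images]
    out: list[NDArray[np.int64]] = []
    for img in images:
        out.append(_segment_one(segmenter, img))
    return out
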