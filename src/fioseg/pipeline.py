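"""Experiment orchestration: enhance-or-not x backend x mode, with reports.

An experiment runs one or more two-class segmentation backends over one or
more image subsets (on-disk folders in the ``Original_*/Ground_Truth_*``
layout, or phantom subsets generated on the fly), in batch and/or
one-by-one invocation mode, under the "before" (raw images) and "after"
(FIO contrast-enhanced images) conditions.  Each (subset, mode) yields a
metrics table — one row per backend, Before/After sub-columns for global
accuracy, mean IoU and mean BF, in percent to 2 decimals — and the
per-mode tables are averaged across subsets with an appended column-mean
row, mirroring the standard before/after comparison layout.

Everything downstream of the master seed is deterministic: identical
configuration and seed reproduce byte-identical reports.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray
from PIL import Image
from pydantic import BaseModel, Field

from . import metrics as sm
from .backends import (
    InferenceMode,
    SegmenterSpec,
    TinyLearnedSegmenter,
    segment_with,
    train_tiny_learned,
)
from .enhance import EnhanceConfig, enhance
from .phantom import PhantomParams, generate_pair

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetPair",
    "PhantomSource",
    "DiskSource",
    "ExperimentConfig",
    "ExperimentReport",
    "load_dataset",
    "run_experiment",
    "write_report",
    "config_from_yaml",
    "ReportDocument",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


class DatasetPair(NamedTuple):
    name: str
    image: NDArray
    mask: NDArray


@dataclass(frozen=True)
class PhantomSource:
    """Generate ``n`` phantoms from ``params`` (seeded per subset)."""

    params: PhantomParams
    n: int


@dataclass(frozen=True)
class DiskSource:
    """Load pairs from an ``Original_*/Ground_Truth_*`` folder."""

    path: Path
    mask_mapping: str = "labels"


@dataclass
class ExperimentConfig:
    """Full description of one experiment run.

    ``subsets`` maps a subset name (the benign/malignant analogue) to its
    source.  ``conditions`` selects raw ("before") and/or FIO-enhanced
    ("after") inputs.  ``bf_tolerance`` is the boundary-F1 distance
    tolerance in pixels (None: 0.75% of the image diagonal, ceil).
    """

    subsets: dict[str, PhantomSource | DiskSource]
    backends: list[SegmenterSpec | TinyLearnedSegmenter]
    modes: list[InferenceMode] = field(default_factory=lambda: ["batch", "one_by_one"])
    conditions: list[str] = field(default_factory=lambda: ["Before", "After"])
    bf_tolerance: float | None = None
    enhance_config: EnhanceConfig = field(default_factory=EnhanceConfig)
    report_dir: Path | None = None
    materialize_enhanced: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subsets:
            raise ValueError("at least one subset is required")
        if not self.backends or not self.modes or not self.conditions:
            raise ValueError("at least one backend, mode and condition are required")
        bad = set(self.conditions) - {"Before", "After"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        for m in self.modes:
            if m not in ("batch", "one_by_one"):
                raise ValueError(f"unknown mode {m!r}")


@dataclass
class ExperimentReport:
    """Per-(subset, mode) metrics tables, per-mode aggregates, metadata."""

    tables: dict[tuple[str, str], pd.DataFrame]
    aggregated: dict[str, pd.DataFrame]
    metadata: dict


def load_dataset(
    path: str | Path, mask_mapping: str = "labels"
) -> list[DatasetPair]:
    """Load aligned (image, truth-mask) pairs from a dataset folder.

    The folder must contain ``Original_<subset>/`` image folders paired by
    name with ``Ground_Truth_<subset>/`` mask folders; images and masks
    pair by filename.  Unpaired files are reported in a warning and
    skipped; a mask with labels outside {1, 2} raises an error naming the
    file; an empty result is an error.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset folder {root} does not exist")
    pairs: list[DatasetPair] = []
    orig_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("Original_"))
    if not orig_dirs:
        raise ValueError(f"no Original_* folders under {root}")
    for orig in orig_dirs:
        subset = orig.name.removeprefix("Original_")
        gt = root / f"Ground_Truth_{subset}"
        if not gt.is_dir():
            logger.warning("no Ground_Truth_%s folder for %s: skipped", subset, orig.name)
            continue
        images = {p.name: p for p in orig.iterdir() if p.suffix.lower() in _IMAGE_EXTS}
        masks = {p.name: p for p in gt.iterdir() if p.suffix.lower() in _IMAGE_EXTS}
        for name in sorted(images.keys() | masks.keys()):
            if name not in masks:
                logger.warning("image %s/%s has no ground-truth partner: skipped", orig.name, name)
                continue
            if name not in images:
                logger.warning("mask %s/%s has no image partner: skipped", gt.name, name)
                continue
            img = np.asarray(Image.open(images[name]))
            mask = sm.read_mask(masks[name], mapping=mask_mapping)  # type: ignore[arg-type]
            if img.shape[:2] != mask.shape:
                raise ValueError(f"{name}: image {img.shape[:2]} and mask {mask.shape} disagree")
            pairs.append(DatasetPair(f"{subset}/{name}", img, mask))
    if not pairs:
        raise ValueError(f"no image/mask pairs found under {root}")
    return pairs


def _subset_pairs(
    name: str, source: PhantomSource | DiskSource, master_seed: int
) -> list[DatasetPair]:
    if isinstance(source, DiskSource):
        return load_dataset(source.path, source.mask_mapping)
    # one independent child seed stream per subset, derived from the master
    # (crc32 is stable across processes, unlike hash())
    subset_entropy = zlib.crc32(name.encode()) % (2**31)
    seeds = np.random.SeedSequence([master_seed, subset_entropy]).generate_state(source.n) % (2**31)
    pairs = []
    for i in range(source.n):
        p = replace(source.params, seed=int(seeds[i]))
        pair = generate_pair(p)
        pairs.append(DatasetPair(f"{name}/phantom_{i:04d}.png", pair.image, pair.mask))
    return pairs


def _backend_name(b: SegmenterSpec | TinyLearnedSegmenter) -> str:
    return b.spec.name if isinstance(b, TinyLearnedSegmenter) else b.name


def _resolve_backend(
    b: SegmenterSpec | TinyLearnedSegmenter, pairs: Sequence[DatasetPair]
) -> SegmenterSpec | TinyLearnedSegmenter:
    if isinstance(b, SegmenterSpec) and b.kind == "learned":
        logger.info("training learned backend %s on %d pairs", b.name, len(pairs))
        return train_tiny_learned([(p.image, p.mask) for p in pairs], b)
    return b


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full before/after x backend x mode comparison.

    For every subset, backend and mode the raw images ("Before") and the
    FIO-enhanced images ("After") are segmented and scored against ground
    truth with set-level evaluation; per-mode tables are then averaged
    across subsets with :func:`fioseg.metrics.aggregate_tables`.  A
    backend failure aborts the run naming the offending image.
    """
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    meta: dict = {
        "seed": config.seed,
        "subsets": {},
        "backends": [_backend_name(b) for b in config.backends],
        "modes": list(config.modes),
        "conditions": list(config.conditions),
        "bf_tolerance": config.bf_tolerance,
        "enhance": {
            "channel_policy": config.enhance_config.channel_policy,
            "iterations": config.enhance_config.iterations,
        },
    }
    columns = pd.MultiIndex.from_tuples(
        [(m, c) for m in ("Global Accuracy", "Mean IoU", "Mean BF") for c in config.conditions],
        names=["metric", "condition"],
    )
    for subset, source in config.subsets.items():
        pairs = _subset_pairs(subset, source, config.seed)
        meta["subsets"][subset] = {"n": len(pairs)}
        inputs: dict[str, list[NDArray]] = {}
        if "Before" in config.conditions:
            inputs["Before"] = [p.image for p in pairs]
        if "After" in config.conditions:
            inputs["After"] = [enhance(p.image, config.enhance_config) for p in pairs]
            if config.materialize_enhanced and config.report_dir is not None:
                out = Path(config.report_dir) / f"Fuzzy_{subset}"
                out.mkdir(parents=True, exist_ok=True)
                for p, img in zip(pairs, inputs["After"]):
                    arr = np.asarray(img, dtype=np.uint8)
                    Image.fromarray(arr).save(out / Path(p.name).name)
        truths = [p.mask for p in pairs]
        backends = [_resolve_backend(b, pairs) for b in config.backends]
        for mode in config.modes:
            rows: dict[str, dict[tuple[str, str], float]] = {}
            for backend in backends:
                row: dict[tuple[str, str], float] = {}
                for cond, images in inputs.items():
                    try:
                        preds = segment_with(backend, images, mode)
                    except Exception as exc:  # re-raise naming the context
                        raise RuntimeError(
                            f"backend {_backend_name(backend)} failed on subset "
                            f"{subset!r} ({mode}, {cond}): {exc}"
                        ) from exc
                    res = sm.evaluate_set(
                        list(zip(preds, truths)), tolerance=config.bf_tolerance
                    )
                    row[("Global Accuracy", cond)] = sm.round_half_up(100 * res.global_accuracy)
                    row[("Mean IoU", cond)] = sm.round_half_up(100 * res.mean_iou)
                    row[("Mean BF", cond)] = sm.round_half_up(100 * res.mean_bf)
                rows[_backend_name(backend)] = row
            df = pd.DataFrame.from_dict(rows, orient="index")
            df.columns = pd.MultiIndex.from_tuples(df.columns, names=["metric", "condition"])
            df = df.reindex(columns=columns)
            df.index.name = "model"
            tables[(subset, mode)] = df
    aggregated = {
        mode: sm.aggregate_tables([tables[(s, mode)] for s in config.subsets])
        for mode in config.modes
    }
    report = ExperimentReport(tables=tables, aggregated=aggregated, metadata=meta)
    if config.report_dir is not None:
        write_report(report, config.report_dir)
    return report


# ---------------------------------------------------------------------------
# Report serialisation (CSV per table + a JSON twin with a pydantic schema)
# ---------------------------------------------------------------------------

class ReportCell(BaseModel):
    metric: str
    condition: str
    value: float = Field(ge=0.0, le=100.0)


class ReportRow(BaseModel):
    model: str
    cells: list[ReportCell]


class ReportTable(BaseModel):
    name: str
    rows: list[ReportRow]


class ReportDocument(BaseModel):
    """Schema of the machine-readable report twin."""

    metadata: dict
    tables: list[ReportTable]


def _table_model(name: str, df: pd.DataFrame) -> ReportTable:
    rows = []
    for model, row in df.iterrows():
        cells = [
            ReportCell(metric=m, condition=c, value=float(v))
            for (m, c), v in row.items()
            if pd.notna(v)
        ]
        rows.append(ReportRow(model=str(model), cells=cells))
    return ReportTable(name=name, rows=rows)


def write_report(report: ExperimentReport, path: str | Path) -> dict[str, Path]:
    """Write one CSV per table plus a schema-validated JSON twin.

    CSV columns keep the metric / Before-After two-row header; values are
    percentages at 2 decimals.  Returns the written file paths.
    """
    if not report.tables:
        raise ValueError("empty report")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    named: list[tuple[str, pd.DataFrame]] = [
        (f"{subset}_{mode}", df) for (subset, mode), df in report.tables.items()
    ] + [(f"average_{mode}", df) for mode, df in report.aggregated.items()]
    for name, df in named:
        p = out / f"{name}.csv"
        df.to_csv(p, float_format="%.2f")
        written[name] = p
    doc = ReportDocument(
        metadata=report.metadata,
        tables=[_table_model(name, df) for name, df in named],
    )
    jp = out / "report.json"
    jp.write_text(doc.model_dump_json(indent=2))
    written["json"] = jp
    logger.info("wrote report (%d tables) to %s", len(named), out)
    return written


# ---------------------------------------------------------------------------
# YAML configuration (CLI `run` entry point)
# ---------------------------------------------------------------------------

def config_from_yaml(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Schema::

        seed: 0
        modes: [batch, one_by_one]
        conditions: [Before, After]
        bf_tolerance: null
        report_dir: reports/
        subsets:
          benign_like:            # phantom subset
            phantom: {n: 20, contrast: 0.35, speckle_looks: 4}
          clinic:                 # on-disk subset
            folder: /data/some_dataset
            mask_mapping: labels
        backends:
          - {name: otsu, kind: classical, smoothing_radius: 2}
    """
    raw = yaml.safe_load(Path(path).read_text())
    subsets: dict[str, PhantomSource | DiskSource] = {}
    for name, spec in raw["subsets"].items():
        if "phantom" in spec:
            opts = dict(spec["phantom"])
            n = int(opts.pop("n"))
            if "size" in opts:
                opts["size"] = tuple(opts["size"])
            if "lesion_area_fraction" in opts:
                opts["lesion_area_fraction"] = tuple(opts["lesion_area_fraction"])
            subsets[name] = PhantomSource(params=PhantomParams(**opts), n=n)
        else:
            subsets[name] = DiskSource(
                path=Path(spec["folder"]), mask_mapping=spec.get("mask_mapping", "labels")
            )
    backends = [SegmenterSpec(**{**b, "hidden_layers": tuple(b.get("hidden_layers", (32, 16)))})
                if "hidden_layers" in b else SegmenterSpec(**b)
                for b in raw["backends"]]
    kwargs: dict = {}
    for key in ("modes", "conditions", "bf_tolerance", "seed", "materialize_enhanced"):
        if key in raw:
            kwargs[key] = raw[key]
    if "report_dir" in raw:
        kwargs["report_dir"] = Path(raw["report_dir"])
    if "enhance" in raw:
        kwargs["enhance_config"] = EnhanceConfig(**raw["enhance"])
    return ExperimentConfig(subsets=subsets, backends=backends, **kwargs)
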