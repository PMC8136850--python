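"""Published per-model evaluation tables shipped as package data.

The breast-ultrasound segmentation study this package re-implements
reports, for eight CNN segmentation models, global accuracy / mean IoU /
mean BF percentages before and after fuzzy enhancement, separately for the
benign and malignant image subsets and for the batch and one-by-one
invocation modes, together with printed cross-subset average tables and
headline averages.  Those printed numbers are shipped here as a CSV so the
table-aggregation arithmetic can be exercised and checked offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import METRIC_COLUMNS

__all__ = ["load_reference_table", "REFERENCE_TABLE_IDS"]

#: t1/t2: batch benign/malignant; t3: printed batch average (with Average row);
#: t4/t5: one-by-one benign/malignant; t6: printed one-by-one average.
REFERENCE_TABLE_IDS = ("t1", "t2", "t3", "t4", "t5", "t6")


def _raw() -> pd.DataFrame:
    with resources.files("fioseg.data").joinpath("reference_tables.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_table(table_id: str) -> pd.DataFrame:
    """Return one published table as a metrics-table DataFrame.

    Rows are model names (plus an ``Average`` row for the printed average
    tables), columns are the (metric, condition) pairs in the standard
    order, values are percentages to 2 decimals.
    """
    if table_id not in REFERENCE_TABLE_IDS:
        raise ValueError(f"unknown table id {table_id!r}; choose from {REFERENCE_TABLE_IDS}")
    raw = _raw()
    sub = raw[raw["table"] == table_id]
    wide = sub.pivot_table(
        index="model", columns=["metric", "condition"], values="value", sort=False
    )
    wide = wide.reindex(columns=METRIC_COLUMNS)
    order = [m for m in sub["model"].unique()]
    wide = wide.loc[order]
    wide.index.name = "model"
    wide.columns.names = ["metric", "condition"]
    return wide
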