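"""Readers and writers for count tables, cell tables and metadata.

All tables are UTF-8 CSV with a header row; ROI ids are strings; missing
values are empty cells and are rejected in count columns. Round-tripping a
dataset through ``write_counts``/``read_counts`` is the identity.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .config import CohortMeta, PanelConfig
from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

REQUIRED_META = ["roi_id", "tissue_id", "mask_area", "cd45_fraction"]


def read_counts(path: str | Path, panel: PanelConfig) -> ExpressionDataset:
    """Read a raw ROI x antibody count table.

    The file must have one row per ROI with ``roi_id``, ``tissue_id``,
    ``mask_area``, ``cd45_fraction`` and one column per panel name. Unknown
    protein columns are dropped with a warning; missing required columns and
    negative counts are errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    frame = pd.read_csv(
        path, sep=sep, dtype={"roi_id": str, "tissue_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_META if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    expected = panel.all_columns
    missing_proteins = [c for c in expected if c not in frame.columns]
    if missing_proteins:
        raise ValueError(f"missing panel column(s): {missing_proteins}")
    known = set(REQUIRED_META) | set(expected)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"dropping unknown column(s): {unknown}")
    counts = frame[expected].copy()
    if counts.isna().any().any():
        bad = list(counts.columns[counts.isna().any()])
        raise ValueError(f"missing values in count column(s): {bad}")
    if (counts.to_numpy() < 0).any():
        bad = list(counts.columns[(counts < 0).any()])
        raise ValueError(f"negative counts in column(s): {bad}")
    index = pd.Index(frame["roi_id"].astype(str), name="roi_id")
    counts.index = index
    meta_cols = ["tissue_id", "mask_area", "cd45_fraction"]
    if "compartment" in frame.columns:
        meta_cols.append("compartment")
    roi_meta = frame[meta_cols].copy()
    roi_meta.index = index
    ds = ExpressionDataset(
        matrix=counts,
        roi_meta=roi_meta,
        state="raw",
        control_columns=panel.control_columns,
    )
    logger.info("read_counts(%s): %d ROIs x %d columns", path, *counts.shape)
    return ds


def write_counts(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as CSV (ROI metadata first, then count columns)."""
    path = Path(path)
    meta_cols = ["tissue_id", "mask_area", "cd45_fraction"]
    if "compartment" in ds.roi_meta.columns:
        meta_cols.append("compartment")
    frame = pd.concat([ds.roi_meta[meta_cols], ds.matrix], axis=1)
    frame.index.name = "roi_id"
    frame.to_csv(path)
    logger.info("write_counts(%s): %d ROIs", path, len(frame))


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a per-cell table (centroids, features, optional immune flag)."""
    cells = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in cells.columns:
            raise ValueError(f"cell table missing required column {col!r}")
    if "immune" in cells.columns:
        cells["immune"] = cells["immune"].astype(bool)
    return cells


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cohort_meta(path: str | Path) -> CohortMeta:
    """Read tissue-level cohort metadata from CSV.

    Columns: tissue_id, patient_id, indication, arm, timepoint, response.
    """
    frame = pd.read_csv(path, dtype=str)
    required = ["tissue_id", "patient_id", "indication", "arm", "timepoint", "response"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort metadata missing column(s): {missing}")
    if frame["tissue_id"].duplicated().any():
        dupes = frame.loc[frame["tissue_id"].duplicated(), "tissue_id"].tolist()
        raise ValueError(f"duplicate tissue ids: {dupes}")
    return CohortMeta.from_dict(
        {
            row.tissue_id: {
                "patient_id": row.patient_id,
                "indication": row.indication,
                "arm": row.arm,
                "timepoint": row.timepoint,
                "response": row.response,
            }
            for row in frame.itertuples()
        }
    )


def write_cohort_meta(meta: CohortMeta, path: str | Path) -> None:
    rows = [{"tissue_id": t, **vars(info)} for t, info in meta.tissues.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_supplementary(path: str | Path) -> ExpressionDataset:
    """Adapter stub for externally distributed clinical cohort data files.

    Such files ship in ad-hoc spreadsheet layouts rather than a standard
    schema; once the files are in hand this adapter should map their ROI
    annotation and count columns onto :func:`read_counts` conventions
    (roi_id, tissue_id, mask_area, cd45_fraction + one column per antibody).
    """
    raise NotImplementedError(
        "external cohort data schema unknown; adapt this loader to the files "
        "and construct an ExpressionDataset via read_counts conventions."
    )
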