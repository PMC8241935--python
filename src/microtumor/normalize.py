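"""Three-step DSP count processing and ROI compartment classification.

Digital spatial profiling counts are processed in a fixed order before any
modelling:

1. **ERCC normalization** — each ROI's counts are divided by the ratio of
   its ERCC spike-in geometric mean to the grand geometric mean over all
   ROIs, removing batch/system scale differences.
2. **Isotype subtraction** — the matched IgG isotype control count in the
   same ROI is subtracted from each target; negatives are floored at zero.
3. **Area normalization** — counts are divided by the UV mask area, giving
   a count density (counts per µm²) comparable across differently sized
   ROIs.

For tissue-level comparisons the densities are then averaged within each
tissue compartment (immune-rich vs immune-poor), and for modelling the
densities are ln(x+1)-transformed and standardized per protein.

ROIs are classified immune-rich/immune-poor either by a fixed CD45+ cell
fraction cutoff (rich strictly above, default 25%) or by a 1-D hierarchical
2-cluster split of the fractions which also reports its derived cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._base import BaseEstimator
from .config import PanelConfig
from .dataset import ExpressionDataset, geometric_mean

logger = logging.getLogger(__name__)

IMMUNE_RICH = "immune_rich"
IMMUNE_POOR = "immune_poor"


def ercc_normalize(ds: ExpressionDataset, panel: PanelConfig) -> ExpressionDataset:
    """Divide each ROI by its ERCC scale factor.

    The per-ROI factor is ``f_i = geomean(ERCC_i) / grand_geomean`` where the
    grand geometric mean is taken over the per-ROI ERCC geometric means.
    After normalization every ROI has the same ERCC geometric mean.
    """
    ds.require_state("raw")
    missing = [c for c in panel.ercc_controls if c not in ds.matrix.columns]
    if missing:
        raise ValueError(f"ERCC control columns missing from matrix: {missing}")
    ercc = ds.matrix[panel.ercc_controls].to_numpy(dtype=float)
    nonpos = (ercc <= 0).any(axis=1)
    if nonpos.any():
        bad = ds.matrix.index[nonpos].tolist()
        raise ValueError(f"nonpositive ERCC count in ROI(s): {bad}")
    roi_geomeans = geometric_mean(ercc, axis=1)
    grand = geometric_mean(roi_geomeans)
    factors = roi_geomeans / grand
    out = ds.copy()
    out.matrix = ds.matrix.div(pd.Series(factors, index=ds.matrix.index), axis=0)
    out.advance_state("ercc_normalized")
    logger.info("ercc_normalize: %d ROIs, factor range [%.4g, %.4g]",
                len(factors), factors.min(), factors.max())
    return out


def isotype_subtract(ds: ExpressionDataset, panel: PanelConfig) -> ExpressionDataset:
    """Subtract the matched IgG isotype background, flooring at zero.

    When a target maps to several controls their arithmetic mean is used.
    Control columns are kept in the matrix (they remain flagged via
    ``control_columns``) so downstream steps stay auditable.
    """
    ds.require_state("ercc_normalized")
    out = ds.copy()
    for target in panel.targets:
        if target not in out.matrix.columns:
            continue
        controls = panel.isotype_for(target)  # validated non-empty at panel load
        background = out.matrix[controls].mean(axis=1)
        out.matrix[target] = (out.matrix[target] - background).clip(lower=0.0)
    out.control_columns = list(panel.control_columns)
    out.advance_state("background_subtracted")
    return out


def area_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Divide counts by the ROI's UV mask area, yielding count density."""
    ds.require_state("background_subtracted")
    area = ds.roi_meta["mask_area"].astype(float)
    if (area <= 0).any():
        bad = area.index[area <= 0].tolist()
        raise ValueError(f"nonpositive mask_area in ROI(s): {bad}")
    out = ds.copy()
    out.matrix = ds.matrix.div(area, axis=0)
    out.advance_state("density")
    logger.info("area_normalize: %d ROIs converted to count density", len(area))
    return out


def process_counts(ds: ExpressionDataset, panel: PanelConfig) -> ExpressionDataset:
    """Run the full raw -> density chain (ERCC, isotype, area)."""
    return area_normalize(isotype_subtract(ercc_normalize(ds, panel), panel))


def compartment_mean(ds: ExpressionDataset, compartment: str) -> pd.DataFrame:
    """Per-tissue unweighted mean density over that tissue's ROIs in a compartment.

    Tissues with no ROI in the requested compartment are omitted with a
    warning. Only biological target columns are averaged.
    """
    ds.require_state("density")
    if "compartment" not in ds.roi_meta.columns:
        raise ValueError("compartment labels not assigned; run classify_rois first")
    known = set(ds.roi_meta["compartment"].dropna().unique())
    if compartment not in known:
        raise ValueError(f"unknown compartment label {compartment!r}; have {sorted(known)}")
    in_scope = ds.roi_meta["compartment"] == compartment
    tissues = ds.roi_meta["tissue_id"]
    all_tissues = pd.unique(tissues)
    rows = {}
    for tissue in all_tissues:
        mask = in_scope & (tissues == tissue)
        if not mask.any():
            warnings.warn(
                f"tissue {tissue!r} has no ROI in compartment {compartment!r}; omitted"
            )
            continue
        rows[tissue] = ds.targets().loc[mask.to_numpy()].mean(axis=0)
    result = pd.DataFrame(rows).T
    result.index.name = "tissue_id"
    logger.info("compartment_mean(%s): %d tissues x %d proteins",
                compartment, result.shape[0], result.shape[1])
    return result


@dataclass
class RoiClassification:
    labels: pd.Series  # ROI id -> IMMUNE_RICH / IMMUNE_POOR
    cutoff: float      # the cutoff applied (derived for the cluster method)
    method: str


def classify_rois(
    ds: ExpressionDataset, method: str = "threshold", cutoff: float = 0.25
) -> RoiClassification:
    """Label ROIs immune-rich or immune-poor from their CD45+ cell fraction.

    ``threshold``: rich iff fraction strictly exceeds ``cutoff``.
    ``cluster``: 1-D agglomerative (Ward) 2-cluster split of the fractions;
    the cluster with the higher mean fraction is immune-rich and the derived
    cutoff is the midpoint between the two clusters' facing extremes.
    """
    frac = ds.roi_meta["cd45_fraction"].astype(float)
    if method == "threshold":
        labels = pd.Series(
            np.where(frac > cutoff, IMMUNE_RICH, IMMUNE_POOR), index=frac.index
        )
        used = float(cutoff)
    elif method == "cluster":
        values = frac.to_numpy()
        if np.ptp(values) == 0:
            raise ValueError("all CD45 fractions identical; no 2-cluster split exists")
        Z = linkage(values.reshape(-1, 1), method="ward")
        assign = fcluster(Z, t=2, criterion="maxclust")
        means = {c: values[assign == c].mean() for c in np.unique(assign)}
        rich_cluster = max(means, key=means.get)
        low = values[assign != rich_cluster].max()
        high = values[assign == rich_cluster].min()
        used = float((low + high) / 2.0)
        labels = pd.Series(
            np.where(assign == rich_cluster, IMMUNE_RICH, IMMUNE_POOR),
            index=frac.index,
        )
    else:
        raise ValueError(f"unknown classification method {method!r}")
    n_rich = int((labels == IMMUNE_RICH).sum())
    logger.info("classify_rois(%s, cutoff=%.3f): %d rich / %d poor",
                method, used, n_rich, len(labels) - n_rich)
    return RoiClassification(labels=labels, cutoff=used, method=method)


def log_standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ln(x+1)-transform then center/scale each column to mean 0, sd 1.

    Columns with zero variance after the log transform are dropped with a
    warning and recorded in the returned parameter table (sd = 0).
    Returns ``(Z, params)`` where ``params`` has per-column ``mean``, ``sd``
    (of the log values) and a ``kept`` flag.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("log_standardize requires a non-negative matrix")
    logged = np.log1p(matrix.astype(float))
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    kept = (logged.max(axis=0) - logged.min(axis=0)) > 0  # exact constancy check
    sd = sd.where(kept, 0.0)
    dropped = list(matrix.columns[~kept])
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
        logger.info("log_standardize: dropped zero-variance columns %s", dropped)
    Z = (logged.loc[:, kept] - mean[kept]) / sd[kept]
    params = pd.DataFrame({"mean": mean, "sd": sd, "kept": kept})
    return Z, params


class LogStandardizer(BaseEstimator):
    """Transformer wrapping :func:`log_standardize` with stored parameters.

    ``fit`` learns per-column log-scale mean/sd; ``transform`` applies them
    to new data (aligning by column name), so held-out ROIs are scaled with
    training parameters only.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "LogStandardizer":
        _, params = log_standardize(X)
        self.params_ = params
        self.columns_ = list(params.index[params["kept"]])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_is_fitted("params_")
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        logged = np.log1p(X[self.columns_].astype(float))
        p = self.params_.loc[self.columns_]
        return (logged - p["mean"]) / p["sd"]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
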