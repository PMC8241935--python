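"""Micro-tumor analyses: per-ROI PLS modelling and differential statistics.

Each profiled ROI is treated as an independent "micro-tumor" with its own
local response, so a cohort of a dozen tissues still yields tens to hundreds
of modelling units. On those units this module provides:

* ``plsr_workflow`` — PLS regression of a continuous readout (e.g. CD8A or
  Ki67 density, or the mean immune-neighbor number) on all other measured
  proteins within one tissue compartment;
* ``plsda_workflow`` — PLS discriminant analysis of a binary response label
  (responder = 1, nonresponder = 0) with ROC-AUC scoring;
* ``eliminate_variables`` — backward elimination of uninformative proteins
  (VIP < 0.8 and |coefficient| < 0.1 by default) down to the minimal set
  that still classifies with AUC above the configured floor;
* ``volcano`` / ``mann_whitney`` — tissue-level differential expression
  (log2 ratio of group mean densities vs two-sided Mann–Whitney U);
* ``tissue_score`` — tissue-level aggregation of ROI prediction scores;
* ``pearson_per_protein`` and ``cutoff_sensitivity`` — the simple-correlation
  comparison and the CD45-cutoff robustness check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._base import BaseEstimator
from .config import RunConfig
from .dataset import ExpressionDataset
from .normalize import compartment_mean, log_standardize
from .pls import ComponentSelection, CvResult, NipalsPLS, cross_validate, select_components

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve by pairwise concordance.

    AUC = (#concordant pairs + 0.5 * #tied pairs) / (n1 * n0), computed
    exactly via midranks. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1 if labels.dtype != bool else labels
    pos = np.asarray(pos, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u1 = float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0
    return u1 / (n1 * n0)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U, p) with U = min(U1, U2).

    The p-value is exact (full null distribution) when n1*n2 <= 400 and the
    pooled sample is tie-free, otherwise a normal approximation with
    continuity and tie correction is used. Two identical samples (all ties,
    zero-variance null) are defined to give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    if np.ptp(pooled) == 0:  # all observations identical
        u = len(x) * len(y) / 2.0
        return u, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return u, min(float(res.pvalue), 1.0)


# ---------------------------------------------------------------------------
# PLS-DA estimator
# ---------------------------------------------------------------------------

class PLSDiscriminant(BaseEstimator):
    """PLS-DA: PLS1 regression on a 0/1 response, scored by ROC AUC.

    ``decision_function`` returns the continuous prediction score;
    ``predict`` thresholds it at 0.5 (the midpoint of the class codes).
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLSDiscriminant":
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
            raise ValueError("PLS-DA requires a binary 0/1 response with both classes")
        self.pls_ = NipalsPLS(n_components=self.n_components, scale=self.scale).fit(X, y)
        self.classes_ = np.array([0, 1])
        self.train_scores_ = self.pls_.predict(X)
        self.train_auc_ = auc(self.train_scores_, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_is_fitted("pls_")
        return self.pls_.predict(X)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0.5).astype(int)

    @property
    def vip_(self) -> np.ndarray:
        self._check_is_fitted("pls_")
        return self.pls_.vip_

    @property
    def coef_(self) -> np.ndarray:
        self._check_is_fitted("pls_")
        return self.pls_.coef_


# ---------------------------------------------------------------------------
# model reports
# ---------------------------------------------------------------------------

@dataclass
class PlsReport:
    """Everything a fitted micro-tumor PLS workflow produced.

    The estimator operates on ln(density + 1) values; ``predict`` applies
    that transform to new density rows (aligned by protein name) before
    scoring, so callers always work on the density scale.
    """

    model: NipalsPLS
    y_name: str
    features: list[str]
    compartment: str | None
    roi_ids: list[str]
    excluded_rois: list[str]
    dropped_columns: list[str]
    cv: CvResult
    selection: ComponentSelection
    actual: np.ndarray      # ln(y density + 1) on the modelled ROIs
    predicted: np.ndarray   # fitted values on the same scale
    vip_table: pd.DataFrame  # protein -> vip, coef (standardized), coef_original
    auc: float | None = None
    labels: pd.Series | None = None

    @property
    def a_star(self) -> int:
        return self.selection.a_star

    def predict(self, densities: pd.DataFrame) -> np.ndarray:
        X = np.log1p(densities[self.features].astype(float))
        return self.model.predict(X)

    def important(self, vip_cutoff: float = 1.0) -> pd.DataFrame:
        return self.vip_table[self.vip_table["vip"] > vip_cutoff].sort_values(
            "vip", ascending=False
        )

    def to_dict(self) -> dict:
        return {
            "y": self.y_name,
            "compartment": self.compartment,
            "n_rois": len(self.roi_ids),
            "excluded_rois": list(self.excluded_rois),
            "dropped_columns": list(self.dropped_columns),
            "a_star": self.a_star,
            "a_min_press": self.selection.a_min_press,
            "press": self.cv.press.tolist(),
            "q2": self.cv.q2.tolist(),
            "r2x_cum": self.cv.r2x_cum.tolist(),
            "r2y_cum": self.cv.r2y_cum.tolist(),
            "q2_at_a_star": float(self.cv.q2[self.a_star - 1]),
            "auc": self.auc,
            "vip": self.vip_table["vip"].to_dict(),
            "coef": self.vip_table["coef"].to_dict(),
            "intercept": float(self.model.intercept_),
        }


def _prepare_xy(
    ds: ExpressionDataset,
    compartment: str | None,
    cfg: RunConfig,
    y_protein: str | None = None,
) -> tuple[pd.DataFrame, pd.Series | None, list[str], list[str]]:
    """Common ROI/column scoping for PLS workflows (density scale).

    Subsets to the compartment, optionally pulls the dependent protein out of
    the predictor set, excludes ROIs whose dependent density is zero (signal
    indistinguishable from background) and removes control columns.
    Returns (X densities, y densities or None, excluded ROI ids, features).
    """
    ds.require_state("density")
    if compartment is not None:
        if "compartment" not in ds.roi_meta.columns:
            raise ValueError("compartment labels not assigned; run classify_rois first")
        keep = ds.roi_meta["compartment"] == compartment
        sub = ds.subset_rois(ds.roi_meta.index[keep])
    else:
        sub = ds
    X = sub.targets().astype(float)
    excluded: list[str] = []
    y = None
    if y_protein is not None:
        if y_protein not in X.columns:
            raise ValueError(f"dependent protein {y_protein!r} not in dataset")
        y = X[y_protein]
        if (y == 0).all():
            raise ValueError(f"dependent protein {y_protein!r} is zero in every ROI")
        excluded = list(y.index[y == 0])
        if excluded:
            logger.info("excluding %d ROI(s) with zero %s density: %s",
                        len(excluded), y_protein, excluded)
        keep_rows = y > 0
        X = X.loc[keep_rows]
        y = y.loc[keep_rows]
        X = X.drop(columns=[y_protein])
    if len(X) < cfg.min_rois:
        raise ValueError(
            f"only {len(X)} usable ROIs; at least {cfg.min_rois} required"
        )
    return X, y, excluded, list(X.columns)


def _drop_constant(X_log: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    varies = (X_log.max(axis=0) - X_log.min(axis=0)) > 0
    dropped = list(X_log.columns[~varies])
    if dropped:
        warnings.warn(f"dropping zero-variance predictor(s): {dropped}")
    return X_log.loc[:, varies], dropped


def _select_and_fit(
    X_log: pd.DataFrame, y_vec: np.ndarray, cfg: RunConfig
) -> tuple[NipalsPLS, CvResult, ComponentSelection]:
    n, p = X_log.shape
    a_max = max(1, min(cfg.a_max, n - 2, p))
    cv = cross_validate(X_log, y_vec, a_max)
    selection = select_components(cv, alpha=cfg.cv_alpha, n_perm=cfg.n_perm, seed=cfg.seed)
    model = NipalsPLS(n_components=selection.a_star).fit(X_log, y_vec)
    return model, cv, selection


def _vip_table(model: NipalsPLS, features: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vip": model.vip_,
            "coef": model.coef_,
            "coef_original": model.coef_original_,
        },
        index=pd.Index(features, name="protein"),
    )


def plsr_workflow(
    ds: ExpressionDataset, y_protein: str, compartment: str | None, cfg: RunConfig
) -> PlsReport:
    """PLS regression of one protein's density on all others in a compartment.

    Densities are ln(x+1)-transformed; the component count is chosen by
    leave-one-out PRESS with the van der Voet sign-permutation backtrack.
    """
    X, y, excluded, _ = _prepare_xy(ds, compartment, cfg, y_protein)
    X_log = np.log1p(X)
    X_log, dropped = _drop_constant(X_log)
    if X_log.shape[1] == 0:
        raise ValueError("no informative predictors remain")
    y_log = np.log1p(y.to_numpy(dtype=float))
    if np.ptp(y_log) == 0:
        raise ValueError(f"dependent protein {y_protein!r} has zero variance")
    model, cv, selection = _select_and_fit(X_log, y_log, cfg)
    report = PlsReport(
        model=model,
        y_name=y_protein,
        features=list(X_log.columns),
        compartment=compartment,
        roi_ids=list(X_log.index),
        excluded_rois=excluded,
        dropped_columns=dropped,
        cv=cv,
        selection=selection,
        actual=y_log,
        predicted=model.fitted_values(),
        vip_table=_vip_table(model, list(X_log.columns)),
    )
    logger.info("plsr_workflow(%s, %s): n=%d, A*=%d, Q2=%.3f",
                y_protein, compartment, len(report.roi_ids), report.a_star,
                cv.q2[report.a_star - 1])
    return report


def plsr_on_response(
    ds: ExpressionDataset,
    y_values: pd.Series,
    compartment: str | None,
    cfg: RunConfig,
    y_name: str = "response",
) -> PlsReport:
    """PLSR with an external continuous dependent variable per ROI
    (e.g. the mean immune-neighbor number of the ROI)."""
    X, _, _, _ = _prepare_xy(ds, compartment, cfg)
    y = y_values.reindex(X.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])
        raise ValueError(f"dependent values missing for ROI(s): {missing}")
    X_log, dropped = _drop_constant(np.log1p(X))
    y_vec = y.to_numpy(dtype=float)
    model, cv, selection = _select_and_fit(X_log, y_vec, cfg)
    return PlsReport(
        model=model,
        y_name=y_name,
        features=list(X_log.columns),
        compartment=compartment,
        roi_ids=list(X_log.index),
        excluded_rois=[],
        dropped_columns=dropped,
        cv=cv,
        selection=selection,
        actual=y_vec,
        predicted=model.fitted_values(),
        vip_table=_vip_table(model, list(X_log.columns)),
    )


def plsda_workflow(
    ds: ExpressionDataset,
    labels: pd.Series,
    compartment: str | None,
    cfg: RunConfig,
    features: list[str] | None = None,
) -> PlsReport:
    """PLS discriminant analysis of a binary ROI response label.

    ``labels`` maps ROI id -> {0, 1} (nonresponder / responder). The model is
    a PLS1 fit to the class code; classification quality is the ROC AUC of
    the in-sample prediction scores. ``features`` restricts the predictor set
    (used by backward elimination).
    """
    X, _, _, _ = _prepare_xy(ds, compartment, cfg)
    y = labels.reindex(X.index)
    if y.isna().any():
        raise ValueError(f"labels missing for ROI(s): {list(y.index[y.isna()])}")
    y_vec = y.to_numpy(dtype=float)
    counts = pd.Series(y_vec).value_counts()
    if len(counts) < 2:
        raise ValueError("PLS-DA requires both classes present")
    if counts.min() < 3:
        raise ValueError(f"each class needs >= 3 ROIs, got {counts.to_dict()}")
    if features is not None:
        missing = [f for f in features if f not in X.columns]
        if missing:
            raise ValueError(f"unknown feature(s): {missing}")
        X = X[list(features)]
    X_log, dropped = _drop_constant(np.log1p(X))
    model, cv, selection = _select_and_fit(X_log, y_vec, cfg)
    scores = model.fitted_values()
    report = PlsReport(
        model=model,
        y_name="response",
        features=list(X_log.columns),
        compartment=compartment,
        roi_ids=list(X_log.index),
        excluded_rois=[],
        dropped_columns=dropped,
        cv=cv,
        selection=selection,
        actual=y_vec,
        predicted=scores,
        vip_table=_vip_table(model, list(X_log.columns)),
        auc=auc(scores, y_vec.astype(int)),
        labels=pd.Series(y_vec, index=X_log.index),
    )
    logger.info("plsda_workflow(%s): n=%d, A*=%d, AUC=%.3f",
                compartment, len(report.roi_ids), report.a_star, report.auc)
    return report


# ---------------------------------------------------------------------------
# backward variable elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationStep:
    features: list[str]
    a_star: int
    auc: float
    vip: pd.Series
    coef: pd.Series
    removed: list[str]


@dataclass
class EliminationTrace:
    """Record of the backward elimination towards a minimal predictor set."""

    steps: list[EliminationStep]
    final: PlsReport
    floor_unreachable: bool = False

    @property
    def final_features(self) -> list[str]:
        return self.final.features

    @property
    def removed_per_step(self) -> list[list[str]]:
        return [s.removed for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "floor_unreachable": self.floor_unreachable,
            "final_features": self.final_features,
            "final_auc": self.final.auc,
            "steps": [
                {
                    "features": s.features,
                    "a_star": s.a_star,
                    "auc": s.auc,
                    "vip": s.vip.to_dict(),
                    "coef": s.coef.to_dict(),
                    "removed": s.removed,
                }
                for s in self.steps
            ],
        }


def eliminate_variables(
    ds: ExpressionDataset,
    labels: pd.Series,
    cfg: RunConfig,
    compartment: str | None = None,
    one_at_a_time: bool = False,
) -> EliminationTrace:
    """Iteratively remove low-importance proteins from a PLS-DA model.

    At each step the proteins with VIP < ``cfg.vip_drop`` AND standardized
    |coefficient| < ``cfg.coef_drop`` are removed together (or the single
    worst one if ``one_at_a_time``) and the model is refit. Elimination stops
    when no protein qualifies, when removal would empty the model, or when
    the refit AUC falls to or below ``cfg.auc_floor`` (the previous model is
    kept). If even the full model cannot exceed the floor the trace is
    flagged ``floor_unreachable`` and the best model seen is returned.
    """
    report = plsda_workflow(ds, labels, compartment, cfg)
    steps: list[EliminationStep] = []
    if report.auc <= cfg.auc_floor:
        steps.append(
            EliminationStep(
                features=report.features,
                a_star=report.a_star,
                auc=report.auc,
                vip=report.vip_table["vip"],
                coef=report.vip_table["coef"],
                removed=[],
            )
        )
        logger.info("eliminate_variables: initial AUC %.3f <= floor %.2f",
                    report.auc, cfg.auc_floor)
        return EliminationTrace(steps=steps, final=report, floor_unreachable=True)

    while True:
        vip_s = report.vip_table["vip"]
        coef_s = report.vip_table["coef"]
        removable = list(
            vip_s.index[(vip_s < cfg.vip_drop) & (coef_s.abs() < cfg.coef_drop)]
        )
        if one_at_a_time and removable:
            removable = [vip_s.loc[removable].idxmin()]
        if not removable or len(removable) >= len(report.features):
            steps.append(
                EliminationStep(
                    features=report.features,
                    a_star=report.a_star,
                    auc=report.auc,
                    vip=vip_s,
                    coef=coef_s,
                    removed=[],
                )
            )
            break
        remaining = [f for f in report.features if f not in removable]
        candidate = plsda_workflow(ds, labels, compartment, cfg, features=remaining)
        if candidate.auc <= cfg.auc_floor:
            # keep the current model; removal would break classification
            steps.append(
                EliminationStep(
                    features=report.features,
                    a_star=report.a_star,
                    auc=report.auc,
                    vip=vip_s,
                    coef=coef_s,
                    removed=[],
                )
            )
            logger.info("eliminate_variables: stopping, removal would drop AUC to %.3f",
                        candidate.auc)
            break
        steps.append(
            EliminationStep(
                features=report.features,
                a_star=report.a_star,
                auc=report.auc,
                vip=vip_s,
                coef=coef_s,
                removed=removable,
            )
        )
        report = candidate
    logger.info("eliminate_variables: final set %s (AUC %.3f)",
                report.features, report.auc)
    return EliminationTrace(steps=steps, final=report, floor_unreachable=False)


# ---------------------------------------------------------------------------
# differential (volcano) analysis
# ---------------------------------------------------------------------------

@dataclass
class DifferentialTable:
    """Per-protein effect sizes and Mann–Whitney statistics.

    ``effect`` is the log2 ratio of group mean densities (per-tissue means),
    so the conventional cutoff |effect| > 1 marks a 2-fold change.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    effect_definition: str = "log2(mean density group_a / mean density group_b), per-tissue means"

    def hits(self, effect_cutoff: float = 1.0, p_cutoff: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t["effect"].abs() > effect_cutoff) & (t["p"] < p_cutoff)]


def volcano(
    ds: ExpressionDataset,
    groups: pd.Series,
    compartment: str,
    group_a: str | None = None,
    group_b: str | None = None,
) -> DifferentialTable:
    """Tissue-level differential expression between two response groups.

    ``groups`` maps tissue_id -> group label. Per-tissue compartment mean
    densities are compared protein by protein: the effect size is the log2
    ratio of group means and the p-value a two-sided Mann–Whitney U test on
    the per-tissue values. A zero group mean yields a ±inf effect sentinel
    with a warning.
    """
    means = compartment_mean(ds, compartment)
    groups = groups.reindex(means.index)
    present = groups.dropna().unique().tolist()
    if group_a is None or group_b is None:
        if len(present) != 2:
            raise ValueError(
                f"need exactly 2 groups (or pass group_a/group_b); found {present}"
            )
        group_a, group_b = sorted(present)
    in_a = means.loc[groups == group_a]
    in_b = means.loc[groups == group_b]
    if len(in_a) < 2 or len(in_b) < 2:
        raise ValueError(
            f"each group needs >= 2 tissues; got {len(in_a)} vs {len(in_b)}"
        )
    rows = []
    for protein in means.columns:
        a_vals = in_a[protein].to_numpy(dtype=float)
        b_vals = in_b[protein].to_numpy(dtype=float)
        ma, mb = a_vals.mean(), b_vals.mean()
        if ma > 0 and mb > 0:
            effect = float(np.log2(ma / mb))
        else:
            warnings.warn(f"zero group mean for {protein!r}; effect set to ±inf")
            effect = np.inf if ma > mb else (-np.inf if mb > ma else 0.0)
        u, p = mann_whitney(a_vals, b_vals)
        rows.append((protein, effect, u, p))
    table = pd.DataFrame(rows, columns=["protein", "effect", "U", "p"]).set_index("protein")
    table["sig_p05"] = table["p"] < 0.05
    table["sig_p10"] = table["p"] < 0.10
    table["large_effect"] = table["effect"].abs() > 1.0
    return DifferentialTable(
        table=table, group_a=group_a, group_b=group_b, n_a=len(in_a), n_b=len(in_b)
    )


# ---------------------------------------------------------------------------
# tissue-level scoring and robustness checks
# ---------------------------------------------------------------------------

@dataclass
class TissueScoreResult:
    scores: pd.Series        # tissue_id -> mean ROI prediction score
    labels: pd.Series        # tissue_id -> 0/1
    auc: float
    u: float
    p: float


def tissue_score(
    report: PlsReport, ds: ExpressionDataset, tissue_labels: pd.Series
) -> TissueScoreResult:
    """Aggregate ROI prediction scores to tissues and test group separation."""
    roi_scores = pd.Series(report.predicted, index=report.roi_ids)
    tissues = ds.roi_meta.loc[report.roi_ids, "tissue_id"]
    per_tissue = roi_scores.groupby(tissues).mean()
    labels = tissue_labels.reindex(per_tissue.index)
    missing = list(labels.index[labels.isna()])
    if missing:
        warnings.warn(f"tissues without labels omitted: {missing}")
        per_tissue = per_tissue.drop(index=missing)
        labels = labels.drop(index=missing)
    y = labels.astype(int).to_numpy()
    value = auc(per_tissue.to_numpy(), y)
    u, p = mann_whitney(per_tissue.to_numpy()[y == 1], per_tissue.to_numpy()[y == 0])
    return TissueScoreResult(scores=per_tissue, labels=labels.astype(int), auc=value, u=u, p=p)


def pearson_per_protein(
    ds: ExpressionDataset, y_protein: str, compartment: str | None, cfg: RunConfig
) -> pd.Series:
    """Pearson r between each protein's log density and the dependent
    protein's log density over the in-scope ROIs (zero-variance -> NaN)."""
    X, y, _, _ = _prepare_xy(ds, compartment, cfg, y_protein)
    X_log = np.log1p(X)
    y_log = np.log1p(y.to_numpy(dtype=float))
    out = {}
    yc = y_log - y_log.mean()
    y_ss = float(yc @ yc)
    for protein in X_log.columns:
        xv = X_log[protein].to_numpy(dtype=float)
        xc = xv - xv.mean()
        x_ss = float(xc @ xc)
        if x_ss == 0 or y_ss == 0:
            warnings.warn(f"zero variance for {protein!r}; correlation undefined")
            out[protein] = np.nan
            continue
        out[protein] = float(xc @ yc) / np.sqrt(x_ss * y_ss)
    return pd.Series(out, name=f"pearson_r_vs_{y_protein}")


@dataclass
class SensitivityReport:
    top_sets: dict[float, list[str]]   # cutoff -> proteins with VIP > vip_stable
    skipped: list[float]
    stable: bool
    vip_threshold: float


def cutoff_sensitivity(
    ds: ExpressionDataset,
    y_protein: str,
    cfg: RunConfig,
    cutoffs: tuple[float, ...] = (0.20, 0.25, 0.30),
) -> SensitivityReport:
    """Re-run the PLSR workflow at several CD45 cutoffs and compare the
    top-importance protein sets (VIP > ``cfg.vip_stable``)."""
    from .normalize import classify_rois  # local import to avoid cycle at module load

    top_sets: dict[float, list[str]] = {}
    skipped: list[float] = []
    for cutoff in cutoffs:
        cls = classify_rois(ds, method="threshold", cutoff=cutoff)
        labelled = ds.with_compartments(cls.labels)
        try:
            report = plsr_workflow(labelled, y_protein, "immune_rich", cfg)
        except ValueError as exc:
            warnings.warn(f"cutoff {cutoff} skipped: {exc}")
            skipped.append(cutoff)
            continue
        vips = report.vip_table["vip"]
        top_sets[cutoff] = sorted(vips.index[vips > cfg.vip_stable])
    sets = list(top_sets.values())
    stable = len(sets) > 0 and all(s == sets[0] for s in sets)
    return SensitivityReport(
        top_sets=top_sets, skipped=skipped, stable=stable, vip_threshold=cfg.vip_stable
    )
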