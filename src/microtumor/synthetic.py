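"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume, with
the ground truth recorded so recovery can be tested end to end:

* ROI count tables: per-ROI latent factors drive lognormal count densities
  with a planted linear link between the informative predictor proteins and
  one dependent protein; the clean densities are corrupted exactly the way
  the normalization chain can undo — multiplied by sampled mask areas and a
  per-batch lognormal ERCC scale factor, plus Poisson isotype background —
  and ERCC / IgG control columns are emitted alongside. Densities are on a
  counts-per-mm² scale (mask areas in mm²) so the pipeline's ln(x+1)
  transform acts as a genuine log transform on them.
* Response cohorts: the same model plus a class-dependent shift (δ, in
  log-scale sd units) on a chosen set of discriminant proteins.
* Cell maps: homogeneous Poisson or Thomas cluster point processes for
  immune cells, independent Poisson for the rest, at matched intensities.
* Two-channel images: Gaussian spots at the cell centroids (CD45 channel
  bright only for immune cells) with additive Gaussian noise.
* Signature matrices: category-shifted Gaussian gene expression for the
  molecular responder / nonresponder clustering.

Every generator is a pure function of its configuration and seed. Default
cohort sizes mirror a realistic study: 14 tissues with up to 16 ROIs each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PanelConfig
from .dataset import ExpressionDataset


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, serializable to JSON."""

    seed: int
    loadings: list[list[float]] | None = None        # protein x K
    q_true: list[float] | None = None                # K
    mu: list[float] | None = None                    # per-protein log-density mean
    informative: list[str] = field(default_factory=list)
    discriminant: list[str] = field(default_factory=list)
    coef_signs: dict[str, int] = field(default_factory=dict)
    delta: float | None = None
    ercc_batch_factors: list[float] | None = None
    isotype_background_rate: float | None = None
    point_process: dict | None = None
    signature_means: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RoiSimConfig:
    """Configuration of the ROI count generator.

    ``n_informative`` proteins carry nonzero latent loadings linking them to
    the dependent protein; the rest are pure noise. ``noise_sd`` is the
    residual log-density sd around the latent structure.
    """

    n_roi: int = 60
    n_proteins: int = 20
    n_latent: int = 1
    n_informative: int = 5
    noise_sd: float = 0.3
    y_protein: str = "CD8A"
    y_noise_sd: float = 0.1
    loading_scale: float = 1.0
    mu_log_density: float = 9.8      # baseline ln density (~18,000 counts/mm²)
    mu_log_density_sd: float = 0.5
    n_tissues: int = 14
    max_rois_per_tissue: int = 16
    mean_mask_area: float = 0.025    # mm² (25,000 µm²)
    mask_area_cv: float = 0.3
    n_batches: int = 3
    ercc_batch_sd: float = 0.3       # lognormal sd of batch scale factors
    isotype_background_rate: float = 200.0  # background counts per mm²
    n_isotype: int = 2
    ercc_levels: tuple[float, ...] = (32.0, 128.0, 512.0, 2048.0, 8192.0)
    frac_rich: float = 0.5
    rich_cd45: tuple[float, float] = (0.3, 0.7)
    poor_cd45: tuple[float, float] = (0.0, 0.2)

    def __post_init__(self) -> None:
        if self.n_roi < 10:
            raise ValueError("n_roi must be >= 10")
        if self.n_proteins < 5:
            raise ValueError("n_proteins must be >= 5")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative cannot exceed n_proteins")
        if self.noise_sd < 0 or self.y_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


def default_panel(config: RoiSimConfig) -> PanelConfig:
    targets = [f"P{j:02d}" for j in range(1, config.n_proteins + 1)] + [config.y_protein]
    isotypes = [f"IgG{k}" for k in range(1, config.n_isotype + 1)]
    erccs = [f"ERCC{k}" for k in range(1, len(config.ercc_levels) + 1)]
    iso_map = {t: isotypes[i % len(isotypes)] for i, t in enumerate(targets)}
    return PanelConfig(
        targets=targets,
        isotype_controls=isotypes,
        isotype_map=iso_map,
        ercc_controls=erccs,
    )


def _assign_tissues(n_roi: int, config: RoiSimConfig) -> list[str]:
    per = min(config.max_rois_per_tissue, int(np.ceil(n_roi / config.n_tissues)))
    tissues = []
    t = 0
    while len(tissues) < n_roi:
        take = min(per, n_roi - len(tissues))
        tissues.extend([f"T{t + 1:02d}"] * take)
        t += 1
    return tissues[:n_roi]


def _simulate_log_densities(
    config: RoiSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Latent-factor log densities for predictors and the dependent protein."""
    p, K = config.n_proteins, config.n_latent
    predictors = [f"P{j:02d}" for j in range(1, p + 1)]
    informative = predictors[: config.n_informative]
    loadings = np.zeros((p, K))
    for idx in range(config.n_informative):
        row = rng.uniform(0.5, 1.0, size=K) * rng.choice((-1.0, 1.0), size=K)
        loadings[idx] = config.loading_scale * row
    q_true = rng.uniform(0.5, 1.0, size=K)
    mu = rng.normal(config.mu_log_density, config.mu_log_density_sd, size=p)
    t = rng.standard_normal((config.n_roi, K))
    eps = rng.normal(0.0, config.noise_sd, size=(config.n_roi, p))
    log_x = mu[None, :] + t @ loadings.T + eps
    mu_y = config.mu_log_density
    log_y = mu_y + t @ q_true + rng.normal(0.0, config.y_noise_sd, size=config.n_roi)
    frame = pd.DataFrame(log_x, columns=predictors)
    frame[config.y_protein] = log_y
    return frame, loadings, q_true, mu, informative


def _corrupt_to_counts(
    log_density: pd.DataFrame,
    config: RoiSimConfig,
    rng: np.random.Generator,
    panel: PanelConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Densities -> raw counts with area, batch-factor and background layers."""
    n = len(log_density)
    density = np.exp(log_density.to_numpy())
    area = config.mean_mask_area * rng.lognormal(
        mean=-0.5 * np.log(1 + config.mask_area_cv**2),
        sigma=np.sqrt(np.log(1 + config.mask_area_cv**2)),
        size=n,
    )
    batch_of_roi = rng.integers(0, config.n_batches, size=n)
    batch_factors = rng.lognormal(mean=0.0, sigma=config.ercc_batch_sd, size=config.n_batches)
    factor = batch_factors[batch_of_roi]
    # normalize to per-ROI geometric mean 1 so the ERCC step inverts the
    # corruption exactly (the global scale is unidentifiable anyway)
    factor = factor / np.exp(np.mean(np.log(factor)))
    bg_mean = config.isotype_background_rate * area
    target_bg = rng.poisson(bg_mean[:, None], size=(n, density.shape[1]))
    counts = (density * area[:, None] + target_bg) * factor[:, None]
    matrix = pd.DataFrame(counts, columns=log_density.columns)
    for iso in panel.isotype_controls:
        matrix[iso] = rng.poisson(bg_mean) * factor
    for level, ercc in zip(config.ercc_levels, panel.ercc_controls):
        matrix[ercc] = level * factor
    meta = pd.DataFrame({"mask_area": area, "batch": batch_of_roi})
    return matrix, meta, batch_factors, factor


def gen_roi_counts(
    config: RoiSimConfig | None = None, seed: int = 0
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a raw ROI count table with planted predictor-response structure.

    Returns the raw-state dataset (targets + IgG + ERCC columns, per-ROI mask
    area and CD45 fraction) and the :class:`SyntheticTruth` describing the
    planted loadings, informative set and corruption parameters.
    """
    config = config or RoiSimConfig()
    rng = np.random.default_rng(seed)
    panel = default_panel(config)
    log_density, loadings, q_true, mu, informative = _simulate_log_densities(config, rng)
    matrix, meta, batch_factors, _ = _corrupt_to_counts(log_density, config, rng, panel)

    n = config.n_roi
    n_rich = int(round(config.frac_rich * n))
    rich = np.zeros(n, dtype=bool)
    rich[rng.choice(n, size=n_rich, replace=False)] = True
    cd45 = np.where(
        rich,
        rng.uniform(*config.rich_cd45, size=n),
        rng.uniform(*config.poor_cd45, size=n),
    )
    roi_ids = [f"ROI{i + 1:03d}" for i in range(n)]
    matrix.index = pd.Index(roi_ids, name="roi_id")
    roi_meta = pd.DataFrame(
        {
            "tissue_id": _assign_tissues(n, config),
            "mask_area": meta["mask_area"].to_numpy(),
            "cd45_fraction": cd45,
        },
        index=matrix.index,
    )
    ds = ExpressionDataset(
        matrix=matrix,
        roi_meta=roi_meta,
        state="raw",
        control_columns=panel.control_columns,
    )
    coef_signs = {
        prot: int(np.sign(loadings[i] @ q_true))
        for i, prot in enumerate(informative)
    }
    truth = SyntheticTruth(
        seed=seed,
        loadings=loadings.tolist(),
        q_true=q_true.tolist(),
        mu=mu.tolist(),
        informative=informative,
        coef_signs=coef_signs,
        ercc_batch_factors=batch_factors.tolist(),
        isotype_background_rate=config.isotype_background_rate,
    )
    return ds, truth


@dataclass
class ResponseSimConfig:
    """Configuration of the binary-response cohort generator."""

    n_per_class: tuple[int, int] = (40, 40)
    n_discriminant: int = 2
    n_noise: int = 10
    delta: float = 2.0              # class shift in log-density sd units
    base: RoiSimConfig | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if min(self.n_per_class) < 5:
            raise ValueError("both class sizes must be >= 5")

    def base_config(self) -> RoiSimConfig:
        """The ROI generator configuration backing this cohort (for panels)."""
        if self.base is not None:
            return self.base
        n = sum(self.n_per_class)
        p = self.n_discriminant + self.n_noise
        return RoiSimConfig(
            n_roi=n, n_proteins=p, n_informative=0, noise_sd=1.0, frac_rich=1.0,
            n_tissues=max(2, min(14, n // 5)),
        )


def gen_response_cohort(
    config: ResponseSimConfig | None = None, seed: int = 0
) -> tuple[ExpressionDataset, pd.Series, SyntheticTruth]:
    """Generate a raw cohort whose discriminant proteins separate two classes.

    Class 1 (responders) ROIs have the discriminant proteins' log densities
    shifted by +δ/2 marginal sd and class 0 by −δ/2. Labels are returned per
    ROI (0/1), grouped so each tissue is single-class.
    """
    config = config or ResponseSimConfig()
    n0, n1 = config.n_per_class
    n = n0 + n1
    p = config.n_discriminant + config.n_noise
    base = config.base_config()
    if base.n_roi != n or base.n_proteins != p:
        raise ValueError("base config dimensions inconsistent with class sizes")
    rng = np.random.default_rng(seed)
    panel = default_panel(base)
    log_density, loadings, q_true, mu, _ = _simulate_log_densities(base, rng)

    predictors = [f"P{j:02d}" for j in range(1, p + 1)]
    discriminant = predictors[: config.n_discriminant]
    # interleave tissues across classes: first tissues class 0, rest class 1
    tissue_ids = _assign_tissues(n, base)
    labels_arr = np.array([0] * n0 + [1] * n1)
    marginal_sd = np.sqrt((loadings**2).sum(axis=1) + base.noise_sd**2)
    for prot in discriminant:
        j = predictors.index(prot)
        shift = config.delta * marginal_sd[j]
        log_density[prot] = log_density[prot] + np.where(labels_arr == 1, 0.5, -0.5) * shift

    matrix, meta, batch_factors, _ = _corrupt_to_counts(log_density, base, rng, panel)
    roi_ids = [f"ROI{i + 1:03d}" for i in range(n)]
    matrix.index = pd.Index(roi_ids, name="roi_id")
    cd45 = rng.uniform(*base.rich_cd45, size=n)
    roi_meta = pd.DataFrame(
        {"tissue_id": tissue_ids, "mask_area": meta["mask_area"].to_numpy(),
         "cd45_fraction": cd45},
        index=matrix.index,
    )
    ds = ExpressionDataset(
        matrix=matrix, roi_meta=roi_meta, state="raw",
        control_columns=panel.control_columns,
    )
    labels = pd.Series(labels_arr, index=matrix.index, name="response")
    truth = SyntheticTruth(
        seed=seed,
        loadings=loadings.tolist(),
        q_true=q_true.tolist(),
        mu=mu.tolist(),
        discriminant=discriminant,
        delta=config.delta,
        ercc_batch_factors=batch_factors.tolist(),
        isotype_background_rate=base.isotype_background_rate,
    )
    return ds, labels, truth


def gen_cell_map(
    kind: str = "poisson",
    window: tuple[float, float] = (1000.0, 1000.0),
    intensity: float = 2e-4,
    cluster_sd: float = 20.0,
    offspring_mean: float = 10.0,
    immune_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cell map with immune cells from a spatial point process.

    ``kind='poisson'``: homogeneous Poisson immune cells at ``intensity``
    (cells per unit area). ``kind='thomas'``: Thomas cluster process with
    parent intensity ``intensity / offspring_mean``, Poisson(offspring_mean)
    offspring displaced by an isotropic Gaussian of sd ``cluster_sd``, so the
    expected immune intensity matches the Poisson case. Non-immune cells are
    an independent Poisson process sized by ``immune_fraction``. Synthetic
    CD45/nuclei intensities and morphology columns are attached so the table
    is drop-in compatible with the classification and neighbor operations.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    w, h = window
    if w <= 0 or h <= 0:
        raise ValueError("window area must be positive")
    if cluster_sd < 0 or offspring_mean <= 0:
        raise ValueError("cluster parameters must be positive")
    if not 0 < immune_fraction <= 1:
        raise ValueError("immune_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    area = w * h
    if kind == "poisson":
        n_immune = rng.poisson(intensity * area)
        ix = rng.uniform(0, w, size=n_immune)
        iy = rng.uniform(0, h, size=n_immune)
    elif kind == "thomas":
        pad = 4 * cluster_sd
        parent_area = (w + 2 * pad) * (h + 2 * pad)
        kappa = intensity / offspring_mean
        n_parents = rng.poisson(kappa * parent_area)
        px = rng.uniform(-pad, w + pad, size=n_parents)
        py = rng.uniform(-pad, h + pad, size=n_parents)
        xs, ys = [], []
        for cx, cy in zip(px, py):
            n_off = rng.poisson(offspring_mean)
            xs.append(cx + rng.normal(0, cluster_sd, size=n_off))
            ys.append(cy + rng.normal(0, cluster_sd, size=n_off))
        ix = np.concatenate(xs) if xs else np.empty(0)
        iy = np.concatenate(ys) if ys else np.empty(0)
        inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        ix, iy = ix[inside], iy[inside]
    else:
        raise ValueError(f"unknown point process kind {kind!r}")
    other_intensity = intensity * (1.0 / immune_fraction - 1.0)
    n_other = rng.poisson(other_intensity * area)
    ox = rng.uniform(0, w, size=n_other)
    oy = rng.uniform(0, h, size=n_other)

    n_immune = len(ix)
    x = np.concatenate([ix, ox])
    y = np.concatenate([iy, oy])
    immune = np.concatenate([np.ones(n_immune, bool), np.zeros(n_other, bool)])
    n_total = len(x)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_total + 1),
            "x": x,
            "y": y,
            "area": rng.normal(120.0, 20.0, size=n_total).clip(40.0),
            "eccentricity": rng.uniform(0.1, 0.8, size=n_total),
            "solidity": rng.uniform(0.85, 1.0, size=n_total),
            "mean_nuclei": rng.normal(1500.0, 150.0, size=n_total),
            "mean_cd45": np.where(
                immune,
                rng.normal(2000.0, 100.0, size=n_total),
                rng.normal(200.0, 100.0, size=n_total),
            ).clip(0.0),
            "immune": immune,
        }
    )
    return cells


def gen_image(
    cells: pd.DataFrame,
    psf_sd: float = 3.0,
    noise_sd: float = 0.0,
    size: tuple[int, int] = (256, 256),
    amplitude: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a two-channel (nuclei, CD45) raster of Gaussian spots.

    Every cell gets a nuclei spot; only immune cells get a CD45 spot.
    Raises if any centroid falls outside the image.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    img = np.zeros((2, h, w))
    if len(cells):
        x = cells["x"].to_numpy(dtype=float)
        y = cells["y"].to_numpy(dtype=float)
        if ((x < 0) | (x >= w) | (y < 0) | (y >= h)).any():
            raise ValueError("cell centroid(s) outside image window")
        ys = np.arange(h)
        xs = np.arange(w)
        immune = cells["immune"].to_numpy(dtype=bool) if "immune" in cells else np.zeros(len(x), bool)
        gy = np.exp(-((ys[None, :] - y[:, None]) ** 2) / (2 * psf_sd**2))
        gx = np.exp(-((xs[None, :] - x[:, None]) ** 2) / (2 * psf_sd**2))
        img[0] = amplitude * np.einsum("ni,nj->ij", gy, gx)
        if immune.any():
            img[1] = amplitude * np.einsum("ni,nj->ij", gy[immune], gx[immune])
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


def gen_signature_matrix(
    n_mr: int,
    n_mnr: int,
    genes: dict[str, str] | None = None,
    delta: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a sample x gene signature matrix with planted mR/mNR clusters.

    mR samples get +δ/2 on T-cell/IFN-γ genes and −δ/2 on cell-cycle genes
    (in sd units), mNR samples the mirror image, plus unit-sd Gaussian noise.
    """
    if n_mr < 1 or n_mnr < 1:
        raise ValueError("both group sizes must be >= 1")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    genes = genes or default_signature_genes()
    categories = set(genes.values())
    for cat in ("t_cell_ifng", "cell_cycle"):
        if cat not in categories:
            raise ValueError(f"gene category {cat!r} is empty")
    rng = np.random.default_rng(seed)
    n = n_mr + n_mnr
    labels = pd.Series(
        ["mR"] * n_mr + ["mNR"] * n_mnr,
        index=[f"S{i + 1:02d}" for i in range(n)],
        name="true_label",
    )
    shift_sign = {"t_cell_ifng": 1.0, "cell_cycle": -1.0}
    data = {}
    for gene, cat in genes.items():
        mu = np.where(labels == "mR", 0.5, -0.5) * delta * shift_sign[cat]
        data[gene] = mu + rng.standard_normal(n)
    expr = pd.DataFrame(data, index=labels.index)
    truth = SyntheticTruth(
        seed=seed,
        delta=delta,
        signature_means={
            "mR": {"t_cell_ifng": delta / 2, "cell_cycle": -delta / 2},
            "mNR": {"t_cell_ifng": -delta / 2, "cell_cycle": delta / 2},
        },
    )
    return expr, labels, truth


def default_signature_genes() -> dict[str, str]:
    """A synthetic 23-gene signature: 13 T-cell/IFN-γ and 10 cell-cycle genes.

    Stand-in gene list for the response signature (the real signature derives
    from a prior trial and is supplied by the user as config); names follow
    the biology of the two categories.
    """
    t_cell = [
        "CD8A", "CD3E", "GZMA", "GZMB", "PRF1", "IFNG", "STAT1", "CXCL9",
        "CXCL10", "IDO1", "HLA-DRA", "TBX21", "LAG3",
    ]
    cycle = [
        "MKI67", "CCNB1", "CDK1", "TOP2A", "BUB1", "AURKA", "PLK1", "E2F1",
        "FOXM1", "CCNE1",
    ]
    genes = {g: "t_cell_ifng" for g in t_cell}
    genes.update({g: "cell_cycle" for g in cycle})
    return genes
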