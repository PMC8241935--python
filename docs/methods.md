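# Methods

`microtumor` analyzes spatially resolved protein profiling of tumor tissue
under the "micro-tumor" premise: each profiled region of interest (ROI) is a
small, deeply characterized tumor sample with its own local therapy
response, so a cohort of a dozen tissues yields tens to hundreds of
modelling units. This note documents the models, the numerical conventions,
the synthetic-data generator, and the known limitations.

## Count processing

Raw antibody-barcode counts are processed in a fixed, state-checked order:

1. **ERCC normalization.** Each ROI i is divided by
   `f_i = geomean(ERCC_i) / geomean over ROIs of geomean(ERCC)`,
   where `geomean(ERCC_i)` is the geometric mean of ROI i's spike-in
   control counts. The geometric mean is used because the spike-ins are
   subject to multiplicative (batch/system) scale noise. After the step all
   ROIs share the same ERCC geometric mean. The anchoring to the grand
   geometric mean keeps counts on a familiar scale; as a consequence the
   chain is scale-*equivariant*: multiplying every count (targets and
   controls) by c multiplies every density by exactly c, and all
   downstream log-scale analyses (which standardize per protein) are
   unaffected.
2. **Isotype background subtraction.** For each target,
   `count ← max(0, count − background)` where the background is the matched
   IgG isotype control count in the same ROI (the arithmetic mean when a
   target maps to several species-matched controls). The zero floor
   prevents negative counts; subtraction is monotone and non-negative by
   construction.
3. **Area normalization.** Counts are divided by the UV-illuminated mask
   area, giving a count density comparable across differently sized ROIs.
   Mask areas are carried in whatever squared-length unit the input uses;
   the synthetic generators use mm², which puts typical densities at
   O(10³–10⁴) counts/mm² so that the later ln(x+1) transform behaves as a
   genuine log transform (at densities ≪ 1 the transform would be nearly
   the identity and the lognormal modelling assumption would not engage).

For tissue-level comparisons, densities are averaged per tissue within a
compartment (unweighted over ROIs — the densities are already
area-normalized; an area-weighted variant is available). For modelling,
densities are ln(x+1)-transformed and standardized per protein (sample sd,
ddof = 1); constant columns are dropped with a warning and recorded.

**Compartment classification.** ROIs are labeled immune-rich/immune-poor
from their image-derived CD45+ cell fraction, either by a fixed cutoff
(default 0.25, rich strictly above — the boundary value is poor) or by a
1-D Ward 2-cluster split that also reports its derived cutoff (midpoint
between the facing extremes of the two clusters).

## PLS engine

The core model is single-response partial least squares fitted by NIPALS,
written from first principles so every convention is explicit:

- X columns and y are centered and unit-variance scaled before fitting;
  coefficients are reported on both the standardized and the original scale.
- Per component: `w = X'y/‖X'y‖`, `t = Xw`, `p = X't/(t't)`, `q = y't/(t't)`,
  then X and y are deflated. Scores are mutually orthogonal; weights have
  unit norm. Coefficients are `b = W(P'W)⁻¹q`.
- **VIP**: `VIP_j = sqrt(p · Σ_a SS_a w_aj² / Σ_a SS_a)` with
  `SS_a = q_a² t_a't_a`, so mean(VIP²) = 1 exactly; VIP > 1 marks a
  predictor as important.
- **Cross-validation**: leave-one-out, refitting and *re-standardizing
  inside every fold* so no scaling information leaks from the held-out ROI.
  PRESS(A) sums squared prediction errors on the original y scale;
  Q²(A) = 1 − PRESS(A)/Σ(yᵢ−ȳ)² with the full-sample corrected sum of
  squares in the denominator. If deflation exhausts the X'y covariance in a
  fold (noiseless low-rank data), the fold's model stops early and carries
  its last prediction forward.
- **Component selection**: A_min = argmin PRESS; each smaller A is compared
  to A_min by the van der Voet statistic Σᵢ(e²ᵢ,A − e²ᵢ,A_min) with a
  Monte-Carlo sign-permutation null (default 2000 draws, seeded; α = 0.10).
  A* is the smallest A not significantly worse than A_min — the parsimonious
  choice. Both A* and A_min are reported.

Numerical edge cases: ‖X'y‖ below 1e−12 raises "no covariance remaining";
a singular P'W raises rather than being silently regularized; zero-variance
X columns are rejected in `fit` (detected by exact constancy, not a float
sd threshold) and dropped per fold in cross-validation.

## Micro-tumor analyses

- **PLSR workflows** regress one protein's log density (e.g. CD8A, Ki67) or
  an external ROI-level readout (e.g. mean immune-neighbor number) on all
  other proteins within one compartment. ROIs whose dependent density is
  zero are excluded (signal indistinguishable from background) and logged;
  control columns never enter X. At least 6 usable ROIs are required.
- **PLS-DA** codes the binary response as y ∈ {0, 1} and fits the same PLS1
  engine; classification quality is the ROC AUC of the prediction scores,
  computed exactly by midranks (ties contribute 0.5 per pair).
- **Backward elimination** removes, at each step, every protein with
  VIP < 0.8 AND |standardized coefficient| < 0.1, refits, and stops when no
  protein qualifies or when removal would push the AUC to or below the 0.90
  floor (the previous model is kept). Batch removal matches the idea of
  successively shrinking predictor subsets; one-at-a-time removal is
  available as an option. If even the full model cannot beat the floor the
  trace is flagged `floor_unreachable` — there is no minimal predictor set
  to report.
- **Differential (volcano) statistics** compare per-tissue compartment mean
  densities between two groups. The effect size is the log₂ ratio of group
  means — so the conventional |effect| > 1 cutoff means a 2-fold change —
  and this definition is recorded in the output metadata because "effect
  size" is not standardized across tools. The test is a two-sided
  Mann–Whitney U with U reported as min(U₁, U₂); the p-value is exact (full
  null distribution) when n₁·n₂ ≤ 400 and the pooled data are tie-free,
  otherwise a normal approximation with continuity and tie correction.
  Two identical samples are defined to give p = 1. A zero group mean yields
  a ±inf effect sentinel with a warning rather than a crash.
- **Tissue-level scoring** averages ROI prediction scores per tissue and
  reports AUC and Mann–Whitney statistics at the tissue level; inference at
  the ROI level and the tissue level are kept distinct because ROIs within
  a tissue are not independent.
- **Robustness checks**: a per-protein Pearson correlation against the
  dependent protein (the naive alternative PLSR is compared to), and a
  CD45-cutoff sensitivity analysis that reruns the PLSR at 20/25/30%
  cutoffs and compares the sets of top-importance proteins (VIP > 1.15).

## Immune neighbor analysis

Immune cell–cell interaction is summarized by the immune neighbor number:
for each immune (CD45+) cell, the count of *other* immune cells whose
centroids lie within a radius r; the tissue statistic is the mean over the
tissue's immune cells. "Adjacent" is operationalized as centroid distance
≤ r with r configurable (default 30 px) and always recorded in output
metadata, because the appropriate radius depends on the pixel scale of the
source images. Only immune cells give and receive counts; the relation is
symmetric and self-exclusive, and counting is done with a k-d tree.

Cells come from per-cell tables or from simplified two-channel segmentation:
Gaussian smoothing of the nuclei channel, automatic Otsu threshold,
connected components, then a distance-transform watershed (the distance map
is lightly smoothed so plateaus do not spawn spurious markers) to split
touching nuclei, followed by per-object centroid, area, eccentricity,
solidity and per-channel mean intensity. Objects outside configurable area
bounds are discarded; a blank image yields an empty table. Immune
classification is a deterministic threshold on CD45 mean intensity fit to
labeled training objects by minimizing training misclassification (ties
broken toward the higher threshold); single-class training degrades to a
constant prediction with a warning. Out-of-focus or defective images are
excluded upstream by a user-driven QC flag, not automatically.

Density maps place a unit-mass isotropic Gaussian kernel at each immune
centroid on the pixel grid; with pixel area 1 the raster sums to the number
of immune cells (within 1% for interior patterns), which makes the maps
comparable across tissues.

## Molecular-response classification

Tumors are labeled molecular responders (mR) / nonresponders (mNR) by Ward
hierarchical clustering (Euclidean distance) of samples on the z-scored
genes of a response signature, cut at k = 2. Clusters are then *oriented by
biology*, never by cluster index: the cluster with the higher mean z-score
difference (T-cell/IFN-γ genes minus cell-cycle genes) is mR. Equal
category scores raise an explicit "orientation ambiguous" error. Ward on
z-scores was chosen for determinism and robustness; linkage and metric are
configurable. Whether to cluster normalized counts, log counts or z-scores
is a genuine free choice; z-scores were chosen so that no single
high-variance gene dominates the distance. The gene list with category tags
is a required input (the bundled 23-gene list is synthetic, for tests and
demos only).

## Synthetic data generator

The generators are pure functions of (config, seed) and ship the planted
ground truth alongside every dataset, so the whole pipeline is testable
end-to-end:

- **ROI counts**: per ROI, K latent factors t ~ N(0, I) drive log densities
  `x_j = μ_j + P_j·t + ε` (ε sd 0.3 by default) for the predictors and
  `y = μ_y + q·t + noise` for the dependent protein; informative proteins
  are the rows of P with nonzero loadings. Densities (counts/mm²,
  lognormal) are corrupted in exactly the layers the processing chain
  undoes: multiplied by lognormal mask areas (mean 0.025 mm², CV 0.3) and a
  per-batch lognormal ERCC factor, plus Poisson isotype background
  (~5 counts per ROI); ERCC and IgG columns are emitted so the chain can
  invert the corruption. Per-ROI factors are normalized to geometric mean 1
  because the global scale is unidentifiable from spike-ins alone. Default
  cohort: 60 ROIs over 14 tissues (≤ 16 ROIs per tissue), 20 predictor
  proteins of which 5 informative, half the ROIs immune-rich.
- **Response cohorts**: the same model plus a class shift of δ marginal
  log-sd units (δ/2 up vs δ/2 down; default δ = 2) on a set of discriminant
  proteins; default 40 ROIs per class, 2 discriminant + 10 noise proteins.
- **Cell maps**: immune cells from a homogeneous Poisson process or a
  Thomas cluster process (parents at intensity/offspring_mean, Poisson
  offspring, Gaussian displacement; parents simulated in a padded window to
  reduce edge bias) at matched expected intensity — the construction behind
  the point that equal density can carry very different neighbor structure.
  Non-immune cells are independent Poisson; synthetic CD45/nuclei
  intensities and morphology make the tables drop-in compatible with the
  classifier and neighbor operations.
- **Images**: Gaussian spots (nuclei for all cells, CD45 only for immune)
  plus optional Gaussian noise, with the ground-truth table returned.
- **Signature matrices**: mR samples get +δ/2 on T-cell/IFN-γ genes and
  −δ/2 on cell-cycle genes (sd units), mNR mirrored, unit-sd noise.

What the generator does **not** emulate: spatial autocorrelation of protein
expression between neighboring ROIs, heavy-tailed or zero-inflated counts,
segmentation artifacts beyond Gaussian optics, antibody cross-reactivity,
or tissue-level batch structure beyond a scalar ERCC factor. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own modelling assumptions — not that those assumptions
hold for any particular real dataset.

## Problem sizes and determinism

Recovery properties are quantified at the generator defaults: 100 seeded
cohorts for PLSR recovery (all informative proteins at VIP > 1 with correct
coefficient sign), 100 for elimination recovery and for the label-null
(floor-unreachable) behaviour, 50 for signature clustering at δ = 3, and
100 seeded pairs for the clustered-vs-dispersed neighbor comparison. All
randomized stages take explicit seeds and are bit-reproducible; the
acceptance script derives every sub-seed from its single `--seed` argument.

## Known limitations

- PLS coefficient signs for strongly collinear predictors become unstable
  as the component count grows (the coefficient allocation approaches the
  least-squares solution, which is arbitrary under collinearity); VIP is
  the more stable importance measure and is the primary screening quantity.
- The exact Mann–Whitney path requires tie-free data; with ties the normal
  approximation is used even at small n.
- The supplementary-data loader for the original study's files is an
  adapter stub: those files have no public accession, and their schema must
  be mapped onto the reader conventions once obtained.
- Segmentation is a simplified nuclei-watershed pipeline adequate for
  synthetic optics; it is not a replacement for a tuned production
  segmentation model on real micrographs.
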