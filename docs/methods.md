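# Methods

## Scope and model

`sdmshift` implements the temporal-transfer SDM workflow for
presence-only data: effort-corrected background sampling, boosted
regression trees (BRT), projection onto other periods' environmental
stacks, MaxSSS binarization, distribution-change indices and
convex-hull niche analysis. Because real occurrence databases and
multi-decadal environmental stacks are large, proprietary or both, the
package is built around a synthetic virtual-species world whose ground
truth is known exactly; all validation is property- and
recovery-based.

## Grid and raster conventions

* Regular lat/lon grid, row 0 northernmost, 0-based indices; cell
  (r, c) is half-open with its west/south edges owned by the cell via
  the floor snapping convention `col = floor((lon − west)/res)`,
  `row = floor((north − lat)/res)`; a record on an interior edge is
  assigned east/south. Cell centers sit at edge + res/2. Default
  resolution 0.1°.
* Depth is meters positive-down; negative-elevation rasters are negated
  on read (logged). ASCII NODATA sentinel −9999; ASCII values are
  written at 10 significant digits (one write/read cycle is a fixed
  point). GeoTIFF I/O uses tifffile with the ModelPixelScale,
  ModelTiepoint and GDAL_NODATA tags; single band, north-up, square
  cells only.
* Missing values are filled by nearest-non-missing-cell assignment
  (Euclidean distance in cell units), with exact ties broken by
  row-major order of the candidate source cells. The fill is
  idempotent and never alters observed cells. This is a deliberately
  conservative reading of "neighbour interpolation": it introduces no
  new values, only copies.
* Extent masking combines a lat/lon box with a maximal depth; masks
  only grow, and masking with nested boxes composes as intersection.

## Synthetic world (the study conditions)

One `FieldSpec` per descriptor: latitudinal gradient + moving-average
smoothed Gaussian noise (correlation length in cells) + per-period
additive shift. Noise fields are seeded by (seed, field name) only, so
periods generated from one seed differ *exactly* by their shifts —
between-period change is fully controlled. Defaults (a
Kerguelen-Plateau-like 100 × 180 cell box, −56..−46° S, 63..81° E):

| field | gradient (per ° lat) | noise sd | period shifts |
|---|---|---|---|
| temperature | 0.8 °C | 0.3 | past −0.5 °C, future +2.0 °C |
| salinity | 0.05 PSU | 0.15 | future −0.3 PSU |
| depth | −20 m | 200 | constant |
| chlorophyll | 0 | 0.4 | constant |
| ice_cover | −0.02 | 0.15 | constant |
| temp_copy | = temperature | — | planted, VIF ∞ |
| temp_chl_mix | 0.43·T + 2.5·chl + N(0, 0.47) | — | planted, R² ≈ 0.9 (VIF ≈ 10) |
| geomorphology | 3 codes by quantile thresholding a smooth latent | — | constant |

Noise amplitudes are balanced so genuinely distinct descriptors pass
the |ρ| ≤ 0.85 / VIF ≤ 5 filters while the two planted layers are
removed. The warming/freshening magnitudes follow the scenario logic
of sub-Antarctic projections (future change much larger than the
recorded past change); a +Δ uniform shift moves every isotherm by
Δ/gradient degrees of latitude, the ground truth for shift recovery.

The virtual species has a product-of-Gaussians suitability
`s = Π_j exp(−(x_j − opt_j)²/(2 tol_j²))^{w_j}` rescaled to max 1
(default: optimum 2 °C / 34 PSU, tolerances 1.2 °C / 0.25 PSU).
Presences are drawn without replacement with probability ∝ suitability
× effort, emulating detection bias; survey effort is a Gaussian KDE of
visited cells sampled from a northeast-biased log-linear intensity
(0.25 per degree), mimicking port- and route-concentrated sampling.

What the generator does **not** emulate: oceanographic physics,
sea-ice dynamics, spatially heterogeneous (non-uniform) climate
shifts, temporal autocorrelation of records, taxonomic misidentification,
and absence of the species from reachable habitat (dispersal limits).
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signals under the stated bias model — not
predictive skill on real oceanographic data.

## BRT engine

Native stagewise implementation: intercept = logit of prevalence; per
stage, a bag of `round(bf·n)` rows drawn without replacement, a
least-squares tree with `tc` internal splits grown best-first on the
gradient *y − p*, terminal values by one Newton step Σr/Σp(1−p), tree
added with shrinkage `lr`. Split gain is the SSE decrease
`Σ²_L/n_L + Σ²_R/n_R − Σ²/n`; continuous splits at midpoints between
distinct sorted values; categorical splits by exhaustive subset search
for ≤ 8 codes (mean-gradient ordering above), with codes unseen in
training routed to the more populous child. With `bf = 1` training
deviance is non-increasing in tree count (a tested invariant); with a
fixed seed, fit → predict is bit-reproducible.

Tree count: stratified k-fold CV (default 10 folds), held-out
Bernoulli deviance evaluated every `step` trees (default 50), first
minimum returned; a minimum at `max_trees` logs a warning. Relative
influence is the per-predictor share of total split gain over the
retained trees, normalized to 100 %.

Defaults: `lr = 0.01`, `tc = 2`, `bf = 0.75`, 400–800 trees. The
classic literature calibration `lr = 0.0001` (with tens of thousands
of trees) is preserved as `PAPER_PRESET`; the algorithm is identical,
only the shrinkage/length trade-off differs.

## Evaluation, thresholding, indices

* AUC: midrank (Mann–Whitney) formulation, ties ½. By construction
  presence-background AUC is bounded by 1 − α/2 for a species occupying
  fraction α of the evaluated area (tested on constructed cases).
  Reported AUC is training AUC on the replicate, matching common SDM
  practice; the recovery experiments additionally report held-out AUC
  on a 20 % random split.
* MaxSSS: candidates are the observed scores; sensitivity = fraction of
  presences ≥ t, specificity = fraction of backgrounds < t. Tie
  comparison is integer-exact (counts on the common denominator), the
  smallest maximizing threshold wins. "Suitable" is `p ≥ threshold`
  (boundary inclusive), applied uniformly.
* Indices are computed on the intersection of the per-period masks
  (only co-defined cells are comparable); `E_occupied` is reported
  unscaled per period, instability/overlap scaled by the reference
  (present-day) occupancy of the same replicate. Replicate summaries
  use the sample standard deviation (n − 1).
* Wilcoxon signed-rank (environmental-shift test): zero differences
  dropped, midranks for tied magnitudes; two-sided p exact by dynamic
  programming over the 2ⁿ sign assignments for ≤ 25 nonzero pairs
  (ranks doubled to integers), normal approximation with continuity and
  tie corrections above. Grid cells are spatially autocorrelated, so
  these p-values are descriptive; reports carry that caveat.

## Niche space

Occupied environmental points are the predictor-value tuples of
suitable cells inside the focal box (default: the full default grid, a
Kerguelen-Plateau-like window). Hulls use Andrew's monotone chain;
area by the shoelace formula; centroid is the polygon *area* centroid
(not the point mean), falling back to the point mean for degenerate
(≤ 2 distinct / collinear) inputs. Axes keep native units, so areas
are comparable only within one predictor pair; the analysis uses the
two highest-influence continuous predictors by default.

Two pairings of binary map and stack answer different questions:
per-period map with per-period stack describes the niche of a species
that *tracks* its habitat (the pipeline's niche stage); the
reference-period map with each period's stack describes a
*non-dispersing* population experiencing in-situ change — under a
uniform warming Δ its temperature-axis hull centroid moves by exactly
Δ, which the shift-recovery experiment exploits as an end-to-end check
of projection, thresholding and hull arithmetic.

## Pipeline and reproducibility

One global seed drives everything; each stage derives
`(seed·1000003 + crc32(stage)) mod 2³¹`, decoupling stages. Layers
without past/future data (default: chlorophyll, ice_cover) are
substituted from the reference period, reproducing the held-constant
convention for descriptors unavailable outside the present. Report
bundles (JSON with sorted keys, fixed-precision ASCII rasters, no
timestamps) are byte-identical across reruns with the same config — a
tested acceptance property.

## Problem sizes

Default world 100 × 180 cells; 200 presences, equal background count,
100 background replicates in the full protocol; 400-tree ensembles at
`lr = 0.01` per replicate; recovery experiments use 20 seeds with
200/200 samples and 500–800 trees. These sizes make a full protocol
run plus both experiments complete in minutes on a single core while
keeping per-replicate AUC and index estimates stable (replicate sds in
the report quantify the residual spread).

## Known limitations

* Nearest-neighbour missing-value fill creates plateaus at data gaps;
  it is not an interpolant in the smoothing sense.
* The effort KDE bandwidth default (2-D Scott's rule on visited-cell
  coordinates) is a heuristic; strongly multimodal effort may warrant a
  manual bandwidth.
* Training AUC on bias-matched backgrounds understates overfitting;
  use the held-out option for model comparison.
* Categorical predictors bypass the collinearity filters (rank
  correlation and OLS are undefined on unordered codes); association
  between categorical and continuous predictors is not screened.
* No reprojection: all rasters must share one lat/lon grid.
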