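# Methods

This note documents the statistical models, the synthetic data the tests
run on, the numerical conventions, and the places where a design had to be
fixed by this package rather than by established practice.

## The modelling problem

The pipeline estimates a habitat suitability surface for a species from
presence-only records and gridded environmental predictors. Because true
absences are unavailable, it uses the presence–background design: presences
are contrasted with pseudo-absence points sampled from the landscape, and
the fitted classifiers' probability outputs are read as relative
suitability, not occupancy probability. All spatial data live on one
north-up WGS84 lat/lon grid of square cells; missing cells (ocean) are NaN
in memory and a sentinel value in the plain-text ESRI ASCII grids used on
disk.

## Occurrence handling

Cleaning drops records without coordinates, fossil records, records dated
before a configurable cutoff year (default 1800; records with *unknown*
year are retained, since the filter removes only positively pre-dated
records), and exact duplicates on (lon, lat, year, basis). Extent filtering
keeps points inside the grid footprint — boundary points are retained
(closed extent) — and, when a land mask is supplied, only points in land
cells. Thinning keeps at most one record per grid cell of the *modelling*
grid; within a cell the earliest-dated record wins, unknown years sort
last, and remaining ties go to the first record in stable input order.
Thinning at the modelling resolution (rather than a separate 1 km grid) is
the package default because it is the resolution at which duplicate
records can inflate evaluation; the thinning grid is configurable.

## Pseudo-absences

Each background set is a uniform draw without replacement from cells that
are land, contain no presence, and whose centers lie farther than
`buffer_km` (default 1 km, great-circle on a sphere of radius 6371.0088 km)
from every presence. At the default 0.04° (~4.4 km) resolution the 1 km
buffer mainly excludes the presence cells themselves; the constraint is
still enforced exactly. Defaults: 10 sets at a 10:1 background:presence
ratio; no environmental stratification or bias correction. Each set is
paired with the presences to form one modelling table; evaluation metrics
are averaged over sets, and the final maps are produced from the first
set's table (a fixed, documented choice — averaging maps over sets changes
results negligibly but doubles cost).

## Predictor screening

Collinearity is removed by iterative VIF: VIF_j = 1/(1 − R²_j) with R²
from OLS of predictor j on the other retained predictors (plus intercept).
While any VIF ≥ 5, the largest is dropped; ties (including several
infinite VIFs under exact collinearity, e.g. the closed sand/silt/clay
composition) resolve to the *later* column in input order. Constant
columns count as infinite VIF. The screen is computed on the pooled
presence + first-set background rows of all species, so every species
models on the same predictor set. The same screen is available as the
sklearn transformer `VIFScreen`.

## Model families

All four families implement the sklearn estimator API on the same table
contract, output probabilities in [0, 1], and are deterministic given
`random_state`. No class weighting is applied — the 1:10 imbalance is part
of the design.

| family | implementation | fixed defaults |
|---|---|---|
| `linear_logistic` | unpenalised ML logistic regression | linear terms only; under (near-)perfect separation, where the MLE does not exist, refits with a weak L2 penalty (C = 100) and warns |
| `smooth_additive_logistic` | binomial GAM, penalised cubic B-splines | 10 basis functions per predictor, shared smoothing parameter chosen on the grid {0.1, 1, 10, 100, 1000} by GCV = n·deviance/(n − edf)², where edf is the penalised hat-matrix trace computed via pseudo-inverse (stable under collinearity); prediction inputs are clipped to the training range because the spline basis vanishes outside its knots |
| `elastic_net_logistic` | elastic-net logistic regression | mixing 0.5; penalty strength by internal stratified 5-fold CV over 10 values on log-loss; features standardised inside the estimator |
| `randomized_tree_ensemble` | random forest | 500 trees, floor(√p) candidate predictors per split, unlimited depth |

## Evaluation

* **AUC** — rank-based (Mann–Whitney), ties counted ½.
* **COR** — Pearson correlation of scores with the 0/1 labels; undefined
  (NaN in replicate records) when a model scores all rows identically.
* **TSS** — max over all unique score thresholds of
  sensitivity + specificity − 1, rule `score ≥ t`; the smallest maximising
  threshold is reported, with a 10⁻⁹ tolerance so float noise between
  mathematically tied thresholds cannot change the tie-break.
* **Deviance** — mean scaled binomial deviance
  −(2/n)·Σ[y ln p̂ + (1−y) ln(1−p̂)], p̂ clipped to [10⁻⁶, 1−10⁻⁶].

Replication: `subsample` holds out a stratified 30% test partition;
`bootstrap` trains on an n-out-of-n resample and tests out-of-bag;
single-class partitions are redrawn (≤100 attempts). The replicate count
is configurable with default 10; 3 is appropriate for quick looks and is
what the packaged fixture uses.

**Spatial block CV.** Points are projected to planar km by a local
azimuthal-equidistant mapping about their centroid (distances from the
centroid are exact; adequate at the 200 km block scale), tiled with square
blocks (default 200 km), and occupied blocks are allocated uniformly at
random to k folds, redrawing until every fold holds both classes. Blocks
are never split across folds. Each fold is predicted by a model trained on
the other folds; the mean held-out AUC, compared with the random-split
AUC, quantifies the optimism contributed by spatial autocorrelation.

**Null-model test.** The full fit-and-evaluate closure is rerun on
`n_null` (default 99) sets of presences placed uniformly at random on land
cells; the observed AUC is significant at α = 0.05 iff it exceeds the
empirical 95th percentile of the null AUCs. Inside the pipeline the null
statistic is the full-table training AUC of a configurable family list
(default: the linear logistic model only): observed and null statistics
are computed by the *same* closure, so the comparison is exchangeable and
the test calibrated, while remaining affordable at 99 replicates. The
calibration (type-I error ≈ 5%) and power are verified in the acceptance
suite.

## Ensemble and importance

Family weights are max(mean test TSS, 0) across all replicates, schemes
and background sets, normalised to sum 1; all-nonpositive TSS is an error.
Members are refitted on the full table before prediction, so the final
surface is deterministic; the ensemble map is the per-cell weighted mean
and is a convex combination of the member maps (nodata propagates).
Permutation importance is the drop in AUC when one predictor's column is
shuffled (mean over `n_perm` permutations), computed per family and
aggregated by the ensemble weights; AUC is used as the accuracy measure
because it is the discrimination metric used throughout the evaluation.
Negative aggregated importances are floored at 0 for reporting, raw values
retained. Genus-level composites are cell-wise means over species maps,
displayed via equal-count percentile bins (class c covers the
((c−1)/n, c/n] percentile interval; six bins by default).

## Habitat classes, areas, pressure

The ensemble surface is thresholded with the 10th percentile of suitability
at the (training) presences — linear interpolation between order
statistics — and a fixed core cut of 0.40: unsuitable < p10,
marginal ∈ [p10, 0.40] (closed interval), core > 0.40. If a small presence
sample pushes p10 above the core cut, p10 is capped at the cut rather than
failing. Cell areas use the exact spherical band formula
A = (π/180)·R²·Δλ·(sin(φ+h) − sin(φ−h)), R = 6371.0088 km, h = Δφ/2 — the
cosine approximation is recovered in the small-cell limit, and the formula
is validated against a numerical surface integral to 0.01%. Pressure
overlay: land-cover codes are aggregated to anthropogenic / natural /
other via a mapping table; each land-cover cell (same grid or finer)
contributes its own latitude-corrected area to the habitat class of the
cell containing its center; per-class category shares are reported in
percent and sum to 100.

## Environmental characterisation

Predictor values extracted at each species' occurrences are compared
across species per variable with one-way ANOVA plus Tukey HSD pairwise
tests (Kruskal–Wallis plus Dunn tests with Holm adjustment by
configuration), summarised as median/quartiles, 1.5×IQR outlier counts and
a compact letter display (insert-and-absorb algorithm: groups sharing a
letter are pairwise non-significant). Species with fewer than two usable
records are excluded with a warning.

## Synthetic data: what it emulates, and what it does not

Predictor fields are white Gaussian noise low-pass filtered by an
isotropic Gaussian kernel with sd = `corr_range_cells`, standardised and
rescaled to plausible units (e.g. VPD ~0.9 ± 0.35 kPa, light
~16 ± 3 MJ m⁻² day⁻¹, elevation ~350 ± 300 m). The sand/silt/clay triplet
is produced by per-cell normalisation of three positive log-normal fields
to sum exactly 100, reproducing compositional closure and hence the exact
collinearity the VIF screen must handle. Engineered collinear layers are
stated linear combinations of source layers plus Gaussian noise. The
virtual species has Gaussian responses per predictor; suitability is the
weight-normalised response sum passed through a logistic rescaled to reach
0 at response 0 and 1 at the combined optimum (an `identity` link is
available). Presences are drawn without replacement with probability ∝
suitability × optional bias, at cell centers (within-cell jitter off by
default so thinning is deterministic). Land cover is generated by
rank-thresholding a smooth field, so the realised anthropogenic share
equals the target up to grid discreteness, with spatial clustering at the
stated range.

The simulator does **not** emulate observation error (misidentification,
coordinate uncertainty), temporal non-stationarity, dispersal limitation,
biotic interactions, or the heavy-tailed sampling bias of real occurrence
archives (beyond the explicit bias grid). Tests passing on this world show
that the *pipeline machinery* is correct and calibrated — not that any
particular real species' map is right.

### Study scales used by the test and acceptance suites

Chosen once as representative desk-scale conditions: the niche-recovery
study uses a 60×60 grid (0.04° cells) with nine predictor layers, a single
dominant driver (VPD optimum one standard deviation above the field mean,
breadth 0.15 kPa), 50 presences and a 10:1 background; the null-model
calibration uses a 30×30 grid, three predictors, 15 presences, 5:1
background, 99 null replicates and the linear-logistic closure; the
spatial-blocking study uses a 100×100 grid (~440 km square), sampling
aggregated into 8 Gaussian clusters (sd 4 cells) independent of the
environment, predictors autocorrelated at 4 cells, 100 km blocks and 4
folds; the end-to-end fixture uses a 40×40 grid, one species with 30
presences, 2 background sets, 3 replicates and 19 null replicates.

## Numerical conventions and edge cases

* Tie-breaks are deterministic everywhere (VIF: later column; TSS:
  smallest threshold; thinning: earliest year then input order).
* All stochastic stages derive seeds from one master seed via SHA-256 of
  stage-name strings; the run manifest records them, contains no
  timestamps, and hashes every output, so rerunning a configuration
  reproduces the manifest byte-for-byte.
* Degenerate inputs fail loudly: single-class tables, fewer rows than
  columns in the VIF screen, empty presence sets, p10 > core cut,
  constant maps for percentile binning, unmapped land-cover codes.
* Bilinear resampling interpolates between source cell centers; target
  centers outside the source center lattice (beyond half a cell from the
  edge) become nodata; a 10⁻⁹ index tolerance absorbs float error at the
  lattice boundary.

## Known limitations

* The GAM's smoothing search is a shared-alpha grid, not per-term
  optimisation; strongly anisotropic smoothness across predictors is
  approximated.
* The null-model default closure scores training AUC (exchangeable and
  fast); it is not an estimate of out-of-sample skill, only a significance
  reference.
* Block allocation to folds is uniform random rather than
  spatially-balanced or systematic; with few occupied blocks, fold sizes
  can be uneven.
* Areas assume a spherical Earth; the WGS84 ellipsoid changes cell areas
  by <0.3%.
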