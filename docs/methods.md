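# Methods

## Problem setting

Presence-only suitability modelling asks: given locations where a crop
is successfully grown and gridded climate predictors, how suitable is
every cell of a landscape, now and under projected future climates?
True absences are rarely observable for crops (land without orchards is
not necessarily unsuitable), so models are trained on presences plus
*background* pseudo-absences sampled from the landscape, and evaluated
by their ability to rank presences above background (AUC).

`ensdm` implements this as an ensemble: several structurally different
algorithms are fitted, weak ones are excluded, and the survivors'
per-cell scores are averaged with AUC-proportional weights. Ensembles
of this kind are standard in the crop-suitability literature because no
single algorithm family dominates across species and regions.

## Data model and conventions

* Grids are regular, north-up, lon/lat with square cells. The origin is
  the **north-west corner edge**; rows run north→south. Point-to-cell
  lookup uses half-open intervals `[edge, edge + cell_size)`, so a point
  exactly on a cell's NW corner belongs to that cell and the southern and
  eastern outer edges are outside the grid. This removes all boundary
  ambiguity.
* All layers of a stack share one boolean nodata mask. On disk the
  sentinel is −9999 for float rasters and 255 for byte class maps, stored
  in the GDAL_NODATA tag next to standard GeoTIFF georeferencing tags, so
  files interoperate with GDAL tooling. Only per-file and multiband
  single-file GeoTIFFs are supported; reprojection is out of scope.
* Occurrence CSVs are `lon,lat[,label]` in decimal degrees WGS84; a
  missing label column means presence. Presence thinning keeps at most
  one point per grid cell, choosing the survivor uniformly at random
  under a seed (how real studies resolved such ties is typically
  unreported); thinning is idempotent.

## Predictor screening

The variance inflation factor of predictor *i* is VIF = 1/(1 − R²ᵢ)
with R²ᵢ from an OLS regression of that predictor on all others plus an
intercept. Pruning is greedy: recompute all VIFs, drop the largest one
at or above the threshold (default 10; ties drop the later column),
repeat until all survive. Greedy worst-first removal is the standard
stepwise practice and is deterministic. VIFs are computed on the values
extracted at occurrence + background points by default — the same sample
the models see — with whole-raster computation available.

## The four built-in algorithms

Suitability algorithms rank candidate sites; mapping those ranks onto a
common [0, 1] scale is a modelling choice. The choices here are
documented per algorithm and unit-tested exactly as stated:

* **BIOCLIM envelope** (presence-only). Per variable, the candidate's
  midrank percentile within the presence sample,
  p = (n_below + ½·n_equal)/n, folded symmetrically to 2·min(p, 1−p):
  1 at the presence median, 0 at or beyond the envelope. The overall
  score is the minimum over variables (limiting-factor logic).
* **DOMAIN** (presence-only). Gower distance to each presence point —
  mean over variables of |x−xᵢ|/rangeₖ with ranges from the presence
  sample; a zero-range variable contributes 0 on exact match, else 1.
  Score = 1 − (distance to the nearest presence), clipped to [0, 1].
* **Mahalanobis niche** (presence-only). D² = (x−μ)ᵀΣ⁻¹(x−μ) with the
  presence mean and covariance; score = P(χ²_m > D²). The score is 1 at
  the centroid, monotone decreasing in distance, and invariant to affine
  reparameterizations of the predictors. An ill-conditioned covariance
  (condition number > 10¹⁰) is ridge-stabilized by ε·trace(Σ)/m on the
  diagonal with ε = 10⁻⁸.
* **GLM** (presence/background). Unpenalized maximum-likelihood logistic
  regression with intercept; under perfect separation the optimizer
  stops at its iteration cap with a warning and the capped fit is used.

Presence-only members train on presences alone but are *evaluated*
against background scores, which is how such algorithms are assessed in
practice. Additional learners (random forests, SVMs, boosting) enter
through an adapter wrapping any `predict_proba` classifier; ensemble
membership is configuration-driven.

## Evaluation, gating, weighting

* **Split**: stratified 70/30 by label, seeded.
* **AUC**: Mann–Whitney probability with ties counted ½, computed by
  midranks; verified in tests against an all-pairs brute force to 10⁻¹².
* **Cross-validation**: stratified 5-fold on the training split; the
  *mean CV AUC* drives the gate, while the 30% holdout is reserved for
  reporting, keeping selection and assessment separate.
* **Gate**: members with mean CV AUC < 0.77 are excluded (the
  conventional "useful model" threshold in this literature).
* **Weights**: wᵢ = AUCᵢ taken literally, normalized to sum to 1 (an
  alternative wᵢ = max(AUCᵢ − 0.5, 0) is available by configuration).
  Members whose normalized share falls below 5% ("contribution",
  interpreted as normalized weight share) are dropped one at a time —
  lowest share first, ties dropped later-in-input-order first — with
  re-normalization after each drop. If every remaining member ties at
  the same sub-5% share, dropping any one would be arbitrary and all are
  retained.
* **Ensemble score**: S_e = Σ wᵢSᵢ / Σ wᵢ per cell, so S_e always lies
  between the member minimum and maximum (checked as an invariant).
* **Variable importance**: permutation-based (the literature typically
  reports importance without defining a procedure, so one is defined
  here): per member, the mean AUC drop over n permutations of each
  column; drops are weight-averaged across members, floored at 0, and
  normalized to percentages summing to 100.

## Thresholding, classes, consensus, change

* The binary threshold either maximizes sensitivity + specificity over
  candidate thresholds (midpoints of adjacent distinct scores plus 0 and
  1; ties resolve to the smallest) or is fixed by configuration
  (e.g. 0.34). A cell is suitable when score ≥ threshold. The
  baseline-derived threshold is reused unchanged for all future
  projections, since it is a property of the fitted baseline model.
* Five classes: [0, t) unsuitable; [t, 1] tiled by four equal-width bins
  (marginal, moderate, optimal, highly suitable; top bin closed). The
  source literature names the five classes without giving breakpoints,
  so equal widths above the threshold are used and are
  config-overridable; bin edges are reported in metadata.
* Consensus over N future models: suitable only where at least
  ⌈agreement·N⌉ models vote suitable (12 of 17 at 66%). As written, a
  two-way split can leave a cell where neither class reaches the
  agreement level; the rule resolves this conservatively toward
  unsuitable. The integer vote count is computed with a tolerance so
  ties like 0.66·50 = 33.0 do not round up through floating-point error.
* Change codes per cell from (current, future): never suitable, loss,
  stable suitable, gain. Area conservation — current = remaining + loss
  − gain — is asserted per region and in total on every summary.

## Area accounting

Cell areas are constant (default 25 km², matching a ~5 km grid) or
latitude-corrected: (111.320·Δ)²·cos(lat_center) for a Δ-degree cell.
Percentages divide by a configurable land-area denominator rather than
the full grid surface (for the Malawi study system: 94,449 km² of land
out of 118,484 km² total; using land area reproduces the published
percentage columns, e.g. 53,925/94,449 → 57%). One published regional
percentage (Southern, 10.7%) is inconsistent with that denominator
(which gives 10.9%); the package reproduces the arithmetic, not that
cell. Rendered tables round half-up at the printed precision.

## Synthetic worlds

The generator fabricates a complete study system with known truth:

* **Layers**: Gaussian white noise smoothed by an isotropic Gaussian
  kernel (σ = the correlation length in cells, truncated at 3σ,
  reflective boundary; length ≤ 1 means white noise), standardized to
  mean 0, sd 1. The first ⌈n/2⌉ layers mix a shared factor,
  √ρ·F + √(1−ρ)·G, giving pairwise correlation ρ (default 0.95) so the
  VIF pruner has genuine work — mirroring real bioclim sets where fewer
  than half the variables survive screening.
* **Truth**: logistic(β₀ + Σβₖzₖ). The default β (intercept −6; 3 on
  one collinear layer; 7, −5, 3, −2.5 cycled over independent layers)
  makes a steep surface with roughly a quarter of the landscape suitable.
  Steepness is a deliberate design constraint: with presences sampled
  proportionally to suitability and uniform backgrounds, the achievable
  presence-vs-background AUC is capped near 1 − f/2 (f the suitable
  fraction), because backgrounds falling on suitable cells are
  indistinguishable from presences. A shallow surface would cap every
  member below the 0.77 gate and make the pipeline untestable; the steep
  default emulates a strongly climate-determined crop and yields member
  CV AUCs in the 0.71–0.89 range, so the gate genuinely excludes the
  weaker envelope methods on most seeds.
* **Occurrences**: presence cells drawn without replacement with
  probability proportional to truth; 500 background cells drawn
  uniformly from the remaining cells; points at cell centres. Default
  200 presences on a 100×100 grid.
* **Futures**: pseudo-GCM g's layer k = baseline + shiftₖ + ε_{g,k},
  with ε a layer-wide N(0, spreadₖ²) offset per model — shared climate
  signal, between-model disagreement. Default: 17 models, shift 0.4 sd
  against each layer's favourable direction (a warming/drying analogue),
  spread 0.15 sd.
* **Regions**: horizontal bands of near-equal height (extra rows north),
  standing in for administrative regions.
* All randomness flows from one root seed through named substreams
  (layers, presences, background, gcms); identical configs give
  bit-identical worlds.

What the synthetic world does **not** emulate: physically realistic
climate fields (no seasonality structure, no units), spatial sampling
bias in occurrences, spatially varying GCM disagreement, or irregular
region geometries. Passing recovery tests therefore demonstrates the
pipeline's statistical correctness, not field-data performance.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery analysis on a 100×100
grid with 200 presences and 500 backgrounds — large enough for stable
AUCs and correlation targets (±0.1), small enough to run in seconds.
Tolerances: AUC vs brute force 10⁻¹²; VIF vs independent OLS 10⁻⁶;
Mahalanobis affine invariance 10⁻⁶; weight normalization 10⁻¹²;
recovery bands: truth-label AUC ≥ 0.80, suitable-fraction error ≤ 0.10,
single-signal importance share > 50%. Exact collinearity flags VIF as
infinite rather than a large number. Degenerate inputs (constant
columns, identical presence rows, single-class labels, folds without
presences) raise typed errors rather than propagating NaNs.

## Known limitations

* Only 4 of the ~18 algorithms used by large ensemble platforms are
  built in; others must come through the scikit-learn adapter.
* No spatial cross-validation; random folds can be optimistic under
  strong spatial autocorrelation.
* No calibration of member scores beyond each algorithm's documented
  [0, 1] mapping; members with different score sharpness are averaged
  as-is.
* Areas assume either constant cell size or a cos(latitude) correction;
  no equal-area projection support.
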