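# Methods

## Observation model: chronicle fate coding

The observation unit is a grid cell × period *fate row*. Cells are
half-open `[west, east) × [south, north)` squares (default 0.5°, points on
the outer domain edge fold into the last cell); periods are half-open
30-year bins tiling the study window (default 1700–2000, so ten periods; a
50-year variant is a config change away). For each cell with at least one
detection, the **last** detection period yields a 0-row; if the window
contains a later period and no later detection exists, that next period
yields a 1-row. Consequences worth stating explicitly:

- each uncensored extinction event contributes exactly one 0-row and one
  1-row, so uncensored rows = 2 × events;
- re-detection after a gap cancels any intervening absence (the rule keys
  on the last detection);
- cells last seen in the final period are right-censored (0-row only).

A `presence_rows="all"` switch emits a 0-row at every detected period for
sensitivity analysis; the default is the pair-per-event reading, the only
one consistent with a row count of twice the event count. Covariates on
fate rows are arithmetic means of the decadal input slices over the row's
period; rows over nodata cells are dropped and counted.

## Additive logistic extinction model

Binomial-logit additive model on fate rows. Univariate smooths are cubic
B-splines with 10 basis functions (interior knots at data quantiles) and a
second-order difference penalty; the spatial term is a 5 × 5 tensor product
of marginal lon/lat bases with the additive Kronecker penalty
`P₁⊗I + I⊗P₂`. Every smooth is column-centred against the training data and
an unpenalized intercept is kept, so effects are identifiable and partial
effects are centred on the logit scale.

Fitting is penalized IRLS. A single smoothing multiplier shared across
terms (each term's penalty rescaled by ‖XₖᵀXₖ‖/‖Pₖ‖ so one multiplier means
comparable shrinkage) is selected by GCV, `n·D/(n − edf)²`, over a fixed
log-spaced grid. Per-term GCV refinement was implemented and measured but
rejected: coordinate-wise GCV minimization undersmooths individual terms
(a known failure mode of GCV), destroying the monotone shape of weak
partial effects. A fixed multiplier can be supplied to bypass selection —
the nested-model monotonicity property (adding a smooth never decreases
deviance explained) is only guaranteed at a common fixed penalty and is
tested that way.

Numerical safeguards: a ridge of `1e-7` × the mean squared column norm
(never on the intercept) keeps the penalized Hessian invertible when a
covariate has few distinct values (the holistic temperature proxy has one
value per period); quasi-separation (|η| > 30) triggers a one-time ridge
increment, a warning, and linear-predictor capping. Reported diagnostics:
per-term effective degrees of freedom (trace of the hat sub-block), Wald
chi-square on the penalized coefficients with df = round(edf), deviance
explained `1 − D/D₀`, and adjusted R² =
`1 − (1 − R²_dev)(n − 1)/(n − edf − 1)`.

Collinearity screening fits single-smooth models for both members of any
predictor pair with Pearson |r| above 0.95 and drops the one with lower
adjusted R² (AIC = deviance + 2·edf as tiebreaker); constant predictors are
dropped outright with a "zero variance" log entry.

## Record screening

All distances are haversine on a sphere of radius 6371.0088 km; the
original protocol used projected tooling without stating a metric, so one
consistent geodesic metric is used everywhere (including the nominally
"Euclidean" 10 km rarefaction). A record in the screening window is an
extinction occurrence iff it is outside the range polygon AND farther than
`buffer_km` (default 50) from every extant record; with no extant records
the buffer condition is vacuously true. Because the two screens overlap,
the report carries three counts — outside range, outside all buffers, and
the intersection used downstream — rather than guessing how overlapping
published bins were split.

Rarefaction is deterministic: a greedy id-ascending pass keeps a record iff
it is ≥ `rarefy_km` from every kept record, then one record per 5-arcmin
cell (lowest id). Determinism replaces the randomized order of the common
desktop tool; a seeded random order would change which records survive, not
the minimum-distance guarantee. Ripley's K uses the unadjusted estimator
`K̂(r) = (A/n²) Σ_{i≠j} 1[d_ij ≤ r]` (no edge correction — the tool the
protocol names does not document its estimator) with a Monte-Carlo CSR
envelope (default 99 uniform simulations in the spherical bounding box, the
latitude drawn via inverse-CDF of sin so points are uniform on the sphere);
interpretation is envelope-based only.

## Maximum-entropy risk model

Features per variable: linear, quadratic, and hinge with knots at the nine
interior background deciles, all scaled to [0, 1] over the background and
clamped outside it. The penalized log likelihood

    (1/m) Σᵢ λ·f(xᵢ) − log Σ_bg e^{λ·f} − Σⱼ βⱼ|λⱼ|,   βⱼ = c·sⱼ/√m

(`c` the regularization multiplier, `sⱼ` the background SD, `m` presences)
is maximized by cyclic coordinate-wise proximal Newton with backtracking,
plus an active-set Newton polish once the KKT violation falls below 1e-3
(correlated hinge features make pure coordinate descent zigzag). Weights
are bounded at ±200 because separable data leave the objective unbounded;
bound-pinned features are exempt from the KKT convergence test (tolerance
1e-6). The raw output `q(x) = e^{λ·f}/Z` sums to 1 over background; the
logistic output is `q·e^H/(1 + q·e^H)` with `H` the entropy of `q`
(cloglog is not provided). Percent contribution accumulates each
coordinate update's objective gain to the owning variable — it is
path-dependent by construction and therefore seeded; permutation importance
permutes one variable across presence + background and reports the
normalized training-AUC drop (negatives floored at 0). AUC is the exact
Mann–Whitney statistic.

Protocol defaults follow the published workflow where stated and
conventions where not: 10,000 background cells (or all valid cells if
fewer), a 25-run pre-experiment dropping variables with zero contribution
AND zero importance in every run (the rule is literal: any nonzero run
retains), the |r| > 0.7 filter keeping the higher contributor (pairs
visited by descending |r|), 100 replicates, and — the replicate design
being unstated — random subsampling with a 25% test split.

## Thresholding, classification, accounting

Max-SSS scans every distinct observed score; sensitivity = share of
presences ≥ t, specificity = share of background < t; ties resolve to the
smallest threshold (within 1e-12, so vectorized arithmetic cannot flip a
tie). Fisher–Jenks is the exact O(k·n²) dynamic program on sorted values
minimizing total within-class SSD, reporting class maxima, ties toward the
smaller boundary index. Classification applies Jenks with k = 3 to the
at-risk sites only (risk ≥ threshold), labelled low/moderate/high above the
"none" class — the published class boundaries are consistent with the
lowest boundary being the threshold itself; a k-on-all-sites reading is
available by passing threshold 0. Reported percentages use decimal half-up
rounding to 2 decimals, matching the arithmetic style of the published
shares; `report_accounting` exposes the same bin-sum/share arithmetic for
arbitrary bins.

## PCA

Standardized (correlation) PCA via SVD of the column-standardized matrix —
variables mix persons, millimetres and degrees, and the R packages the
protocol names scale by default. Components are ordered by variance with
the largest-magnitude loading made positive; per-variable contribution to a
component is 100 × squared loading. Zero-variance columns are an error
under standardization, named in the message.

## Synthetic chronicle generator

The generator emulates the study's inputs at their real scale: a 66 × 66
grid of 0.5° cells over a China-sized domain (97–130°E, 18–51°N), ten
30-year periods with decadal covariate slices, 159 extant records, and a
current-range polygon. The data-generating process is a discrete-time
hazard: a cell occupied in period p fails to persist through period p+1
with probability `logistic(β₀ + β_temp·z_temp + β_pop·z_logpop + s(lon,lat))`
evaluated on period-(p+1) covariates — the conditions the population did
not survive, which is also what the absence row carries. There is no
recolonization. Detection of an occupied cell-period is Bernoulli; records
are dated uniformly within the period and placed uniformly within the cell.

Default conditions and why:

- `β₀ = −2.0` (log-odds): ≈ 75% of cells extinct by the final period — the
  magnitude of range collapse the species actually experienced, and the
  regime in which fate rows are mostly uncensored pairs.
- `β_temp = 1.0`, `β_pop = 0.75` per SD: a dominant but not exclusive
  climate signal alongside human pressure.
- temperature proxy: trend 0.2 per period with slice-level noise SD 0.3,
  i.e. fluctuation-dominated, as ice-core δ¹⁸O series are. This matters
  for identifiability: every anthropogenic covariate shares the monotone
  time trend, so a trend-only temperature proxy is nearly collinear with
  them and its effect is unrecoverable by any method; the decadal
  fluctuations are the unique variation that identifies it.
- `detection_prob = 0.7`: high enough that coded extinction periods track
  true ones (heavy misdating decorrelates the fluctuating proxy from the
  hazard), low enough to exercise the last-detection logic against missed
  sightings.
- the spatial hazard field is a sum of two sinusoids, giving the spatial
  smooth low-frequency signal to find.
- grazing, cropland and built-up fractions grow with population density
  (saturating), population grows ≈ 8.6× over the window; bioclim-style
  layers are static spatial fields.
- the range polygon is the union of final-period occupied cells eroded by
  one cell width — the stand-in for post-window decline and expert-map
  under-coverage that makes outside-range screening non-trivial; erosion
  halves adaptively when it would swallow a small occupied area.

What the generator does **not** emulate: observer effort varying in space
or time, georeferencing error in historical place names, demographic
structure, recolonization, and real HYDE/WorldClim spatial covariance.
Passing tests therefore show the pipeline recovers known structure under
the stated hazard model — not that the real chronicle data satisfy it.

All randomness flows from one seed through fixed per-stage sub-streams, so
each stage is independently reproducible; pipeline stages use disjoint
fixed stream offsets from the configured seed.

## Scaled-down test conditions

The test and acceptance suites run the generator at 20 × 20 cells
(≈ 750 fate rows, the scale at which the recovery properties are stated)
and the end-to-end determinism check at 20 × 16 cells with 4 replicates and
proportionally shrunken screening distances (15 km buffers, 3 km
rarefaction) — every protocol constant is a config key precisely so reduced
worlds shrink coherently. The noise-only model check permutes fate labels
across rows: running the simulator with all hazard coefficients zero does
not make fate independent of the covariates, because the last-detection
encoding ties fate composition to period (early-period rows are mostly
uncensored pairs), so trending covariates predict fate even under a
constant hazard; permutation delivers the intended independence null.

## Known limitations

- GCV with one shared multiplier can over-smooth a strong term or
  under-smooth a weak one; REML and per-term selection are not provided.
- Wald p-values on penalized coefficients with df = round(edf) are
  approximate; they are labelled as such in the fit table.
- The K-function has no edge correction, so K̂ is biased low near the
  boundary; only envelope comparisons are meaningful.
- Percent contribution depends on the optimization path (as in the
  reference MaxEnt implementation); only seeded runs are comparable.
- Raster I/O is ESRI ASCII text only, and all coordinates must already be
  WGS84 decimal degrees; there is no reprojection.
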