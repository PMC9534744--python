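# chronorisk

Chronicle-based local-extinction analysis for range-collapsing species.

Historical chronicles — gazetteer sightings, rescue records, museum
remains — are some of the only long-term monitoring data for species like
the Chinese pangolin (*Manis pentadactyla*), whose range in China contracted
drastically between 1700 and 2000 AD. `chronorisk` turns such dated,
georeferenced occurrence records into quantitative extinction analyses:

1. **Fate encoding** — the study region is divided into half-degree grid
   cells and the study window into 30-year periods. A cell's last detection
   period is coded 0 (presence); if the species is never detected there
   again, the following period is coded 1 (absence). Each local-extinction
   event therefore contributes one matched 0/1 pair of *fate rows*; cells
   detected in the final period are right-censored.
2. **Additive logistic extinction model** — fate is modelled as
   `logit P(fate = 1) = β₀ + Σⱼ fⱼ(xⱼ) + f(lon, lat)` with cubic B-spline
   smooths `fⱼ` for human population density and count, cropland, grazing,
   a holistic temperature proxy (δ¹⁸O) and regional temperature, plus a
   tensor-product spatial smooth. Penalized IRLS with GCV-selected
   smoothing; collinear predictor pairs (|r| > 0.95) are screened first.
3. **Extinction-record screening** — a recent-window (1970–2000) record is
   an extinction occurrence when it falls outside the current range polygon
   *and* beyond 50 km of every extant record; the set is spatially rarefied
   (10 km, one record per 5-arcmin cell) and checked with Ripley's K.
4. **Maximum-entropy risk surface** — an L1-regularized Gibbs distribution
   over background cells maximizing
   `(1/m) Σᵢ λ·f(xᵢ) − log Z_bg(λ) − Σⱼ βⱼ|λⱼ|`
   with linear, quadratic and hinge features; MaxEnt-style percent
   contribution, permutation importance, the 0%-contribution pre-experiment
   and the |r| > 0.7 correlation filter; 100 replicated subsample fits
   averaged into a logistic risk surface with test AUC.
5. **Risk classification** — the maximum sensitivity-plus-specificity
   threshold separates no-risk sites; Fisher–Jenks natural breaks split the
   at-risk sites into low / moderate / high ("notable" = moderate + high).
6. **PCA attribution** — standardized PCA of the environment at extinction
   records, with per-variable contribution = 100 × squared loading.

A first-class synthetic-data module generates chronicle worlds with known
ground truth (occupancy, true extinction periods, true hazard coefficients),
so every stage is testable end to end without any external download.

## Worked example

```sh
python examples/01_simulate_and_encode.py
```

```
1869 dated records across 400 cells
747 fate rows, of which 354 are extinction events
true number of extinct cells: 342
```

The encoder recovers 354 coded extinction events against 342 true extinct
cells: right-censoring removes events in the final period while imperfect
detection can misdate others; the matched 0/1 pair structure is exact.

```sh
python examples/04_risk_model.py
```

```
17 extinction presences after screening + rarefaction
retained variables: ['popc', 'grazing', 'bio8', 'bio14']
mean test AUC over 100 replicates: 0.756 (sd 0.087)
  popc         contribution  71.2%   importance  13.3%
```

Population count dominates the risk model's training gain, mirroring the
anthropogenic-pressure signal the pipeline is designed to expose; AUC is the
probability a held-out extinction site outscores a random background cell.

The other examples (`02` GAM partial effects, `03` screening and Ripley's K,
`05` classification and PCA) follow the same pattern. The full pipeline is
also available as a CLI:

```sh
chronorisk all --seed 7 --out run/     # simulate -> encode -> gam -> screen
                                       #   -> risk -> classify -> pca
```

Each stage writes CSV/ESRI-ASCII/GeoJSON outputs plus a run manifest; the
same config and seed reproduce byte-identical tables.

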