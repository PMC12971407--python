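# Methods

`ecocoupling` quantifies the interplay between ecosystem health and human
activity on a common raster grid, in three stages: *assessment* (two
composite indices per analysis unit), *coupling* (their spatial
association and coordination), and *driving* (machine-learned attribution
of both indices and their coordination to environmental and socio-economic
covariates). This note documents the models, the defaults and why they
were chosen, what the synthetic scenarios do and do not emulate, and the
numerical conventions.

## Analysis units

All rasters are aggregated onto a lattice of square blocks of
`unit_cells × unit_cells` cells; every index, statistic and model operates
on these units. Edge blocks are retained when at least half of their
nominal cell count is valid; blocks with more masked than valid cells are
dropped. The block mode statistic breaks ties toward the smallest class
code. `unit_cells` is a free configuration parameter (default 4): the
appropriate unit size depends on the raster resolution and the scale of
the processes of interest, and no single default suits all inputs.

## Ecosystem health (VORS)

The ecosystem health index is the geometric mean of four components on
[0, 1]:

    EHI = (EV · EO · ER · ESI)^(1/4)

* **EV (vitality)** — min–max normalized unit-mean net primary
  productivity. Normalization is pooled over all years in the run so that
  levels are comparable through time; a year whose maximum is below
  another year's maximum therefore cannot reach EV = 1.
* **EO (organization)** — a weighted combination of six landscape pattern
  metrics computed on each unit's land-cover sub-raster: Shannon diversity
  (SHDI) and evenness (SHEI), landscape division, interspersion/
  juxtaposition (IJI), contagion (CONTAG) and the area-weighted fractal
  dimension (FRAC). Patches are connected components per class
  (8-neighbour by default); perimeters and adjacencies are always counted
  on the 4-neighbourhood, adjacencies by the double-count method with
  like-class pairs included and the landscape boundary excluded. IJI is
  undefined below three classes and recorded as missing, never zero;
  missing metrics are imputed with the cross-unit median after
  normalization. The default *flat* weighting applies the six published
  sub-weights (0.1499, 0.1502, 0.1002, 0.2173, 0.1191, 0.2633, summing to
  1) to globally min–max normalized metrics. The grouped form
  (connectivity/heterogeneity/shape groups re-weighted by 0.3001/0.4366/
  0.2633) multiplies each sub-weight by its group coefficient a second
  time, which caps the index well below 1; it is implemented as
  `eo_mode: nested` for comparison but is not the default.
* **ER (resilience)** — the area-weighted score
  `Σᵢ Aᵢ (0.4·C_resist,i + 0.6·C_recover,i)` over land-cover classes, with
  the published per-class resistance/recovery coefficients (pure forest
  0.94, pure desert 0.14). Aᵢ is read as the *within-unit class
  proportion*, not an absolute area, so ER is scale-free and commensurate
  with the other components.
* **ESI (services)** — an entropy-weighted sum of five normalized
  ecosystem-service indicators (carbon, food, environmental quality, soil
  retention, water yield). The entropy method gives near-zero weight to
  near-constant indicators; exact zeros are shifted by ε = 1e-6 before the
  share computation because p·ln p is undefined at zero. Fixed
  literature-derived weights can be supplied instead; entropy weighting is
  the default.

Index layers are graded into five levels. The default scheme splits the
natural [0, 1] range into equal intervals (so grades are absolute and
comparable across runs); quantile grading is available.

## Human activity intensity

HAI combines a land-use disturbance score (SLUCC: construction 10,
farmland 7, grassland 3, all else 0, proportion-weighted per unit),
population density and nighttime-light intensity. Each component is
range-normalized (pooled over years, as for EHI) and the three are
averaged. The raw component sum lives on [0, 3]; dividing by 3 makes HAI
commensurate with EHI for the coupling model and is monotone, so level
classifications and ranks are unaffected.

## Spatial association

Global Moran's I (I = n·zᵀWz / (S₀·zᵀz)) and its bivariate form
(I_xy = z_xᵀWz_y / S₀, population-standardized, so it reduces exactly to
the univariate statistic when y = x) are computed on lattice contiguity
weights (queen by default, row-standardized; rook and distance-band
available). Units without neighbours are flagged and excluded.

Inference is by random permutation (999 draws by default, seeded). The
primary p-value is one-sided toward the observed side of E[I] = −1/(n−1),
matching the directional way such results are conventionally reported; a
two-sided companion is always attached. The two-sided value uses
equal-tail doubling, `min(1, 2·min(p≤, p≥))`, which is rank-based and
therefore uniform under the null even though the Moran permutation
distribution is skewed; the one-sided-toward-observed-sign value is by
construction not uniform (it concentrates on (0, ½]) and should not be
used for null calibration.

Hot/cold spots use the Gi* statistic with the focal unit included in its
own (binary) neighbourhood, classified by the 1.65/1.96/2.58 z ladder.
Raw thresholds are the default; an FDR flag is available but off, since
confidence-ladder maps are conventionally reported uncorrected.

## Coupling coordination and quadrants

Coupling degree C = 2√(EHI·HAI)/(EHI+HAI) (defined 0 when both are 0),
coordination index T = α·EHI + β·HAI with α = β = 0.5, and coordination
degree D = √(C·T), graded into five bands with half-open intervals and
the top band closed: [0, .2) severe dissonance, [.2, .4) mild dissonance,
[.4, .6) near-dissonance, [.6, .8) mild coordination, [.8, 1] high
coordination. A literal product form T = (α·EHI)·(β·HAI) is implemented
as `coordination_mode: multiplicative`; with α = β = 0.5 it bounds T by
0.25·EHI·HAI, which cannot produce coordination degrees above ~0.5, so
the additive convention is the default.

The four-quadrant model z-scores both indices and splits at the
standardized means; z ≥ 0 counts as high (a deterministic tie-break).
Quadrant I (high/high) is the coordinated-development zone, II (low
health, high activity) ecological management, III (low/low) risk
prevention, IV (high health, low activity) potential conservation.
Per-year quadrant area shares, mean D per quadrant and first-to-last-year
share changes are summarized.

## Driver attribution

EHI, HAI and D are regressed on unit-level covariates (climate, terrain,
economy, pressure layers; configurable) with an XGBoost regressor.
Hyperparameters are chosen by grid search (default grid: depth {3, 5},
learning rate {0.05, 0.1}, trees {200, 500}, L2 {1, 5}) under 5-fold CV
scored by RMSE; the winner is refit on the 70% train split and reported
with R², RMSE and MAE on train and test.

Attribution uses exact path-dependent TreeSHAP, implemented in this
package in float64 (`ecocoupling.treeshap`): features absent from a
conditioning subset are marginalized by training-cover weights, and the
per-tree recursion yields exact Shapley values without subset
enumeration. Local accuracy — base value plus the row's attributions
equals the ensemble margin — holds to ~1e-14. Two engine-level details
matter for exactness: model dumps print float32 thresholds as 9-digit
decimals, which are cast back through float32 to recover the stored bits,
and split comparisons are evaluated in float32, so inputs are rounded
through float32 before traversal. The implementation is tested against a
brute-force Shapley enumeration (machine-precision agreement on small
ensembles) and against the engine's own contribution output (float32
tolerance). Importance shares are mean |φ| fractions in percent.

Nonlinear thresholds are read from the SHAP dependence relation: sort
(feature value, φ) pairs, smooth φ with a centered rolling median
(window 51), and report the feature value midway between the samples
where the smoothed series first changes sign, with all further crossings
listed and a bootstrap-over-units percentile interval. A series with no
sign change is a valid "no threshold" outcome. For a kinked additive
response with slopes (s₁, s₂) around a breakpoint b, the attribution sign
crossing sits at b + E[(v−b)⁺]·(1 − s₁/s₂), not exactly at b; the
detector therefore carries an intrinsic offset proportional to the
feature's mean deviation beyond the kink.

## Synthetic scenarios

The generator produces everything the pipeline consumes: spatially
autocorrelated fields (Gaussian-filtered white noise, standardized, fully
seeded), an elevation surface with a mountains-to-plains ramp plus
correlated relief, land cover assigned by quantile-thresholding a
suitability field (construction and farmland in the plains, forest on
high ground, exact requested class shares), lognormal human-pressure
layers that decay with elevation, concentrate near construction and can
be tied to ecological condition by a coupling coefficient in [−1, 1], NPP
as a sum of configurable linear/piecewise driver responses plus noise,
five service layers as distinct noisy transforms of NPP, moisture and
vegetation, and a multiplicative year-on-year drift in the human layers.
Climate covariates are scaled to realistic units (PET mean 800 mm,
sd 120 mm; temperature 0 ± 6 °C; precipitation 450 ± 90 mm) so planted
breakpoints sit inside natural ranges.

Presets:

* `negative_coupling` — coupling −0.8 on a 100×100 grid; the pressure
  layers are strongly anti-correlated with NPP, which propagates into a
  negative bivariate Moran's I between HAI and EHI.
* `null` — no coupling, no drift, homogeneous forest cover, correlation
  range 2 cells. Homogeneity matters: with any heterogeneous cover the
  disturbance score (high on construction/farmland) and the resilience
  and organization components (low on the same classes) are functions of
  one shared land-cover field, making the two indices structurally
  negatively coupled — no stochastic configuration can undo that. The
  short correlation range makes unit values approximately exchangeable
  after block aggregation, which permutation inference requires; with
  long-range smoothness the permutation null is anti-conservative for any
  implementation.
* `piecewise` — plants a PET response with slopes (−0.5, −1.0) at
  800 mm: a gentle decline steepening past the breakpoint, whose
  attribution sign crossing sits close to the kink (the 1:2 slope ratio
  halves the analytic offset described above) while preserving a clear
  nonlinear threshold. A symmetric peaked response would instead cross
  zero where the response passes its own mean, far from the kink.

What the scenarios do *not* emulate: real magnitudes and spatial grain of
any particular region, land-cover change over time (cover is held fixed
across years), seasonal dynamics, measurement error structure of remote-
sensing products, and administrative reporting units. Passing recovery
tests on these scenarios demonstrates that the machinery detects the
structures it claims to detect at realistic signal strengths — not that
any particular real-world estimate is correct.

## Numerical conventions and reproducibility

Min–max normalization of a constant column is degenerate; where a
constant is plausible (service indicators, HAI components, organization
metrics on uniform landscapes) it maps to 0.5 with a warning, elsewhere
it raises. Single-class landscapes take SHDI = 0, SHEI = 0,
CONTAG = 100, FRAC = 1 for single-cell patches (limit conventions).
Class-share sums, quadrant partitions and level shares are exact
partitions and always total 100%.

Every random draw descends from one global seed via stage-tagged hashes,
so each pipeline stage is independently reproducible and a staged run
(simulate → assess → couple → attribute) reproduces the monolithic run
exactly. Two runs under the same configuration and seed produce
byte-identical reports (verified by hash). Model fitting is
single-threaded for determinism.

Problem sizes used by the bundled verification runs — 100×100 grids,
625–2,500 analysis units, 20–50 scenario replicates, 999 permutations —
were chosen as the smallest sizes at which the statistical checks have
adequate power; all scale linearly if larger runs are wanted.

## Known limitations

* GeoTIFF support covers single-band rasters with nodata and a simple
  georeferencing payload; reprojection, multi-band imagery and
  cloud-optimized layouts are out of scope (ESRI ASCII is the text
  fallback).
* The organization index's published grouped weighting is internally
  inconsistent (group coefficients duplicate the sub-weight sums); the
  flat form is used by default and the grouped form kept only for
  comparison.
* The dependence-threshold estimator inherits the analytic offset of
  attribution sign crossings for asymmetric kinks; its bootstrap interval
  reflects sampling noise, not that bias.
* Permutation inference assumes exchangeable units under the null;
  strongly autocorrelated fields at the unit scale make it
  anti-conservative, as for any permutation-based Moran test.
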