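# Methods

This note documents the models and procedures implemented in `enmpipe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic validation does and does not demonstrate.

## The estimation problem

Given presence-only records of a species and co-registered environmental
raster stacks for a current and one or more future scenarios, the
pipeline estimates the area of environmental suitability (AES) per
scenario and the percentage change between them, together with an exact
significance test of whether the fitted models predict better than
random.  The regime of interest is *data-poor*: fewer than ~25 spatially
unique occurrence cells, where held-out test sets are not an option.

## Grids, distances, areas

All surfaces live on one regular WGS84 lon/lat grid (default 5 arc-min ≈
10 km at the equator); row 0 is northernmost.  Cells are half-open
(`[west, east) × (south, north]`), a convention that matters only for
records sitting exactly on cell edges.  Distances between cell centres
use the haversine formula with R = 6371 km; cell areas use the exact
spherical band `R²·Δλ·(sin φ_top − sin φ_bot)`.  Any cell that is NoData
in one layer is NoData everywhere downstream.

## PCA reduction and projection

Environmental variables mix incommensurate units, so both blocks (climate;
edaphic/topographic) are reduced by *correlation-matrix* PCA: standardise
each variable over valid cells, then eigendecompose.  Loadings' signs are
fixed (dominant element positive) for reproducibility.  Axis counts:

* `pca.climate.n_axes` — default **6** (the configuration used in
  published applications of this workflow, ~95% of climate variance);
* `pca.edaphic.n_axes` — default **2** (~66%);
* either may be `"broken_stick"`: retain the maximal leading run of axes
  whose eigenvalue proportion strictly exceeds
  `b_k = (1/p) Σ_{i=k..p} 1/i`, floor one axis.  Strictness and the
  leading-run stop are tie-rules chosen here; they only matter for
  degenerate spectra.

Future stacks are *projected*: standardised with the current means/sds and
multiplied by the current loadings (no re-fit), so axes correspond across
scenarios.  Edaphic axes are reused unchanged for every scenario — soils
and terrain do not move on a 50-year horizon.  Because the stored
transform is re-applied to its own training stack to produce the training
scores, the projection identity holds to machine precision.

## Pseudo-absences (disk arrangement)

Eligibility: a valid, non-presence cell whose distance to the *nearest*
presence cell centre lies in `[d_min, d_max]`; the defaults are the min
and max over all presence-pair distances, overridable in config.  Nearest-
presence (rather than all-presence) distance is the standard disk
semantics.  Draws are uniform without replacement, reproducible by seed.
Counts per learner family: GBM/CTA/RF match the presence count (the
standard recommendation for classification-tree methods under this
design); the six regression-type families use 10 000, capped at the
eligible-cell count with a warning (on desk-scale grids the cap always
binds, making the large sets identical across draws — an accepted
degeneracy of small grids).  If spread-out presences leave the annulus
empty, the lower bound is dropped with a warning so calibration can
proceed; the per-sample contract (error when `n` exceeds the eligible
count) is unchanged.

## Learner families

The registry maps each family to a scikit-learn estimator with fixed,
overridable defaults:

| family | implementation | notes |
|---|---|---|
| GBM | `GradientBoostingClassifier` (100 trees, depth 3) | |
| CTA | `DecisionTreeClassifier` | |
| RF | `RandomForestClassifier` (100 trees) | |
| GLM | scaled `LogisticRegression` | |
| GAM | cubic `SplineTransformer` (5 knots) + logistic | |
| MARS | linear `SplineTransformer` (5 knots) + logistic | hinge-like basis |
| ANN | scaled `MLPClassifier` (one hidden layer of 8) | |
| FDA | linear splines + `LinearDiscriminantAnalysis` (lsqr, shrinkage) | |
| MAXENT | linear+quadratic+interaction features + L1 logistic (saga, C=1, tol 1e-2, 100 iter) | documented approximation of Maxent's feature-class + regularisation design; re-implementing full Maxent is out of scope |

Two deliberate numerical choices:

* **Spline extrapolation is linear, not constant.**  Projected scenarios
  routinely push scores outside the training range; freezing the basis
  there ("clamping") overstates transferred suitability, so the basis
  continues linearly.
* **Class balance.**  For the 10 000-pseudo-absence designs, presences are
  up-weighted so total presence weight equals total background weight
  (weights normalised to mean 1 so solver tolerances are scale-free).
  MLP and LDA accept no sample weights; for them presence rows are
  deterministically replicated to the same effective balance.

Runs within a calibration reseed stochastic learners only; deterministic
families produce identical run-duplicates by design.  The ensemble is the
unweighted per-cell mean of all fitted members; individual failed fits
are skipped with a warning.

## Jackknife, threshold, exact test

For each of the *n* presence cells: remove it, re-derive the disk band
from the remaining cells (the left-out cell is also excluded from
pseudo-absence eligibility — no leakage), re-calibrate the full ensemble,
threshold the current-scenario surface at MaxSensSpec (candidates =
midpoints of adjacent distinct pooled scores plus the extremes 0 and 1;
ties to the smallest maximiser, i.e. the more inclusive map), binarise
every scenario at that replicate's threshold, and record

* `p_i` — area-weighted predicted-presence proportion of the replicate's
  current binary map (spherical areas, so high-latitude cells weigh less),
* `success_i` — whether the left-out cell is predicted present.

The test statistic is `D = Σ success_i` with exact p-value
`P(X ≥ D)` for `X = Σ Bernoulli(p_i)` (Poisson-binomial; DP convolution;
`P(X ≥ 0) = 1`, `P(X ≥ n) = Π p_i`).  Replicate-specific `p_i` differ, so
the heterogeneous form is the defensible default; a homogeneous-binomial
option (mean `p̄`) is available in config.  The test is one-sided
("better than random"); the report prints the exact p-value and `D`.

Negative scores for the threshold calibration are the replicate's pooled
pseudo-absence cells (one score per distinct cell) — the design leaves
open which negatives enter the ROC, and pooling uses every calibrated
background cell once.

## Consensus and change accounting

Only replicates that predicted their left-out cell contribute their
binary maps to the consensus; the frequency map (per-cell mean of
contributing maps) is always emitted, and the consensus cell is 1 where
the frequency reaches 0.5 (majority, ties to presence).  If no replicate
qualifies the run errors — a model that never predicts its held-out data
has no defensible consensus.  Loss% and gain% compare scenario area
totals; stable/lost/gained km² are cellwise.  Polygon overlap uses a
cell-centre-in-polygon test (no partial-cell weighting).

## The virtual-species generator

`generate_env` draws `latent_dim` (default 4) smooth climate factor
surfaces (random quadratic trend + Gaussian-smoothed noise, standardised)
and two edaphic factor surfaces, then mixes them linearly into 19
"climate" and 10 "edaphic" variables with independent noise (sd 0.3),
giving realistic within-block correlation.  The edaphic factors are
orthogonalised against the climate factors: soils and terrain are treated
as independent of the climate drivers, and without this, chance spatial
correlation between two random smooth fields lets static edaphic
predictors absorb the climate signal, collapsing projected change.

True suitability is `expit(intercept + w·latents)` — logistic in the
*latent* factors, not the observed variables, so the PCA step genuinely
has a signal subspace to recover.  Presences are drawn without
replacement with probability proportional to truth.  Future scenarios are
additive per-variable shifts in sd units; a shift derived from a latent
delta (`shift_for_latent_delta`) reproduces the shifted-latent world
exactly, so the true future suitable area — and the loss fraction a
scenario is calibrated to (`calibrate_latent_delta`, bisection) — is
known in closed form.

The reference species for recovery and power studies
(`strong_species`) has weight 8 on every climate factor (odds ratio e⁸
per latent sd — a steep, near-threshold response) and intercept −12
(suitable region ≈ the top fifth of the landscape): a rare, strongly
climate-determined species, the regime in which presence records carry
real signal.  `null_species` (weights 0) gives flat suitability and
uniform sampling for type-I studies.

## What the synthetic validation shows — and what it does not

On these fixtures the pipeline (reduced configuration: 3 families
GLM/MARS/MAXENT, 3 pseudo-absence sets, 2 runs, 60×60 grid, 20 presence
cells): recovers calibrated true losses of 20/50/80% within ±15
percentage points in most seeds (run-to-run spread of the reported loss
is ~10–14 points; the moderate fraction is the noisiest); keeps the
jackknife's false-significance rate under the nominal level on null
species; and detects the strong species with ≥90% power at n = 20.  The
modelled consensus AES is systematically *smaller* than the true
cutoff-0.5 region (the MaxSensSpec threshold sits near the lowest
training-presence score, inside the plateau), a conservatism that mostly
cancels in the loss ratio.

The generator does **not** emulate: spatial sampling bias in the
occurrence records, coordinate error, dispersal limits or biotic
interactions, temporal autocorrelation, non-linear (non-additive) climate
change, or non-stationary species–environment relationships.  Passing
these tests shows the machinery is correct and well calibrated under the
stated data-generating process — not that any real-data projection is
accurate.

## Problem sizes and runtime

Defaults mirror the published workflow (9 families × 10 pseudo-absence
sets × 10 runs = 900 models per jackknife replicate).  The shipped tests
and the acceptance script use reduced configurations (2–3 fast families,
2–3 sets, 1–2 runs, 30×60-cell grids) — sizes chosen so a complete
validation runs on one CPU in minutes while exercising every code path;
all of them are ordinary config values, and scaling up is a config edit.

## Known limitations

* Raster I/O is text ESRI ASCII grids only; reprojection/resampling to a
  common grid is a precondition, not a feature.
* MAXENT is an L1-regularised quadratic logistic approximation, not the
  Maxent program; FDA/MARS/GAM are spline-basis logistic/discriminant
  analogues of their R namesakes, not numerical ports.
* Jackknife inference treats replicate successes as independent; with
  heavily clustered presences the effective number of replicates is
  smaller than n.
* `fit`/`project`/`report` are one `run` command: each replicate's fitted
  models project the future scenarios in memory, and persisting hundreds
  of fitted models per replicate to split the stages would add cost
  without capability.
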