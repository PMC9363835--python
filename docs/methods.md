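# Methods

This note documents the models implemented in `yieldgap`, the defaults and
why they are set where they are, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Growing-season delineation

The season is defined thermally. For a county with ≥ 2 whole years of
daily weather, each day of year (DOY 1–365, Feb 29 dropped and later days
shifted so Mar 1 is always DOY 60) gets the probability

p(d) = (# years with (Tmax+Tmin)/2 − Tbase < 0 on DOY d) / n_years,

with Tbase = 5 °C, the temperature below which alfalfa stops meaningful
growth. The probability test uses the *untruncated* degree-day increment —
a negative value is precisely what marks a cold day — while accumulated
seasonal GDD truncates negatives at zero, as thermal-time accounting
requires. These are two deliberate readings of the same quantity.

The profile is ~1 in winter and 0 in midsummer. The algorithm anchors on
the longest midyear run of p = 0 (ties broken toward the earlier run, so a
brief "false spring" never wins), takes the spring limb from the last
p = 1 day before that run to the run's first day and the fall limb
symmetrically after it, fits each limb by least squares of p on DOY, and
reads the season start/end where the lines cross p = 0.2 (up to 2 cold
days in 10 years has negligible yield cost). Crossings are rounded
half-up; season length is end − start. A limb with fewer than two distinct
probability values falls back to linear interpolation between the days
bracketing the threshold. Degenerate profiles return sentinels instead of
fits: never-warm → `no_season`, never-cold → `year_round` (start 1, end
365). Raising the threshold can only widen the season (spring slope < 0,
fall slope > 0), which the tests assert.

## Frontier function (attainable yield)

County-year yields are plotted against growing-season rainfall (GSR), the
GSR range is cut into equal bins (default width 50 mm — the width is a
free constant of the procedure, so `optimum_sensitivity` reports the
optimum across 25/50/100 mm), and the maximum-yield point per bin becomes
a support point (yield ties keep the wetter point). The support is fit by
OLS in log space:

ln Ya = β₀ + β₁ ln X + β₂ (ln X)².

With β₂ < 0 the optimum GSR is X* = exp(−β₁/2β₂) and Ya(X*) is the
attainable yield. This is an envelope regression on binned maxima, not a
maximum-likelihood stochastic-frontier fit; no inefficiency distribution
is estimated. A fitted β₂ ≥ 0 is returned but flagged, and the pipeline
then maximizes the fitted curve over the observed GSR range ("edge
optimum") rather than extrapolating — on panels whose true water response
is linear with a plateau (the synthetic default) a monotone envelope is
the correct outcome, not an error. Zero-yield support points are dropped
before the log transform, counted and warned about.

## Boundary function (water-limited yield, WUE, water loss)

Yield responds to water only up to the rainfall bin containing the
globally best yield; bins above that cutoff (anchored at 0 mm, same
default width) sit on the flat or declining part of the envelope and are
excluded. Through the responsive-range bin maxima — optionally augmented,
unbinned, with variety-trial points, which are high-management yields that
extend the envelope upward — a straight line is fit:

Yw = slope · (GSR − WL),  WUE_pot = 1000 · slope [kg ha⁻¹ mm⁻¹],
WL = −intercept/slope [mm].

A non-positive slope (including float-noise slopes on exactly flat data,
guarded at 1e−9) raises a no-water-response error. A negative fitted WL is
physically impossible for a water loss; it is clamped to 0 with a warning
while the raw x-intercept stays available in `wl_raw`. Predictions floor
at zero below WL.

## Gap metrics

Yc is the mean survey yield; when harvested areas are reported, counties
are area-weighted within each year and the yearly means averaged
unweighted across years (the natural reading of a "weighted mean over the
last 10 years"; an unweighted fallback applies when areas are absent).
Gaps are YGa = Ya − Yc and YGw = Yw − Yc, with percentages relative to the
ceiling. A current yield above a ceiling produces a negative gap and a
warning, never a clamp. Mean realised WUE is the mean of per-county-year
ratios 1000·yield/GSR — not the ratio of means, which disagrees with the
reference table for two states and therefore cannot be what that table
reports. Internal values are kept at full precision; only report
serialization rounds (half-up: yields to 0.1 Mg ha⁻¹, percentages to
integers).

## Conditional-inference tree

At each node every covariate is tested against the response with a
permutation test of |Pearson r|; the p-value is the exact-style
(1 + #{|r*| ≥ |r|})/(1 + n_perm), which is never zero and uniform on its
lattice under the null. Bonferroni multiplies by the number of covariates.
If the smallest adjusted p is below α (default 0.05) the node splits on
that covariate at the midpoint-threshold maximizing the standardized
two-sample mean difference |ȳ_L − ȳ_R| / (s_p √(1/n_L + 1/n_R)), with a
zero pooled SD and unequal means scoring infinity, ties keeping the
smaller threshold, and both children obliged to hold ≥ min_leaf_frac·n
rows (default 1 %); nodes below min_node_frac·n (default 5 %) are never
split. Rows equal to the threshold go left. Defaults: n_perm = 9999,
α = 0.05. This instantiation uses the simple correlation statistic and
Bonferroni rather than the full linear-statistic/min-p machinery of the
reference CIT framework — for a numeric-covariate regression tree the two
coincide in what they protect against (variable-selection bias and
overfitting), and the permutation null is exact either way.

Every node's test stream is spawned deterministically from the config seed
(numpy `SeedSequence`), so a fixed seed gives a bit-identical tree.

Parsimony selection refits the tree over the grid
min_node_frac ∈ {0.05, 0.10, 0.20, 0.40} × min_leaf_frac ∈ {0.01, 0.05,
0.10} (leaf ≤ node) and keeps the candidate with fewest leaves whose
training R² is within 5 % of the (0.05, 0.01) baseline's, ties preferring
the larger leaf fraction. Selection by smallest adjusted p at each node is
equivalent to the lowest-RMSE/highest-R² covariate for a single binary
split, which resolves the apparent ambiguity between test-based and
fit-based variable selection.

## Synthetic data

The generator reproduces the structure the analysis assumes, with known
truth:

- **Temperature** — Tmean(d) = μ − A·cos(2π(d − φ)/365) + AR(1) noise;
  defaults μ = 12 °C, A = 15 °C, φ = DOY 15 (coldest mid-January),
  marginal noise SD 2 °C, persistence 0.7 (day-to-day weather is
  autocorrelated; delineation should be tested under persistence, not
  i.i.d. noise). Tmax/Tmin sit ± 5 °C around Tmean (fixed 10 °C diurnal
  range). Counties receive seeded offsets of ±1.5 °C in the annual mean.
- **Rainfall** — two-state Markov occurrence (P(wet|dry) = 0.25,
  P(wet|wet) = 0.50, stationary wet probability 1/3) with gamma wet-day
  amounts (shape 0.7, scale 13 mm → mean wet-day 9.1 mm, mean daily
  3.03 mm). Over a ~220-day delineated season this yields a mean GSR near
  670 mm — the center of the humid-continental range the analysis
  targets — with county-to-county spread from seeded perturbations of the
  wet probability (±0.03) and scale (±10 %).
- **Yields** — potential = min(ceiling, WUE/1000 · max(0, GSR − WL)) with
  defaults WUE = 28 kg ha⁻¹ mm⁻¹, WL = 150 mm, ceiling 25 Mg ha⁻¹;
  observed = potential × efficiency, efficiency ~ Beta(4, 2) (mean 2/3)
  clipped into (0, 1], with 5 % of county-years forced into [0.98, 1].
  Without that near-frontier subset, bin maxima are the maximum of a few
  Beta draws and sit systematically below the true envelope, biasing both
  envelope fits; with it, the support points trace the truth.
  `efficiency_beta = 0` collapses efficiency to exactly 1 (noise-free
  limit used in tests). A separate helper generates panels whose true
  envelope is log-quadratic, for frontier-recovery checks.

What the generator does **not** emulate: spatially correlated rainfall
fields, trends or teleconnections, measurement error in survey yields,
within-season rainfall timing (only the total matters here), or
management covariates. Passing tests therefore demonstrate that the
procedures recover the parameters of data satisfying the model's own
assumptions at realistic sample sizes — not that those assumptions hold
for any particular real region.

## Problem sizes and tolerances

- Envelope parameter recovery is checked at n = 400 county-years
  (boundary: potential WUE within 10 %, WL within 25 mm; frontier:
  optimum GSR within 10 %), sizes at which the bin-maxima support is
  dense enough for stable envelopes.
- The fixture bundle is deliberately tiny (3 counties × 10 years = 30
  county-years) so every file stays human-readable; at that size the
  boundary estimate carries substantial sampling noise (relative WUE
  errors up to ~35 % across seeds), so the fixture integration test uses
  correspondingly loose bounds (40 % / 160 mm) and the tight claims live
  in the n = 400 checks.
- Season delineation against the closed-form normal-CDF crossing uses 10
  years of i.i.d.-noise weather and a ±5-day band: with n = 10 the
  probability profile has resolution 0.1, which moves the fitted crossing
  by a few days.
- Permutation-test calibration: 500 null replicates at n_perm = 999; the
  lattice rejection probability at α = 0.05 is 49/1000, and the observed
  rate is required in [0.03, 0.07].
- The null-tree check (100 replicates, 4 covariates) requires a single
  leaf in ≥ 90 % of replicates; the Bonferroni-gated familywise split
  probability is just under α.

## Reference dataset

`yieldgap.datasets.load_state_summary()` ships the published state-level
estimates (12 rainfed states, 2009–2018) used by the worked example and
the acceptance script. Two obvious misprints are corrected (a season
length printed "21" restored to end − start = 215; a column mean printed
"110" read as 11.0). Some printed percentages were computed from already-
rounded intermediates (e.g. a gap of 12.7 printed as 12.8 yields 66 %
rather than the recomputed 65 %); recomputations here use full precision
and the tests allow that 1-point discrepancy where it occurs.

## Known limitations

- The boundary and frontier are envelope estimators: they are sensitive
  to the single best observation per bin, and no uncertainty is attached
  to WUE_pot, WL or X*. Bootstrap intervals would be a natural extension.
- The frontier's log-quadratic form cannot represent a hard plateau;
  monotone envelopes surface as edge optima rather than as a plateau
  breakpoint.
- The CIT handles numeric covariates only — no missing values, no
  surrogate splits, no categorical predictors.
- Weather gap-filling substitutes whole days from donor stations; it does
  not interpolate, and it assumes donor and target climates are
  exchangeable at the daily scale.
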