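# Methods

## Threshold diffusion model and program accounting

Producers hold net returns $r_{i,t} = r_i + L_t$ with $r_i \sim
N(\mu,\sigma^2)$ i.i.d. within a county and $L_t$ a common exogenous path;
adoption occurs when $r_{i,t} > 0$, so the county share in period $t$ is
$\Phi((\mu+L_t)/\sigma)$. Adoption shares are computed from the marginal
distribution each period. When $\mu + L_t$ is non-decreasing this
coincides with cumulative (absorbing) adoption; declining paths are
supported and read as dis-adoption. With $\sigma = 0$ the share
degenerates to the indicator $\mathbb{1}[\mu + L_t > 0]$ — handled, not an
error. $\sigma$ defaults to 1 and the distribution is Gaussian only; the
qualitative dynamics require only unimodality, so other families would be
a straightforward extension, but none is implemented.

A program paying incentive $P$ for adoption during window $(t_0, t_1)$
produces, pre-rounding, these exact identities:

- enrollee share $= \Phi((\mu+L_{t_1}+P)/\sigma) - \Phi((\mu+L_{t_0})/\sigma)$,
- non-additional share $= \Phi((\mu+L_{t_1})/\sigma) - \Phi((\mu+L_{t_0})/\sigma)$,
- additional share = enrollee − non-additional,

each floored at 0 (with a `clamped_negative` flag and a warning) when the
path declines by more than the incentive restores; flooring keeps county
sweeps total rather than aborting. Credits are issued per enrollee
(`credits = enrollees × s`), additional tons per additional adopter, so
`credits ≥ additional_tons` always.

**Rounding.** The conventional presentation of the two-county illustration
quotes whole-percent shares on a 1000-producer county; dollar figures like
$130/320 = \$0.41$ and $112.5/90 = \$1.25$ only emerge under that
convention. `RoundingPolicy` makes it explicit: `exact` (default) keeps
real-valued counts; `nearest_percent` rounds each share to the nearest
0.01, ties away from zero, before multiplying by population. Reported
figures are rounded half-away-from-zero (`round_half_away`), matching how
$112.5/180 = 0.625$ prints as $0.63$; banker's rounding would print 0.62.

The agent-based `simulate_agents` applies the same rules producer by
producer on seeded Normal draws; it serves as an independent sampling
check on the closed form (binomial error $\propto n^{-1/2}$; tests and the
acceptance script use a 4-standard-error band at $n = 10^6$).

`rank_counties` sorts ascending on cost metrics and descending on quality,
stable, ties broken by county id; undefined (NaN, zero-denominator)
metrics sort last and carry an explanatory note.

## Synthetic county panels

The generator emulates the statistical structure of the real inputs
(census practice acreage for two waves, daily weather, static soils,
program obligations, per-scenario sequestration rates) without any
geographic realism. Defaults — the conditions under which the test suite
and examples run — are 500 counties, census waves 2012/2017 with a
held-out 2022 wave, daily weather 1997–2022, producer-level $\sigma = 1$.

- **Latent returns.** Per practice, $\mu_c$ is a stated linear function of
  six standardized soil covariates and two latent climate axes
  (temperature, wetness) plus Gaussian noise. Intercepts put cover-crop
  shares at a few percent and reduced-till shares near 40%, both drifting
  upward between waves ($L$ increments 0.15 / 0.12 per wave).
- **County adoption trend.** A county-specific drift (intercept −0.08 /
  −0.06, wetness loading 0.15 / 0.10, sd 0.20 / 0.18 for cover / tillage)
  is added to $L$ per period. This reproduces two documented features of
  the real panels: county log acreage ratios between censuses routinely
  reach ±0.5, and dis-adopting (negative-rate) counties are widespread —
  dry counties disproportionately so for cover crops. Without it the
  negative rate interval would be empty and the classification
  degenerate.
- **Census tables.** Producer returns are drawn once per county-practice
  and threshold-crossed per wave, so shares match
  $\Phi((\mu+L_w)/\sigma)$ within binomial error (the generator's tie to
  the model as oracle). Acres = share × cropland × lognormal noise
  (sd 0.05); the multiplicative form keeps acres positive so log-ratio
  targets are defined. Reduced-till acres are split into no-till and
  conservation-till parts by a per-county fraction. One producer ≈ equal
  acreage; no farm-size modelling. Missingness is MCAR at 5% per
  county-wave-practice cell, with an optional small-county-biased mode
  mimicking disclosure suppression. The third wave lives only in the
  truth table.
- **Weather.** Daily temperature = county mean + seasonal sinusoid
  (trough mid-January) + N(0,3) noise; Tmax/Tmin bracket it by a strictly
  positive half-range, so Tmax ≥ Tmin by construction. Precipitation is
  Bernoulli-wet × gamma amounts. No spatial correlation between counties
  beyond shared seasonality and no AR structure in time — sufficient for
  testing the aggregation stages, but it understates the year-to-year
  persistence real deviations have, so passing tests say nothing about
  weather-feature predictive power in real data.
- **Programs.** Obligations (county × year × measure, 2014–2022) carry
  heavier missingness on the practice-specific measures (25%) than the
  all-programs total (2%). The sequestration table holds two
  single-practice scenarios per practice per county, jittered N(0, 0.05)
  around the county's true rate, plus joint-adoption rows flagged
  `joint=True` for exclusion.

Everything is deterministic given (config, seed); `write_fixture_bundle`
writes byte-identical CSVs on regeneration and a manifest with a config
hash and per-file SHA-256.

## Feature construction

- **Shares.** Per county, the share denominator is the maximum cropland
  acres across the two waves, applied to both waves; reduced till = no-till
  + conservation tillage. The share denominator uses the *raw* maximum
  acres; the log transform enters separately through the
  `log_lagged_acres` predictor (the alternative reading — a
  log-transformed denominator — is noted in the design-matrix manifest).
- **Cropland filter.** Counties at or below the 10th percentile (linear
  interpolation) of cropland-to-land-area are dropped, boundary ties
  included; all-identical ratios drop everything and are flagged
  pathological; under 10 counties the filter is skipped with a warning.
- **Temperature exposure.** Daily index temperature = (Tmax+Tmin)/2 by
  default (a `tmax` basis is a config switch); bins are half-open
  $(-\infty,0), [0,10), [10,20), [20,30), [30,\infty)$ °C — 30.0 °C counts
  as extreme heat — crossed with seasons pre (Jan 1–end Feb), growing
  (Mar 1–Aug 31), post (Sep 1–Dec 31). Days missing the index temperature
  are tallied, never imputed. Season day counts conserve the calendar
  (365/366).
- **Normals and deviations.** The climate normal is the mean over the 20
  calendar years strictly before the census year; the weather deviation is
  the mean of (annual − normal) over the five years ending at and
  including the census year (2013–2017 for the 2017 wave). Whether the
  deviation window should instead start at the earlier census year is
  ambiguous; this package's convention is as stated and is applied
  consistently to training and prediction periods.
- **Obligations.** Three measures (all-programs, cover-crop, tillage
  practices), each divided by the county's maximum cropland acres and
  averaged over a year window — 2014–2017 for training, 2018–2022 for
  prediction (the five post-census years, mirroring the deviation-window
  convention). Missing annual cells are excluded from the mean with a
  count recorded; an all-missing measure stays missing and receives a
  missingness-indicator column at fit time rather than a zero fill.
- **Design matrix.** Lagged share, log lagged acres, 15 temperature-bin
  normals + 3 precipitation normals, the 18 matching deviations, soils,
  3 obligation measures, one-hot region codes. Rows with non-positive
  lagged (or, in training, current) acres are dropped and logged; a
  sidecar JSON manifest records columns and drops.

## Honest regression forest

Hand-authored, since honesty is the load-bearing feature. Per tree: a
without-replacement subsample of `sample_fraction · n` rows is split into
a split half (`honesty_fraction`, default 0.8) that chooses the recursive
partition and an estimation half whose outcomes alone populate leaf
means. At each node `mtry` predictors are drawn; the best split maximises
the split-half variance reduction minus `imbalance_penalty · (1/n_L +
1/n_R)`, subject to each child receiving ≥ `alpha` of the node's
split-half points and ≥ `min_node_size` estimation-half points. Splits at
midpoints of consecutive distinct values; a node with no admissible
positive-score split becomes a leaf. This splitting objective is this
package's concrete contract, documented as such rather than as a clone of
any particular implementation. Fitting refuses configurations whose
estimation half cannot satisfy `min_node_size` at the root.

Reference parameter sets are provided per practice (tillage:
sample_fraction 0.38, mtry 10, min_node_size 3, alpha 0.08,
imbalance_penalty 0.72; cover: 0.45 / 7 / 7 / 0.14 / 0.36), 2000 trees by
default; all overridable from the pipeline config. No automatic
hyperparameter tuning is performed. These parameters assume training sets
of several hundred rows; much below that the 20% estimation halves starve
and predictions over-shrink (the fitting guard catches the extreme case).

Missing predictor cells are median-imputed (training medians) with a
companion `<col>_missing` indicator column, preserving signal in
structured missingness. Out-of-bag predictions average only trees whose
subsample excluded the row; rows with no eligible tree are NaN and
counted. Determinism: one `numpy` Generator seeded from the config drives
subsampling, honesty splits and per-node feature draws sequentially.

**Importance and iterative selection.** Split-frequency importance weights
each split by 1/depth over the top four levels, normalised to sum 1 — a
deterministic, scale-free reading of "most frequently used to make
splits". Stage 1 fits all $p$ predictors; predictors with importance
≥ 1/p (indicator columns credited to their parent) are retained; if none
clear the bar the top ⌈p/4⌉ are kept with a warning. Stage 2 refits on the
retained set with a seed offset and the same parameters (re-tuning between
stages is deliberately not done).

**Calibration test.** OLS of the outcome on two regressors without
intercept — the overall mean OOB prediction (constant) and the demeaned
OOB prediction — with HC3 heteroskedasticity-robust standard errors (the
robust flavour is this package's choice) and one-sided p-values.
Coefficients near 1 mean the average level is right and predicted
heterogeneity tracks outcome heterogeneity one-for-one. Zero-variance
predictions make the differential coefficient undefined (flagged, NaN).

On the synthetic fixture the honest forest's differential coefficient
runs slightly above 1 (typically 1.1–1.3): honest leaf means shrink
prediction spread, and the regression slope compensates. The test-suite
criterion — both coefficients inside their 95% CIs of 1 in ≥ 90% of 20
seeded replicates at 500 counties / 20 predictors / 200 trees — reflects
that behaviour; the tree count and replicate sizes were chosen to keep the
whole suite fast while leaving the statistical conclusions stable.

## Targeting classification

Sequestration per practice is the mean of non-joint scenarios (tillage
pools the no-till/strip-till and reduced-till standards, CPS 329 + 345;
cover-cropping uses CPS 340); joint-adoption scenarios are excluded
because their rates are not attributable to a single practice. Terciles
use 1/3 and 2/3 quantiles (linear interpolation, right-closed intervals)
over counties surviving upstream filters, per practice — conventions fixed
so class counts are bit-reproducible. Rate intervals: `neg` for predicted
log ratios ≤ 0 (zero is grouped with the negatives to keep the intervals
exhaustive), then `low_pos`/`high_pos` split at the median positive value,
right-closed. The 3 × 3 cross yields codes `<interval>|T<tercile>`; the
four corners carry the quadrant labels (inefficient, cheap-low-quality,
expensive-additional, cost-effective). Counties missing either input get
missing markers, never silent drops. A cross-practice join of the two
classification tables is possible from the exports, but no joint-adoption
model is implemented.

## Pipeline and reproducibility

A single YAML config (validated; unknown keys rejected by name) drives
features → train → predict → classify; stages are restartable from their
predecessors' files. All interchange is plain CSV with documented headers;
the geometry input is a county-id stub for joining map attributes, and no
cartographic rendering is done. Every exclusion (missing acres,
non-positive acres, cropland decile, missing features) is logged with a
reason code and count in `run_log.jsonl`. Reruns with the same config are
byte-identical; the test suite asserts this on hashes.

Problem sizes used by the tests and examples — 150–500 counties, 26
weather years, 60–200 trees, 20 calibration replicates — are the package's
reduced-scale defaults for fast, deterministic verification; the code
itself has no such limits.

## Known limitations

- Forest predictions carry no variance estimates (no asymptotic theory is
  implemented); the calibration test is the only fit diagnostic.
- The calibration-coverage and recovery results on synthetic data do not
  transfer to real census data: the generator's linear latent structure,
  MCAR missingness and spatially independent weather are all favourable
  simplifications.
- The conceptual model's cross-county comparisons assume the common
  return path $L_t$ evolves identically across counties; the synthetic
  generator deliberately violates this with county trends (as real data
  would), and the forecasting stage does not rely on the assumption.
- Only Gaussian producer returns; no endogenous $L_t$ dynamics; no
  within-county sub-targeting; no map rendering.
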