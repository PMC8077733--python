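# Methods

## Problem and model

`heatlogic` estimates *outcome-specific* definitions of extreme-heat exposure
from daily health counts. An exposure definition is a Boolean rule
H(**X**_t) over binary indicators X_1, …, X_{L+1}, where X_{ℓ+1} flags that a
daily heat metric on day t−ℓ strictly exceeded a percentile threshold
(default lags 0–3). Rules are represented as *logic trees*: full binary
trees whose internal nodes carry AND/OR and whose leaves are possibly
NOT-ed indicators. This captures threshold, duration and lag structure in
one interpretable binary exposure (e.g. `lag0 AND lag1` = two consecutive
extreme days ending today).

Daily counts Y_t are modelled with a quasi-Poisson log-linear time-series
model,

    ln μ_t = β₀ + β·H(X_t) + ns(T_t) + ns(T̄_t) + ns(DPT_t)
             + α₀,year + f(date)×α₁,year + Σ λ_i DOW_ti + Σ δ_j HOLIDAY_tj
             + Σ γ_k HOSPITAL_tk ,      var(Y_t) = φ·μ_t,

where T_t is the same-day heat metric truncated at the extreme threshold,
T̄_t the mean of the truncated metric over lags 1–3, DPT_t the same-day
maximum dew point (omitted when the metric is apparent temperature, which
already encodes humidity), `ns` a natural cubic spline with 2 equidistant
internal knots, and f(date) a within-season spline with monthly knots
(Jun 1 … Sep 1) interacted with year. Truncation makes β interpretable as
the log relative risk of the extreme event itself: the continuous terms
carry no information above the threshold. With truncation off, β is the
*added* effect beyond the continuous exposure–response curve.

Estimation is a three-stage procedure:

1. **Base fit.** The model is fitted *without* H (IRLS via statsmodels,
   Pearson dispersion φ = χ²_P/(n−p)). Pearson residuals
   r_t = (Y_t − μ̂_t)/√(φ μ̂_t) carry whatever extreme-heat signal the
   smooth terms did not absorb.
2. **Logic regression on residuals.** The tree minimising the residual sum
   of squares of the least-squares fit of r_t on (1, H(X_t)) is sought by
   simulated annealing; 10-fold cross-validation selects the number of
   leaves (candidates 0–3 by default, 0 = no exposure). The returned tree
   is re-oriented so exposed days are the minority (the complement of a
   tree yields an identical least-squares fit with negated slope, so
   orientation is a reporting convention, resolved by day frequency).
3. **Refit.** The full model is refitted with the learned H; RR = exp(β̂)
   with a 95% Wald CI using the φ-scaled covariance.

A grid over the six heat metrics (max/min/mean of dry-bulb or apparent
temperature) × three percentiles (95/98/99) repeats the three stages per
cell; the cell with the smallest QAIC = deviance/φ + 2p is reported. Ties
go to fewer exposed days, then lexicographic metric order. Each cell's
annealing is seeded from (master seed, metric, percentile) so cells are
reproducible in isolation. Each model is compared on its own φ by default;
a shared φ from a reference fit can be passed explicitly to `qaic`.

## Search: moves, cooling, exhaustive oracle

The annealer uses the classical seven-move neighbourhood (alternate leaf,
complement leaf, alternate operator, grow branch, prune branch, split leaf,
delete leaf), uniform over applicable move types, with Metropolis acceptance
min{1, exp(−Δrss/temperature)} and geometric cooling. Start/end temperatures
are auto-calibrated from the median uphill Δrss of a short random walk so
that a typical uphill move is accepted with probability ≈0.9 initially and
≈10⁻³ terminally; both can be overridden. The best tree ever visited (across
restarts) is returned; score ties break toward the lexicographically
smallest canonical DNF, making results deterministic given the seed.

For small instances (k ≤ 4 predictors, ≤ 3 leaves) an exhaustive enumerator
builds every representable Boolean function by dynamic programming on leaf
count and returns the true RSS optimum. It exists as an independent check
on the annealer, never as the production path.

Canonicalisation is by disjunctive normal form: distributive expansion,
removal of contradictory clauses, deduplication, absorption, sorted literal
and clause order. Equivalence of two trees is decided by exhaustive truth
tables (k ≤ 20).

## Synthetic data

Real ED-visit series are protected, so the package ships a generator used
by all study-scale tests.

**Weather.** Hourly dry-bulb temperature over full calendar years: annual
sinusoid (mean 17 °C, amplitude 10.5 °C, peak mid-July) + stationary AR(1)
daily anomaly (ρ = 0.75, SD 2.4 °C) + diurnal sinusoid (amplitude 5 °C,
minimum ~05:00) + noise; dew point sits below dry bulb by a slowly varying
positive gap (mean 6 °C). Percentile thresholds are computed over the *full*
record; because the seasonal swing dwarfs the anomaly SD, essentially all
top-2% days fall in the warm season, so ~2% of 7305 days ≈ 146 lag-0
exceedance days per 20 warm seasons, and the AR(1) clustering yields ≈70
two-day (E2) and ≈30 lagged-pair (E3) days. These frequencies — not any
test outcome — are the calibration target, since statistical power in this
problem is governed by exposure frequency.

**Counts.** Y_t ~ NegBin with mean μ_t·exp(log RR·H_t) and variance φ·μ_t
(size μ/(φ−1); φ=1 is Poisson), matching the quasi-Poisson variance
function so φ is recoverable by the fit. The log-mean combines a seasonal
sinusoid, a log-linear secular year trend, day-of-week and holiday offsets
and a linear response to the truncated heat metric, scaled so the
warm-season average equals the profile's baseline. Three profiles are
provided: circulatory-like (623/day, φ=2.0), renal-like (139/day, φ=1.5)
and heat-illness-like (2.5/day, φ=1.2). The baselines are public summary
statistics of the motivating Atlanta record; the dispersions and effect
sizes are the package's own choices of plausible ED-count structure, fixed
once. Planted scenarios: E1 H=X₁ (same-day), E2 H=X₁∧X₂ (two-day),
E3 H=X₁ᶜ∧X₂∧X₃ (lagged-only pair), over ATMN (daily minimum apparent
temperature) at the 98th percentile.

What the generator does *not* emulate: spatial structure, weather-record
gaps and measurement error, hospital-availability drops (the design accepts
such indicators but the generator emits none), long-memory temperature
regimes, and outcome-specific residual autocorrelation beyond what the
covariates induce. Passing tests therefore demonstrate correctness of the
procedure under a realistic but idealised data-generating process, not
performance guarantees on any particular city's data.

## Simulation study

For each scenario × RR × profile, one weather realisation is generated and
reused across replicates (mimicking a single observed record); counts are
redrawn per replicate from independent seeded streams. Two arms are run:
the full three-stage pipeline (grid fixed to the truth metric/threshold,
as the exposure-structure question is the lag/duration rule), and a
known-H comparator that skips stage 2 and injects the truth tree. Reported
per row: day-level sensitivity and specificity of the recovered
classification (per replicate, then averaged), relative bias
mean(RR̂−RR)/RR and RRMSE √(mean((RR̂−RR)²))/RR for both arms, and CI
coverage of the known arm. When cross-validation selects the null model
the replicate contributes RR̂ = 1 (no effect found) and an all-unexposed
classification; this convention keeps the bias metrics defined and is the
source of the attenuation-toward-null behaviour at weak signal.

Default study sizes in the shipped tests and acceptance script: 20
replicates, 20-year weather, annealing reduced to 2 000 iterations per CV
fold and 5 000 (3 restarts) for the final fit. These sizes keep a full
scenario under ~2 minutes while leaving the strong-signal (RR 1.05,
high-count) recovery essentially deterministic.

## Numerical choices and edge cases

- Quantiles: linear interpolation between order statistics (type 7),
  bit-reproducible.
- Exceedance is strict (`value > threshold`); ties are non-extreme.
- Daily metrics require ≥ 18 of 24 hourly values, else missing.
- Lagged indicators for early-season days use the preceding calendar days
  (April data); thresholds and model rows remain as configured.
- IRLS convergence: statsmodels default criteria, tol 10⁻¹⁰, 100
  iterations; non-convergence raises.
- A constant tree output scores as the centred total sum of squares with
  zero slope; all-zero learned exposures are reported as null findings,
  never errors.
- Reference levels: first year and Sunday. All-zero indicator columns are
  dropped with a warning; rank deficiency raises.
- Missing values propagate: a row with NaN at any index a tree references
  evaluates to NaN and is excluded from scoring.

## Known limitations

- Stage-3 confidence intervals ignore the uncertainty of the learned tree
  (exposure estimated on the same data); coverage statements apply to the
  known-H arm.
- Single-tree models only; no multiple-tree or penalised variants.
- CV folds are random days, not contiguous blocks, which is mildly
  optimistic under residual autocorrelation; blocked folds would be the
  conservative alternative.
- The exhaustive oracle is limited to k ≤ 4, ≤ 3 leaves; beyond that the
  annealer is checked only by internal invariants.
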