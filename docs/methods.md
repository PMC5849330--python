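# Methods

## Data model and exclusion protocol

The unit of observation is the *surface–dive cycle*: one surfacing interval
(at least one member of a tracked group visible at or near the surface,
duration sᵢ) followed by one diving interval (no member visible, dᵢ). Cycles
are grouped into sessions, one per tracked group, carrying the group's
covariates: group size (1–7, classed *small* ≤ 4 / *large* ≥ 5), presence of
calves, water depth (m), water transparency (cm) and tide level (m). A
record begins at the group's first dive — the first post-sighting surface
interval cannot be timed from its true start and would bias E(s) downward,
so the CSV reader rejects rows flagged `first_interval`.

Filtering drops (1) cycles where a disturbance reaction to the platform was
noted, then (2) cycles outside the kept tracking-confidence classes
(default: high only). A cycle failing both rules counts against the reaction
rule, so cycle accounting is exact: kept + reaction + confidence = input.
Groups left with no cycles are removed from group counts. Surviving cycles
are re-indexed contiguously, which makes filtering idempotent; the AR-1 lag
below is therefore defined on the *post-filter* cycle order.

Dispersion fields in summaries are sample standard deviations over pooled
cycles. (The source tables label these "SE"; at n = 248 a standard error of
the mean would be ~0.6 s, far from the printed 9.74, so they are SDs and are
stored as such.) E(s) and E(d) are pooled over cycles rather than averaged
per group: the availability formula consumes mean interval times, and group
structure is honoured by the bootstrap instead.

## Availability estimators

* **Forward-looking estimator** (Laake-style):
  Pr = [E(s) + E(d)(1 − e^(−w/E(d)))]/(E(s)+E(d)). Monotone nondecreasing in
  the window w and bounded by [E(s)/(E(s)+E(d)), 1].
* **Additive comparator** (Barlow-style): Pr = (E(s)+w)/(E(s)+E(d)), capped
  at 1 with a warning. Used only for re-computing the historical
  surface-platform corrections, which were built with this form (the 7 s
  window of those studies is taken as a given input).
* **Time-in-view window**: w(x) = √(r² − x²)/v — the time a point at
  perpendicular distance x stays inside the view circle of radius r crossed
  at speed v. The minus sign is the geometrically meaningful choice (time in
  view must shrink toward the edge of the view area, and r = 300 m,
  v = 50 m/s, x = 0 must give 6 s); availability is evaluated at x = 0 by
  default. The window can be overridden numerically everywhere.

**Bootstrap.** Groups (not cycles) are resampled with replacement to the
original group count; each replicate pools all cycles of the drawn groups
(duplicates counted multiply) and re-applies the estimator. The replicate SD
is the SE and the 2.5/97.5 percentiles give the 95% CI. A single
`numpy.random.default_rng(seed)` drives each run and the seed is recorded in
the output; a fixed seed gives a bit-identical distribution.

**Renewal oracle.** `renewal_oracle` validates the analytic estimator by
brute force: it simulates one long alternating renewal trajectory with
exponential surface and dive phases and places observation windows at
uniform random interior times. Under exponential dives the closed form is
exact — P(unavailable) = [E(d)/(E(s)+E(d))]·e^(−w/E(d)) by memorylessness —
so the empirical availability must match within Monte-Carlo error. The
oracle shares no code with the estimator. Windows drawn from one shared
realization are weakly dependent, so tests use a slightly inflated
binomial-SE tolerance.

## Mixed-effects models on the proportion at surface

Response: natural log of the per-cycle proportion sᵢ/(sᵢ+dᵢ) (the log
stabilises the variance of a positive, right-skewed ratio; the source
analysis states only "log-transformed", and the natural log is adopted).
Each candidate model has a group random intercept and, by default, AR-1
residual correlation on the cycle order within a group (unit lag spacing —
no timestamps exist). Marginally, a group's covariance is
σ²_group·J + σ²_resid·R(φ) with R_ij = φ^|i−j|; ARMA(p,q) structures with
p ∈ {1,2}, q ∈ {0,1} are available through the stationary autocorrelation
function.

Estimation is **maximum likelihood**, not REML: AIC comparisons across
different fixed-effect structures are only valid under ML. The fixed effects
and the residual scale are profiled out analytically (per-group Cholesky
solves, one factorisation per distinct group size), leaving a 1–4 parameter
optimisation over (log variance ratio, tanh-transformed φ / raw ARMA
coefficients) solved by Nelder–Mead (xatol 1e-6, fatol 1e-8). Nonstationary
ARMA proposals are rejected with a penalty value. The parameter count k is
intercept + fixed effects + 2 variance components + correlation parameters.
The implementation is cross-checked in the test suite against R's
`nlme::lme` with `corAR1` (agreement to ≤1e-3 on log-likelihood, AIC,
coefficients, variance components and φ).

All 2⁵ = 32 predictor subsets (group-size class, calves, depth,
transparency, tide; continuous covariates unstandardised) are fitted with
the AR-1 structure, after an explicit AIC comparison of the global model
with and without AR-1. Akaike weights w_i = e^(−Δᵢ/2)/Σe^(−Δⱼ/2) give each
variable's relative importance (sum of weights of models containing it) and
model-averaged coefficients. Averaging defaults to the **full** convention —
a coefficient is 0 in models omitting its predictor — because it shrinks
weakly supported effects toward zero, which is what tiny averaged
coefficients in the source tables imply; conditional averaging is available
behind a flag. Unconditional SEs use the Burnham–Anderson form
Σ w_i √(var_i + (β_i − β̄)²). Non-converged fits are dropped from the weight
normalisation with a warning.

## Synthetic generator

`simulate.generate` draws, per group: a size from a distribution on 1–7
(mean 2.92, ~9% large), calves with p = 0.26, covariates uniform over the
study ranges, and a surviving-cycle count 1 + Poisson(mean − 1) capped at
10 (mean 2.45). Per cycle it draws a total duration t from a lognormal with
mean 55.87 s and SD √(9.74² + 29.06²), truncated to the study's range sums,
and a log proportion lp from the mixed model
μ + β_large·I(large) + b_group + AR-1(φ) noise, then splits
s = t·e^lp, d = t − s (clipped into the published per-phase ranges). The
intercept μ is derived analytically from the configured means, the
log-normal variance correction and the small/large mixture, so E[s] tracks
the configured 16.10 s for any variance setting. Defaults: β_large = 0.44,
σ_group = 0.30, σ_resid = 0.50, φ = 0.35 (variances chosen to match the
observed spread of the log proportion; φ set to the moderate positive
serial correlation the study design implies). Reaction and low-confidence
flags are per-cycle Bernoulli with the study's 6/337 and 83/337 rates.

Generating lp directly (rather than imposing structure on s and d
separately) makes the fitted response model *exactly* the generating model,
so parameter recovery is a meaningful end-to-end check. The trade-off: the
marginal SDs of s and d are only approximately the study's, and s and d are
positively dependent through t. What passing tests show is that the
pipeline recovers known structure of this form; they cannot certify
behaviour on features real data might add (duration–covariate interactions,
non-lognormal tails, observer-specific timing error).

## The packaged fixture

The study deposited no raw records, so `data/fixture_cycles.csv` is a
synthetic stand-in built by a deterministic recipe (`fixture.build_fixture`,
embedded seed, regenerated only by `analysis/01_build_fixture.py`; a test
asserts the shipped file equals the recipe output byte-for-value). The
calibration solves for what is published and leaves everything else to the
seeded draws:

* 337 cycles / 120 groups; 6 reaction and 83 moderate/low-confidence cycles
  placed so filtering yields exactly 248 cycles / 101 groups (19 groups,
  each two low-confidence cycles, vanish entirely).
* Surviving cycle counts per group span 1–10 and sum to 248; group sizes
  average 2.92 with 9 large groups; 26 surviving groups have calves.
* Stratum mean durations are solved (2-d root find) so that the pooled
  filtered means are exactly 16.10/39.77 s *and* the 6-s-window availability
  is 0.37 (small) and 0.66 (large) — the solved small-stratum means are
  ~16.1/42.6 s; the large-stratum solution (~15.9/15.7 s) encodes the much
  shorter dives that make large groups more available. Individual durations
  are drawn around these means and then nudged in 0.01-s steps so the
  stratum totals are exact on the 2-dp grid while every value stays inside
  the published ranges.
* Within-cycle structure: surfacing and diving durations share a group
  multiplier and an AR-1 cycle factor (long cycles are long in both phases)
  plus phase-specific AR-1 noise and an opposing group offset. The shared
  components produce realistic duration dispersions (SD ≈ 9.3/26.9 s)
  without inflating the bootstrap SE of availability — availability is
  nearly invariant to proportional rescaling of both means — which lands
  the group-bootstrap SE at ≈0.015, bracketing the published 0.01, with
  clearly separated small/large CIs. The opposing offset and phase-specific
  AR-1 give the log proportion a genuine group intercept and positive serial
  correlation (the global model prefers AR-1 by ~4 AIC units, φ̂ ≈ 0.3).

## Numerical conventions and edge cases

* Printed-value reproduction rounds to 2 dp (Python bankers' rounding);
  percent differences between availability estimates are computed on
  2-dp-rounded inputs and reported as integers, reproducing table-precision
  arithmetic. Unrounded values are always retained alongside.
* Abundance re-correction: N_new = N·Pr_old/Pr_new (exactly invertible);
  the corrected CV combines the original CV and both availability CVs in
  quadrature (delta-method approximation — the source does not state its
  propagation rule, and the output labels the convention).
* Degenerate inputs: empty summaries, non-positive durations or means,
  windows beyond the view radius, and nonstationary correlation parameters
  raise; out-of-range covariates warn unless strict validation is on;
  an uncapped comparator value above 1 warns and caps.
* Problem sizes: the renewal oracle uses 1e5 passes; bootstrap defaults to
  B = 1000; parameter-recovery checks use 300 groups × 5 cycles and the
  AR-1 selection power check 50 replicates of 100 groups × 5 cycles.

## Known limitations

* The availability model treats the dive process as stationary during the
  pass and the closed form is exact only for exponential dives; for the
  empirical means it is the standard first-order correction.
* The historical comparator's 16%-vs-46% style contrasts depend on rounding
  conventions of the original studies; the re-corrected FMA II abundance is
  therefore checked to 1%, not exactly (the unrounded inputs behind the
  published 6,146 are unrecoverable; the published mean of 2.45
  cycles/group likewise appears truncated from 248/101 = 2.455).
* Perception bias (available animals missed by observers) and TDR-based
  availability are out of scope.
* ARMA candidates beyond AR-1 are implemented and tested for correctness of
  the correlation structure, but the selection workflow follows the study
  design: AR-1 vs none, then AR-1 throughout.
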