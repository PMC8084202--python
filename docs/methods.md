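# Methods

## Model and estimator

We model network activity as a driven branching process with an
autoregressive representation of first order: conditioned on the current
number of active units A_t, the next time bin satisfies

    E[A_{t+1} | A_t] = m·A_t + h·Δt,

where m ≥ 0 is the branching parameter (mean offspring per event per step)
and h is the rate of an uncorrelated external Poisson drive.  For m < 1 the
process is stationary with mean ⟨A⟩ = hΔt/(1−m), and the lag-k regression
slope (correlation coefficient) obeys r_k = m^k.  Writing
m = exp(−Δt/τ) identifies the intrinsic timescale τ = −Δt/ln m as the decay
constant of the autocorrelation function.  Observing only a fraction α of
events (binomial subsampling) multiplies r_{k≥1} by a constant
b = α²Var[A_t]/Var[a_t] < 1 but leaves the decay rate untouched, which is
why the multi-step fit with a free amplitude recovers τ from arbitrarily
subsampled recordings while the naive one-step regression underestimates m.

### Simulator

The simulator draws A_{t+1} ~ Poisson(m·A_t + hΔt) in a single step: the
superposition of independent Poisson offspring per active unit and Poisson
drive is itself Poisson with that mean, so the conditional-mean contract is
exact and counts stay non-negative integers.  Trials start deterministically
at the (rounded) stationary mean, which makes the linear statistics used
here stationary from t = 0; an optional burn-in is available but defaults to
0.  Each trial consumes an independently spawned child of the master seed,
so enlarging `numtrials` never perturbs earlier trials, and the subsampling
stage has its own child stream.  Subsampling is independent binomial
thinning per time bin, a_t ~ Binomial(A_t, α); per-unit identity is not
tracked.

When a target activity a is given with m < 1, the drive is set to
h = a(1−m)/Δt so that ⟨A⟩ = a.  For m ≥ 1 no finite stationary mean exists
and h must be given explicitly.

### Coefficient estimators

For a single recording x = (a_1 … a_{T−k}), y = (a_{1+k} … a_T), the naive
estimator is the regression slope

    r_k = Σ_t (x_t − x̄)(y_t − ȳ) / Σ_t (x_t − x̄)²,

with x̄, ȳ the sample means over the T−k usable pairs.  With N trials,

- **trialseparated** applies the naive estimator per trial and averages the
  per-trial slopes r_{i,k}.  Each trial estimates its own means, so the
  method tolerates systematic trial-to-trial changes of the activity level;
  the price is the classic short-series bias of sample autocorrelations.
- **stationarymean** pools all trials around common lag-dependent means
  x̄_{·,k}, ȳ_{·,k} (averages over all trials and usable bins); the
  numerator averages per-trial cross products with weight 1/(T−k) and the
  variance normalisation sums every sample t = 1..T with weight 1/T.  We
  implement the variance term literally in that form (deviations of the
  full trial from the k-dependent pooled mean); truncating its inner sum at
  T−k instead would change r_k by O(k/T), which is irrelevant in the
  long-trial regime and a documented ambiguity of the formulation.

Degenerate inputs (a constant segment, zero pooled variance) raise
descriptive errors instead of returning NaN, because silent NaNs poison the
downstream fits; errors name the offending trial.  Missing values are
rejected — the estimators assume gapless, equal-length trials with one Δt.
Lags are positive integers, capped at T−2 (at least two point pairs); a
range whose upper end exceeds the cap is clipped with a warning.

### Fits

Fitting is unweighted nonlinear least squares of the model against
(kΔt, r_k).  Models:

| name | form (lag t = kΔt) | parameters |
|---|---|---|
| exponential | A·e^{−t/τ} | τ, A |
| exponential_offset | A·e^{−t/τ} + O | τ, A, O |
| complex | D·e^{−t/τ} + E·e^{−(t/τ_osc)^γ}·cos(2πνt) + F·e^{−(t/τ_gauss)²} + O | τ, D, O, τ_osc, E, γ, ν, τ_gauss, F |

`exponential_offset` is the default: a small offset absorbs slow
non-stationarities.  The complex model adds a stretched-exponentially
damped cosine for network oscillations (ν in 1/dtunit — fitting in physical
lag units makes ν directly interpretable, e.g. in kHz for Δt in ms), and a
Gaussian term for single-neuron refractoriness.  Its canonical parameter
order is (τ, D, O, τ_osc, E, γ, ν, τ_gauss, F).

Initialisation is multi-start: τ₀ on a log-spaced grid over
[first lag, last lag] (6 points; 4 for the complex model), amplitude from
the first coefficient, offset from the mean of the last 10% of
coefficients; complex starts add oscillation-frequency candidates from the
spectrum of the detrended coefficients and from their zero-crossing rate,
γ₀ = 1, and two amplitude-splitting schemes (even thirds, and
exponential-dominated).  The start with the smallest residual sum of
squares wins; trust-region-reflective bounds keep τ, τ_osc, τ_gauss ∈
(0, 10·k_maxΔt], amplitudes ≥ 0, γ ∈ (0, 5], ν ∈ [0, 1/(2Δt)] (Nyquist),
and O unbounded.  A τ̂ pinned at its upper bound flags the result.  On
noiseless model-generated data all three models recover their generating
parameters to optimizer precision (≲1e−8 relative in the tests).

Coefficients that *grow* with the lag indicate a supercritical process
(m > 1): no decay time exists, so instead of attempting a fit with τ < 0
the log-slope of the positive coefficients is reported as m̂ > 1 with a
warning and τ̂ = NaN.  The detector requires ≥ 90% positive coefficients, a
positive log-slope and a rising mean, so noisy subcritical data does not
trigger it.

### Uncertainty

Confidence intervals come from a trial-level bootstrap: each trial is one
exchangeable unit, drawn with replacement N out of N, and the statistic is
re-evaluated per resample.  For trialseparated coefficients a resample is
the mean of the resampled per-trial slopes; for stationarymean the pooled
estimator is re-evaluated exactly from per-trial sufficient statistics
(sums, cross products), which makes 100 resamples of a 500-lag curve cheap.
Fit parameter intervals refit each bootstrap coefficient curve, starting
the optimizer from the point estimate (the global multi-start already ran
on the full data).  Intervals are empirical percentile intervals with
linear-interpolation quantiles, by default the 12.5%–87.5% band (75%
level); the percentile construction was chosen over BCa for its closed-form
testability.  A single trial carries no resampling information: the package
refuses and points to `chunk_into_trials`.  Stage seeds are independent —
`full_analysis(seed=s)` passes s to the coefficient stage and s+1 to the
fit stage (only consumed when the fit generates its own replicates), so
manual chaining reproduces the one-call result bit for bit.

### Short-trial bias

When T is not ≫ τ, the within-trial sample means are biased estimates of
the true expectation, which biases r_k and hence τ̂ downward for the
trialseparated method.  To leading order in 1/T the one-step coefficient
satisfies E[m̂] = m(1 − (3 + 1/m)/T); propagated through τ(m), the ratio is
τ̂/τ = 1/(1 + (τ/(TΔt))(3 + e^{Δt/τ})), and for τ ≫ Δt the universal curve
y = 1/(1 + 4/x) in x = TΔt/τ.  These closed forms are exposed in
`bias_theory` and used as analytic oracles.  Their validity requires
T(1−m) ≫ 1: at T ≈ τ (equivalently T(1−m) ≈ 1) the dropped O(1/T²) terms
are no longer negligible — simulations show the residual deviation of mean
r_1 from the closed form shrinking as 1/T² (≈0.014 at T = τ = 100, ≈0.0002
at T = 20τ) — so high-precision agreement can only be expected for
T ≳ a few τ.  The stationarymean method compensates the bias whenever
activity is stationary across trials.

The built-in bias study (`short_trial_bias_study`, CLI `bias-study`)
simulates, per normalised trial length x = T/τ, an ensemble of 50 trials at
target activity 1000 without subsampling (the bias is independent of
subsampling), runs both coefficient methods on the same realisations and
fits the exponential-offset model.  Lags extend to min(20τ, T/2): the 20τ
window matches the fit range a practitioner would use, and the T/2 cap
keeps at least half the trial as point pairs per regression — lags
comparable to the trial length rest on a handful of pairs, are dominated by
the bias-induced skew and can be exactly degenerate on integer counts.
Default grid x ∈ {1, 3, 10, 30, 100} with 20 repetitions per point and
τ = 100 steps; at these sizes the study runs in about two minutes on one
core, and the trialseparated means track the leading-order curve to a few
percent (the x = 1 point sits ≈0.03 below it, the formula-truncation effect
quantified above) while the stationarymean means stay within ten percent of
1 for x ≥ 10.

## Synthetic data: what it does and does not emulate

All tests run on self-generated branching-process data: stationary
Poisson-innovation dynamics, exact trial structure, binomial subsampling,
and optionally superimposed oscillation terms added directly to coefficient
curves.  This validates the estimator chain (simulation → coefficients →
fit → bootstrap) under the model's own assumptions.  Real recordings
additionally feature non-stationary drive, multiple timescales, bursting
and refractory dynamics at the single-unit level, and non-binomial
sampling; passing tests therefore demonstrate correctness of the method,
not that any particular recording satisfies its assumptions.  The
recommended practical check — compare trialseparated and stationarymean
estimates — is available but cannot be automated into a guarantee.

## Numerical choices and defaults

- Δt defaults to 1 with unit label "steps"; all lags are reported both as
  steps k and physical lag kΔt.
- Default coefficient lag range (1, min(1000, T−2)); the choice of k_max
  should reflect an a-priori τ guess (≈ 10–20τ) and is deliberately not
  automated.
- `full_analysis` requires the coefficient method explicitly — the two
  estimators rest on different stationarity assumptions and silently
  defaulting to either would hide that judgement call.
- Bootstrap default numboot = 100, CI level 0.75.
- Optimizer: scipy `least_squares` (trf), ftol = xtol = 1e−15,
  gtol = 1e−12, max 2000 function evaluations per start.
- Report files are plain text, '#'-commented headers carrying complete
  provenance (all parameters, seeds, package version); the timestamp line
  is the only nondeterminism.  Values are printed at full precision
  (%.17g) so write → read round trips are exact.
- Problem sizes in the test-suite experiments (e.g. 20 recovery seeds, 20
  bias-study repetitions per grid point, 200 datasets in the CI coverage
  check) were chosen as the smallest ensembles whose sampling error is
  well below the effects being tested.

## Known limitations

- Single dominant timescale: sums of exponentials are not a built-in model
  (the generic machinery accepts only the three models above).
- No gap handling, no unequal trial lengths, no time-varying drive h(t).
- The bootstrap is trial-level only; within-trial block bootstrap is not
  implemented, so single-trial uncertainty requires artificial chunking.
- Binary acquisition formats (NWB, Neuralynx, Blackrock) are out of scope;
  inputs are plain-text matrices or spike time-stamp lists.
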