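# mrtau — multi-step regression estimation of intrinsic timescales

`mrtau` estimates the **intrinsic timescale** (autocorrelation time) of
trial-structured activity time series.  The intrinsic timescale is the decay
constant τ of an exponentially decaying autocorrelation function; in
neuroscience it quantifies how long perturbations reverberate in a local
network and serves as a proxy for the distance to criticality, but the same
estimator applies to epidemic case counts or any system with a first-order
autoregressive representation.

The central difficulty in experiments is **spatial subsampling**: we record
a few units out of billions.  Subsampling scales the *amplitude* of the
autocorrelation but leaves the exponential *decay* untouched.  `mrtau`
therefore estimates, for each lag k, the slope r_k of the regression of
activity A_{t+k} on A_t (multi-step regression), and fits

    r_k = b · m^k = b · exp(−kΔt/τ),        τ = −Δt / ln(m)

with the amplitude b free.  The fitted τ is invariant to the sampled
fraction; m is the branching parameter (mean events triggered per event per
step, m < 1 subcritical, m = 1 critical).

What is included:

- **`process_sim`** — a driven branching-process simulator
  (⟨A_{t+1}|A_t⟩ = m·A_t + hΔt, Poisson innovations) with binomial
  subsampling, for ground-truth data.
- **`data_io`** — the `TrialArray` container (trials × time bins) and
  converters: text files (wildcards, one column per trial), spike
  time-stamp binning, chunking long recordings into artificial trials.
- **`coefficients`** — two trial-aware estimators of r_k:
  `trialseparated` (regress per trial, then average; robust to trial-to-
  trial drift, biased for short trials) and `stationarymean` (pool trials
  around common lag-dependent means; compensates short-trial bias when
  activity is stationary across trials).
- **`fits`** — nonlinear least-squares fits of `exponential`,
  `exponential_offset` (default) and a `complex` model with a damped
  cosine (oscillations), Gaussian (refractoriness) and offset terms;
  multi-start initialisation; supercritical (m > 1) detection.
- **`uncertainty`** — trial-level bootstrap with percentile confidence
  intervals (75% by default).
- **`bias_theory`** — closed-form expectations of the short-trial bias
  (E[m̂] = m(1 − (3 + 1/m)/T) and the universal curve
  τ̂/τ = 1/(1 + 4τ/(TΔt))).
- **`workflow` / CLI** — `full_analysis()` one-call pipeline, TSV report
  persistence, optional overview figure, and the `mrtau` executable with
  `simulate`, `coefficients`, `fit`, `full-analysis` and `bias-study`
  subcommands.

## Worked example

Simulate a near-critical branching process (m = 0.98, so
τ = −1/ln 0.98 ≈ 49.5 steps), record only 5% of its events, and recover the
timescale:

```python
import mrtau

bp = mrtau.simulate_branching(
    mrtau.BranchingConfig(
        m=0.98, target_activity=1000, subp=0.05,
        length=20_000, numtrials=10, seed=43771,
    )
)
rks = mrtau.coefficients(
    bp, method="trialseparated", steps=(1, 500),
    dt=1, dtunit="bp steps", numboot=100, seed=101,
)
res = mrtau.fit(rks, "exponential_offset")
print(f"tau = {res.tau:.1f} {res.dtunit},  75% CI [{res.ci['tau'][0]:.1f}, {res.ci['tau'][1]:.1f}]")
print(f"m   = {res.mre:.4f},  75% CI [{res.ci['mre'][0]:.4f}, {res.ci['mre'][1]:.4f}]")
print(f"amplitude A = {res.params['A']:.3f}, offset O = {res.params['O']:.5f}")
```

prints

```
tau = 44.8 bp steps,  75% CI [42.3, 48.6]
m   = 0.9779,  75% CI [0.9766, 0.9796]
amplitude A = 0.566, offset O = 0.00278
```

The estimate recovers the generating values (m = 0.98, τ ≈ 49.5) up to the
realisation's sampling fluctuation, although only one event in twenty was
observed: the fitted amplitude A ≈ 0.57 < 1 absorbs the subsampling-induced
shrinkage while the decay — and hence τ — is unaffected.  Different seeds
scatter τ̂ by a few steps around 49.5.  The same analysis in one call, with
a saved report and overview panel:

```python
report = mrtau.full_analysis(
    bp, dt=1, dtunit="bp steps", kmax=500,
    coefficientmethod="trialseparated",
    fitfuncs=["exp", "exp_offset"],
    numboot=100, seed=101, targetdir="out/", overview=True,
)
```

From a shell, the equivalent pipeline is:

```sh
mrtau simulate --m 0.98 --a 1000 --subp 0.05 --length 20000 \
      --numtrials 10 --seed 43771 --out bp.tsv
mrtau full-analysis bp.tsv --method ts --kmax 500 --numboot 100 \
      --seed 101 --targetdir out/
```

Practical guidance: choose trials at least ten times longer than an a-priori
timescale guess when using `trialseparated`; for shorter trials prefer
`stationarymean` (if activity is stationary across trials) and compare both
methods — agreement indicates the trials are long enough.  The
`mrtau bias-study` subcommand quantifies the short-trial bias directly.

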