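# Methods

## The model

A protein's damage-site signal is modelled as the terminal member of an
irreversible linear chain of first-order reactions,

    X₀ →(k₁) X₁ →(k₂) … →(k_{n−1}) X_{n−1},    X₀(0)=1, all others 0,
    I(t) = A · X_{n−1}(t),

with an optional final dissociation reaction: for t ≥ τ the terminal species
additionally decays at rate k_n (the rate is zero before τ).  The chain
abstracts the sequence of events — damage recognition, intermediate
recruitment steps, complex assembly — that precede stable binding; n is the
*minimal* number of reactions needed to describe the curve, not necessarily
the biological number of steps.  Parameters and units:

| parameter | meaning | units | constraints |
|---|---|---|---|
| k₁…k_{n−1} | recruitment rate constants | 1/s | > 0 |
| k_n | dissociation rate constant | 1/s | > 0, present iff the protein detaches |
| τ | detachment delay (dwell before dissociation starts) | s | ≥ 0 |
| A | amplitude mapping occupancy to measured intensity | intensity | > 0 |

Model assumptions: reactions are irreversible and first order; the
dissociation switch at τ is global (a piecewise-constant rate), not a
per-molecule dwell time — both produce a delayed decay and differ only in the
corner sharpness at τ; curves are population means, so no attempt is made to
model single-molecule stochasticity or spatial diffusion.

Measured curves may be sums of chains.  A `CompositeModel` is

    I(t) = baseline + Σ_c A_c · X^{(c)}_{terminal}(t) + B(t),

with component roles `phase` (one mode of a multiphasic recruitment),
`removable` (detaching fraction) and `non-removable` (fraction that stays
bound for the duration of the experiment; such components must have no
dissociation reaction).  B(t) = −A_b·e^(−k_b t) is a residual photobleaching
deficit from the irradiation pulse that upstream compensation did not fully
restore: a negative contribution recovering to zero.  The exponential shape
is the minimal recovering-deficit form; it makes the component identifiable
whenever k_b differs from the recruitment rates (if k_b equals a
single-exponential recruitment rate, the deficit is exactly absorbed by a
larger amplitude plus a constant, and no fit can distinguish them — the
benchmark fixture therefore uses k_b = 0.15 s⁻¹ against recruitment
0.05 s⁻¹).

## Evaluation engines

Two independent engines compute X_{n−1}(t):

1. **Analytic.**  For pairwise-distinct rates the chain has the classical
   sum-of-exponentials (Bateman) solution.  With a delay τ > 0 the species
   vector is propagated analytically to τ and the solution for t > τ is the
   superposition of sub-chain solutions with dissociation active.  The value
   at t = 0 is set to exactly 0 (the alternating sum cancels only to ~1e−15
   in floating point).
2. **Numerical.**  `scipy.integrate.solve_ivp` (LSODA, rtol 1e−9,
   atol 1e−12) on the chain ODE, split into two segments at t = τ so the
   rate switch is never smoothed over; integration always proceeds to the
   exact segment end so the post-τ initial condition is y(τ).

`evaluate_component` dispatches to the analytic engine and falls back to the
ODE when any two rates agree within a relative 1e−6 (where the analytic
denominators degenerate); `evaluate_closed_form` exposes the restricted
classical solution (no removal, or τ = 0) as an oracle and refuses
degenerate rates instead of silently switching.  The two engines agree to
better than 1e−8 relative on randomized models; the test suite and the
acceptance script re-measure this.  Mass conservation (Σ species +
dissociated pool = 1) holds to ~1e−13.

## Fitting

Weighted nonlinear least squares via `scipy.optimize.least_squares` (TRF) on
transformed parameters: rates, amplitudes and bleach parameters are fitted as
logarithms, τ through a softplus — positivity holds by construction, no
active-set handling is needed.  Wide rails on the transformed values
(rates 1e−8…1e4 s⁻¹, amplitudes 1e−8…1e4 × curve maximum) only prevent
overflow.  Standard errors come from the Gauss–Newton covariance at the
optimum, delta-method-propagated to the natural scale.

Defaults and why:

- **Weighting: none.**  The per-timepoint SD measures cell-to-cell biological
  spread (amplitude variability), not the uncertainty of the mean;
  inverse-variance weighting (1/SD²) is available for data where the SD does
  track measurement error.
- **Multistart: 10 seeded starts.**  Start 1 uses the template's values (for
  automatic selection, a data-driven guess from the observed half-rise time,
  tail decay and peak position); the rest draw rates log-uniformly from
  1e−4–10 s⁻¹ (observed halftimes span < 2 s to > 10 min, i.e. four decades
  of rates), τ uniformly over [0, t_max/2], amplitude from the curve maximum.
- **Baseline fixed at 0.**  Curves are baseline-subtracted relative to the
  pre-irradiation signal with t = 0 at micro-irradiation; pass
  `fixed=("~baseline",)` to free it.
- **Chain-length selection.**  n = 1, 2, … (n = 2 upward when a dissociation
  reaction is expected, since one rate must remain for recruitment) until the
  successor fails the improvement criterion: ΔAICc > 2.0 by default (a
  standard parsimony margin; the stopping rule "fit quality unchanged" needs
  a quantitative threshold and this one is configurable), or a 1% relative
  SSE improvement under the alternative criterion.  Noise-free SSEs are
  floored at (1e−12 × curve scale)² per point so the log in AICc stays
  finite.  If the cap n_max is reached while still improving, the result
  carries a `no_plateau` flag.
- **Label switching.**  Fitted composite components are reported sorted by
  ascending recruitment halftime; near-identical components raise a
  `component_collapse` warning flag.
- **Identifiability.**  Recruitment rates within one chain are exchangeable
  (the curve is symmetric under their permutation), so only the *set*
  {k₁…k_{n−1}} is identifiable; the dissociation rate, τ and A are
  individually identifiable.  Composite fits additionally require fewer free
  parameters than half the number of timepoints.

Uncertainty beyond the delta method comes from a residual-resampling
bootstrap (`bootstrap_uncertainty`): residuals of the fit are resampled onto
the fitted curve and each replicate is refit from the point estimate.
Percentile intervals are widened, if necessary, to contain the point
estimate.  At the reference experiment size (12 cells, 5% noise, 200
resamples, 50 outer replicates) the nominal 95% interval for k₁ covers the
true value roughly 90–96% of the time depending on the replicate seed — both
the acceptance script and the test suite recompute this.

## Derived scalars

- **Recruitment halftime**: earliest t with I(t) = I_max/2 on the rising
  phase, found by a 4096-point bracketing scan plus Brent root refinement on
  the model curve.  For a single-reaction chain this equals ln 2/k₁
  analytically (verified to 1e−9).
- **Removal halftime**: earliest t past the peak with
  I(t) = (I_peak + I_∞)/2, where I_∞ = baseline + Σ non-removable amplitudes
  is the exact asymptote; absent when no component dissociates.
- **Peak time/value**: interior maximum (bounded refinement of the grid
  argmax); monotone curves have no peak time and their asymptote is the peak
  value.
- **Plateau fraction**: I_∞ / I_peak, clipped to [0, 1] — 1 for pure
  non-removable models, 0 for full removal with zero baseline.
- Halftimes are defined on the fitted model curve, not the raw data: the
  model interpolates below the sampling interval and is robust to noise.
- The evaluation horizon is 10 × the slowest model timescale
  (1/min-rate + τ, including the bleach recovery time); the removal-halftime
  search extends it geometrically and reports a horizon error if the midpoint
  is provably not reached.

Condition comparisons (`compare_conditions`) require structure-matched fits
(same chain lengths, roles, bleach presence) and report treated/untreated
ratios per parameter plus halftime deltas; mismatched structures yield a
mismatch report instead of numbers.  `ordering_shift` quantifies how a
treatment changes the recruitment lag between two proteins.
`parameter_path` interpolates between two fits for animation-style
exploration: rates move geometrically (they are scale parameters spanning
decades; linear interpolation would distort the transition), amplitudes,
delays and baseline linearly; `parallel` moves all parameters per step,
`sequential` one parameter per segment (path length p·(steps−1)+1).

## Synthetic data generator

Emulates the acquisition design under which such datasets are collected:
8–21 cells per protein (the default cell count is drawn from that range),
sampling intervals restricted to 0.5–5 s unless explicitly overridden, and
durations long enough to cover the removal phase.  Per cell c,

    trace_c(t) = s_c · I_model(t) + ε_{c,t},
    log s_c ~ N(0, cell_scale_sd),   ε ~ N(0, noise_sd_fraction × peak),

with defaults cell_scale_sd = 0.2 (a ±20% per-cell amplitude spread from
expression level and dose variation) and noise_sd_fraction = 0.05 (5% of
peak, a typical confocal detector-noise scale).  Aggregation takes the mean
and sample SD per timepoint, which is the published form of such data.
Acquisition photobleaching is multiplicative per frame (e^(−rate·j) at frame
j) and its compensation divides by a reference decay normalized to 1 at
frame 0 — the exact inverse when the reference matches the true process, and
unbiased when the reference is estimated from control traces.

What the generator does **not** emulate: the actual noise distribution of
intensity measurements (unknown for real detectors beyond the Gaussian
approximation), photophysics (blinking, saturation), segmentation and
tracking errors, cell movement, and any correlation of noise across
timepoints.  Recovery results on synthetic data therefore demonstrate the
correctness and calibration of the estimation machinery under the stated
noise model, not performance guarantees on arbitrary real curves.

The deterministic benchmark suite (`make_benchmark_suite`) spans the regimes
seen in real data: a sub-2-s fast plateau, a >10-min slow riser, delayed
removal, a two-phase sum, a 70/30 removable/non-removable split, and a
bleach-contaminated curve.  All fixtures are noise-free so closure tests
(select/fit → exact truth) are exact; the single-chain fixtures close under
`select_chain_length`, the composite ones under `fit_composite` with their
truth-shaped templates (a plain chain-length scan has no defined "generating
n" for a sum of chains).

## File formats and conventions

Curve tables are UTF-8 CSV with a `# key: value` metadata header and columns
`time_s, intensity_mean, intensity_sd`, written at full precision (`%.17g`)
and read back bit-identically (`float_precision="round_trip"`).  A permissive
XLSX importer maps common column-name variants.  Model specs are JSON with
explicit `components[]`, `rates_per_s`, `tau_s`, `amplitude`, `has_removal`,
`bleach`, `baseline` and `format_version`.  Readers reject invariant
violations with the offending row/field named; they never repair silently.
One deliberate asymmetry: a curve whose t = 0 value is *positive* beyond
3×SD₀ is rejected (recruitment cannot be instantaneous, so the curve cannot
be baseline-subtracted), but a *negative* start is accepted — an
uncompensated bleach deficit genuinely begins below zero.  Frame indices are
0-based internally; all user-facing times are seconds.

## Problem sizes used in tests and the acceptance script

Oracle agreement uses 50 randomized chains on 100-point grids; conservation
25 chains; halftime recovery 50 seeded replicates of the reference
experiment (12 cells, 2 s interval, 600 s, 5% noise); selection accuracy 3
noise-free chain lengths plus 20 replicates at 1% noise; bootstrap coverage
50 replicates × 200 resamples.  These sizes make the stochastic success
rates reproducible to a few percent while keeping a full run around one
minute on a single CPU.

## Known limitations

- The delay is a global rate switch; convolutional (per-molecule dwell)
  delays would round the corner at τ and are not implemented.
- Equal-rate chains are handled by the ODE engine rather than confluent
  closed forms; fits whose rates collapse to equality are therefore slower
  but remain correct.
- Only aggregate mean curves are fitted; per-cell traces are simulated but
  not jointly fitted.
- Model selection compares nested single chains; it does not search over
  composite structures (the user supplies composite templates).
- No global-optimization guarantee: multistart makes basin-hopping failures
  rare at realistic noise levels (the seeded experiments quantify how rare)
  but cannot exclude them.
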