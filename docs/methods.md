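# Methods

## Model structure and assumptions

Both circuits are population-average ODE models in nM and minutes.
Transcription from the *CMV-TET* promoter is a Hill function of active tTA
with an additive basal term (`v1·(α0 + H(u))`, `H(u) = uⁿ/(θⁿ+uⁿ)`), so the
promoter is leaky but bounded.  Doxycycline acts multiplicatively on tTA
*activity* before the promoter (`u = x2·w(D)`, `w(D) = k_doxʰ/(k_doxʰ+Dʰ)`),
reflecting its mechanism — it prevents tTA from binding the promoter rather
than degrading it.  Translation and degradation are first order.  The
reporter matures in two stages (unfolded → folded at rate `Kf`); both forms
are degraded at the reporter rate `d3`, so the unfolded pool loses mass at
`(Kf + d3)`.  Because tTA and the reporter sit on one bicistronic
(IRES) transcript, a single mRNA variable feeds both translation terms with
the same rate `kp`.  The NOPFL model fixes tTA at the constitutive level
`ρ_tTA`, which makes it linear time-invariant in `(x1, x3, x4)` with
eigenvalues exactly `{−d1, −(Kf+d3), −d3}`.

The shallow fitted Doxycycline Hill coefficient (h ≈ 0.06) means the
response over the working range 0.1–100 nM is nearly hyperbolic;
`fit_mm_approx` quantifies this by least-squares fitting a Michaelis–Menten
curve with a leak floor (residual bound ≈ 0.035 over that range).  The leak
floor (~0.47) captures the biologically relevant point that tTA activity is
never fully shut down.

## Parameters

All constants live in `ParameterSet` (packaged defaults in
`data/table1_params.yaml`): θ [nM] promoter activation coefficient, α0 [-]
basal activity, v1 [nM/min] maximal transcription, kp [1/min] translation,
d1/d2/d3 [1/min] degradation of mRNA/tTA/reporter, n [-] promoter Hill
coefficient, k_dox [nM] and h [-] the Doxycycline response, Kf [1/min]
reporter folding, ρ_tTA [nM] the NOPFL constitutive tTA level, and s_obs
[a.u./nM] the observation scale mapping folded reporter to fluorescence
(default 1, i.e. fluorescence is reported on the nM scale of the folded
reporter).  All must be positive except α0 ≥ 0; Hill coefficients below 1
are deliberately allowed.

## Simulation protocol

`simulate_switch_off` always starts from the ON steady state of the
untreated (D = 0) circuit — the pre-treatment culture condition — and
applies the dose as a step at t = 0.  Defaults match the experiment: 2580
min (43 h) sampled every 15 min (173 samples).  The integrator is LSODA
with analytic Jacobians, rtol 1e-8 and atol 1e-12 nM; the tight tolerances
matter because bistability analysis must not let trajectories numerically
hop between basins.

## Equilibria

Steady states are found on the exact scalar reduction of the (x1, x2)
plane: substituting the mRNA nullcline into the tTA nullcline leaves one
fixed-point equation in x2, which is bracketed on a dense grid (origin plus
4000 log-spaced points spanning the attainable range `[0, K(α0+1)]`,
`K = kp·v1/(d1·d2)`), refined by Brent's method to near machine precision,
deduplicated within 1e-6 relative distance, and lifted to the full state
(x3, x4 are slaved linear readouts).  This replaces a 2-D multistart search:
the reduction is exact, so no equilibrium can be missed up to grid
resolution, and it is cheap enough to run inside the fitting loop.
Stability comes from the analytic Jacobian's eigenvalues (strictly negative
real parts within 1e-12).  Every reported equilibrium must pass a
scale-free residual test (each |dxᵢ/dt| below 1e-10 of the summed term
magnitudes feeding xᵢ).  With the default constants the loop is bistable up
to a critical dose near 42 nM (where `K·w(D)·max H(u)/u = 1`) and
monostable OFF beyond it.

Basins of attraction are mapped on the reduced plane by chunked forward
integration until capture within a relative radius 1e-3 of a stable
equilibrium; points never captured within the horizon are labelled
`undetermined`.

## Switch-off time

T_off smooths the course with a centred moving average (default window 5
samples; shrinking windows at the edges), takes F0 as the mean of the first
4 smoothed samples (1 h), and linearly interpolates the first crossing of a
threshold level.  Two conventions exist for the threshold and the package
implements both, because the defining descriptions differ:

* `mode="initial"` (default): level = f·F0, f = 0.5 by default — the
  fraction-of-initial convention;
* `mode="steady_state"`: level = off + f·(F0 − off), where `off` is the OFF
  steady-state fluorescence (caller-supplied from the model, or estimated
  from the course tail) — the fraction-of-the-way-to-OFF convention.

The threshold fraction and window are free choices (0.5 and 5 are
conventional defaults).  The two modes answer different questions: for the
open-loop circuit the steady-state mode is *exactly* dose-invariant (a
linear system's relaxation shape is input-independent), which is the
topological claim the package tests; the initial mode depends on how far
the steady state drops and with the default constants the open-loop
fluorescence never falls below 50% of F0 in absolute terms, so that mode
returns "not reached" across the board.  The feedback loop, started ON,
fails to reach either threshold within 43 h for doses in and near the
bistable window — the slow-down that distinguishes the two topologies.

## Half-life estimation

`fit_exponential_decay` mirrors the cycloheximide-chase analysis: nonlinear
least squares of `A·e^{−δt}` (optional floor, off by default), seeded by a
log-linear regression, with `t½ = log 2/δ`.  Flat or rising input is a
domain error rather than a δ → 0 fit.

## Inference

The objective is the chi-square of all replicate courses of both circuits
at once: `Σ (ŷᵢ − yᵢ)²/σᵢ²`, with σᵢ² the per-(circuit, dose, time)
replicate sample variance floored at (1% of the condition's maximum
fluorescence)² so coinciding replicates cannot blow up the weights.
Predictions always restart from the candidate parameters' own ON steady
state.  The joint vector has the 12 model parameters (11 shared, ρ_tTA for
the NOPFL only) plus one observation scale per circuit (granularity is
configurable; per-circuit is the default since nothing fixes it further).

Optimisation is `scipy.optimize.least_squares` (trust-region reflective,
bounded) on log₁₀ parameters — all parameters are positive and span
decades, so log space makes the trust region meaningful.  Bounds default to
two decades either side of a midpoint parameter set.  Multistarts are
scrambled-Sobol points in the log-bounded box, fully seeded; identical
seeds give bitwise-identical run tables.  Finite-difference steps of 1e-3
in log₁₀ keep the Jacobian well above integrator noise.  A run counts as
converged when its final chi-square does not exceed the number of fitted
points (the expected value of a chi-square statistic at a correct model);
the best run supplies the estimate and the spread of each parameter across
all runs is its multistart dispersion.  Each run's iteration budget is
capped (default `max_nfev=50`), which is ample for runs that find the
global basin and cuts off hopeless ones.

Problem sizes in the test suite are scaled to keep the full run fast: the
noiseless recovery test uses 5 Sobol starts plus the truth-seeded start,
and the noisy recovery uses 3 seeds × (3 Sobol + truth); the acceptance
script uses the full 20 Sobol starts plus truth.  Recovery tolerances are
unaffected by this scaling: with a truth-seeded start the noiseless refit
must land within 1%, and under 10% replicate noise the identifiable
parameters (n, θ, d1, d3) must come back within 15% in median.

## Synthetic data

`generate_experiment` emulates the time-lapse campaign: for each circuit
and each dose in {0.1, 1, 10, 100} nM (bracketing k_dox = 1 nM; the
experimental concentrations themselves are not recoverable, and the
2/2/3/5 replicate counts are assigned to increasing dose by default — both
configurable), it simulates the noiseless switch-off course and draws
replicates with unit-mean lognormal multiplicative noise (default CV 10%)
plus a small additive Gaussian floor (sd = 1% of the course maximum),
independent across time points, clipped at zero.  It emits the per-point
replicate sample variance the objective consumes.  What the generator does
*not* emulate: cell-to-cell variability and its averaging, autocorrelated
segmentation/illumination drift, photobleaching, and cell-count changes in
the field of view.  Passing recovery tests therefore show identifiability
under well-behaved heteroscedastic noise of realistic magnitude, not
robustness to structured microscopy artefacts.

## Numerical choices and degenerate inputs

Hill functions are evaluated in ratio form (`1/(1+(θ/u)ⁿ)`) so extreme
multistart draws (n up to ~300 at the bound corners) saturate cleanly
instead of overflowing; the Hill derivative uses the product form
`(n/u)·H·(1−H)`.  Simulation failures inside the fit return large residuals
so a multistart run fails softly rather than aborting the campaign.
Near-duplicate equilibrium roots keep the smaller-residual member.  T_off
with an even smoothing window, a course shorter than the window, or a
threshold outside (0,1) are domain errors; courses must sit on uniform
time grids and CSV inputs are validated course-by-course with the offender
named.

## Known limitations

* The bifurcation scan is a discrete dose scan; it brackets but does not
  continue the fold point (no continuation method).
* Multistart dispersion is a spread measure, not a confidence interval;
  the combination (v1, kp, s_obs) is structurally degenerate up to scale
  and only products of it are identifiable.
* The ON steady state used to initialise fitting is the largest-x2
  equilibrium; for parameter draws where the loop is monostable this is the
  unique state, which is the sensible continuation but differs from a true
  ON branch.
* No stochastic (single-cell) simulation: the model is population-average
  by design.
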