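# Methods

## The problem

`tecfit` analyses pre-steady-state kinetics of bacterial transcription
elongation complexes (TECs): single-round nucleotide addition and forward
translocation measured by rapid quench-flow and stopped-flow fluorescence,
backtracking captured through factor-stimulated RNA cleavage, equilibrium
titrations with the translocation-state probe tagetitoxin (TGT), and the
binding kinetics of the elongation factor NusG.  The package provides the
complete computational side of such a study: mechanism definition,
numerical simulation, global fitting, parameter-uncertainty bounds, the
median-reaction-time statistic, and depletion-corrected binding analysis.
Because the study class it targets deposits no raw instrument traces, a
first-class synthetic-data module regenerates every input class from its
published design parameters.

## Kinetic schemes

Mechanisms are declarative mass-action state graphs (`schemes.py`).  Each
transition names a rate parameter; values bind only at simulation or fit
time, so one scheme serves generation, fitting and profiling alike.

* **Three-step nucleotide addition.**  TEC16 interconverts slowly and
  reversibly between an inactive and an active state (recovery `k_rec`,
  inactivation `k_inact`); the active state undergoes irreversible
  nucleotide addition (`k_add`) to TEC17 followed by irreversible forward
  translocation (`k_tr`).  The initial mass splits `slow_fraction` /
  `1 - slow_fraction` between the inactive and active states.  NTP
  dependence is folded into the pseudo-first-order `k_add` because the
  assay design uses saturating substrate (400 µM syringe, 200 µM after
  equal-volume mixing).
* **Backtracking-limited cleavage.**  TEC_pre ↔ TEC_backtracked →
  TEC_cleaved (`k_bt`, `k_fwd`, `k_cleave`).  The cleavage factor's
  concentration is deliberately not a species: inhibition in the target
  system is independent of it over a fourfold range, so cleavage enters as
  an effective unimolecular rate.  `k_fwd` is exposed but given no default
  value; generators use zero, making the cleaved-fraction relaxation
  single-exponential in `k_bt` when `k_cleave >> k_bt`.
* **One-step reversible binding with depletion.**  TEC_free ↔ TEC_bound
  with the association flux multiplied by the *free* ligand concentration,
  tracked as total minus receptor-bound.  Depletion is mandatory, not an
  option: the lowest post-mix ligand concentration in the design (0.1 µM)
  is half the 0.2 µM receptor concentration, so the pseudo-first-order
  approximation fails exactly where the data are most informative about
  `k_off`.

## Numerical integration

`ode_engine.simulate` integrates state fractions with SciPy's LSODA at
rtol 1e-8.  The absolute tolerance is 1e-12, deliberately below the
contract that fractions in [−1e-10, 0) are clamped to zero while anything
more negative raises — solver noise must never be able to masquerade as a
physically negative population.  Output rows are checked to sum to 1
within 1e-8 and then renormalized.  For purely unimolecular schemes the
integrator is verified against an independent matrix-exponential oracle to
1e-6 absolute over randomized schemes (a property test, 100 trials).
Bimolecular schemes keep ligand conservation exact by construction, since
the free concentration is computed from the state fractions at every
evaluation rather than integrated separately.

## Stretched-exponential fits and the median reaction time

Relaxations driven by backtracking are heterogeneous, so traces are fit to

    signal(t) = baseline + amplitude · (1 − exp(−(t/τ)^β)),

with signed amplitude (rising 2-AP, falling 6-MI) and unweighted least
squares per trace (single-instrument, homoscedastic noise).  The summary
statistic is the **median reaction time** τ·(ln 2)^{1/β} — the
half-amplitude crossing of the fitted curve — which generalizes the
half-life to β ≠ 1 and reduces to it at β = 1.  Because the (τ, β) surface
is multimodal, fits start from a fixed grid β ∈ {0.5, 0.75, 1.0} with τ
seeded from the observed half-crossing; the lowest residual sum wins.
β is fit freely within (0.1, 2]; a fit landing on a bound is flagged
(`beta_at_bound`) rather than silently accepted, as is a trace whose span
is shorter than twice the fitted median (`short_span`).  Constant traces —
including flat-but-noisy ones, detected by comparing the smoothed
excursion against the first-difference noise estimate — raise a named
error.

Replicate summaries follow the field's convention: center = mean, spread =
range for duplicates, sample SD for n > 2.  Fold changes propagate the
relative spreads to first order.

## Global fitting

`global_fit.fit_global` minimizes one joint χ² over heterogeneous
observations (quench-flow point series and stopped-flow traces) that share
the scheme's rate constants:

* Rates are optimized in log10 space (positivity, scale-freeness); the
  slow fraction linearly within [0, 1].
* Per-trace fluorescence scale and offset are *profiled analytically*: at
  each parameter evaluation the optimal (scale, offset) is the solution of
  a 2×2 linear least-squares problem.  This is exactly equivalent to
  optimizing them jointly but removes two nonlinear dimensions per trace.
* Weighting: when an observation carries no explicit σ, a pilot
  unit-weight fit runs first and σ is estimated from the sample SD of the
  observation's late-time residuals (final 20% of points, ≥ 4).
  Quench-flow points within one observation share one σ (equal weights).
  The source study reports no weighting scheme; this default is the
  package's own documented choice.
* Multi-start: a truth-agnostic grid of multiplicative factors applied to
  the initial rates (default just ×1; the binding fit uses ×{0.1, 1, 10}).
  Everything is seeded and deterministic.
* A parameter whose Jacobian column is numerically zero is reported as
  structurally insensitive rather than silently pinned.
* The initial inactive fraction can either be a free parameter (the
  default) or tied to the slow pre-equilibrium,
  slow_fraction = k_inact/(k_rec + k_inact)
  (`derive_slow_fraction=True`): assembled complexes interconvert slowly
  before mixing, so their initial split reflects that equilibrium.  With a
  free slow fraction the inactivation rate is barely identifiable in a
  single-round design — it diverts only ~k_inact/k_add of the flux — and
  the tie is what couples it to the slow-phase amplitude.  The
  parameter-recovery suite demonstrates both facts.

## Profile bounds at a fractional χ² increase

Parameter intervals follow the convention of interactive kinetics-fitting
software: the interval for parameter θ is the region where the χ²,
**re-optimized over all other parameters** at each fixed θ, stays within
(1 + f)·χ²_min, with f = 0.10 by default.  Endpoints are located by an
outward geometric walk (warm-starting the inner optimizations) followed by
bisection to 1% relative precision; the endpoint χ² is verified against
the threshold to 1% in tests using a linear model whose profile is an
exact parabola.  Profiles that never reach the threshold within a 10⁶-fold
range (or the domain of a bounded parameter) are flagged unbounded.  Note
this is a practical sensitivity band, not a calibrated frequentist
interval: with noisy data χ²_min grows with the number of points and so
does the allowed increase.

## Depletion-corrected equilibrium binding

At 100 nM receptor the ligand is consumed by complex formation, so the
bound complex concentration is the physical root of

    b² − (R + L + Kd)·b + R·L = 0,

evaluated in the cancellation-free form b = 2RL/(S + √(S² − 4RL)).  A
titration curve interpolates between free- and bound-state signal
endpoints with weight b/R.  `fit_titration` fits a shared Kd (in log10
space) jointly over curves with per-curve endpoints profiled linearly.
The 95% CI is the profile of the joint SSR at the threshold
SSR_min·(1 + F(1, dof; 0.95)/dof); a Wald interval from the local
curvature is reported alongside, since small duplicate designs can make
the two disagree.  A curve set whose best fit never reaches
half-occupancy is flagged `transition_not_spanned`.  Under depletion the
half-occupancy midpoint sits at L = Kd + R/2, which is why the fit — not
the midpoint — is the estimator.  Sequential-addition dilution is
supported through optional cumulative volumes but defaults to off (the
design this package emulates reports addition identities, not per-step
volumes).

## Synthetic data: what it emulates and what it does not

Generators (`synthetic_data.py`) are bit-reproducible per (spec, seed) and
reproduce the study designs:

* quench flow: 12 log-spaced points over 0.004–10 s, 2% amplitude noise;
* stopped flow: uniform sampling after a 1.5 ms dead time, 1% noise,
  400–500 points per trace;
* binding series: post-mix concentrations are half the syringe values
  (equal-volume mixing), receptor 0.2 µM, ligand 0.1–10 µM, trace duration
  about five relaxation times of k_on·L + k_off;
* titration: 100 nM receptor, ligand levels spanning the transition, 2%
  noise.

Condition presets encode the published per-condition median times (wild
type, ΔRL, ΔLL, ΔGL cleft-loop deletions, upstream DNA mismatches, ±NusG)
as single-exponential targets; the backtracking-limited chain's entry rate
is solved (by root finding on the two-step survival function) so the
noiseless trace crosses half-amplitude *exactly* at the target median.

The noise model is additive, Gaussian, homoscedastic and uncorrelated —
real stopped-flow noise is autocorrelated and can drift, real gel
quantification has multiplicative components, and true amplitudes vary
between preparations.  Passing the recovery tests therefore demonstrates
the correctness of the estimators under the stated noise model at the
published designs, not instrument-grade robustness.

## Problem sizes and numerical choices

The shipped analyses use one quench-flow series (12 points) plus one
500-point stopped-flow trace for the three-step fit, seven concentrations
× 200 points for the binding series, and twelve-level duplicate curves for
titrations; recovery-property suites use 20–50 seeded replicates.  These
sizes put every fit comfortably in the well-identified regime for the
parameters the study quantifies while keeping the full analysis fast on a
single CPU.  Ties and degenerate inputs are handled explicitly: zero
ligand gives exactly zero bound fraction, zero rates give identity
dynamics, an empty amplitude raises, and noiseless fits collapse their
confidence intervals to the point estimate.

## Known limitations

* No stochastic (Gillespie) simulation, spatial modelling, multi-site or
  cooperative binding, or instrument-response deconvolution beyond
  dead-time truncation.
* The χ²-threshold bounds depend on the (estimated) σ only through
  χ²_min's scale; badly mis-estimated noise shifts the bands accordingly.
* Local optimization with a documented multi-start grid — no global
  optimality guarantee.
* Whether the inactive-state rates should be shared between ±NusG
  conditions is left to the caller (`fit_global` fits whatever free list
  it is given; shared-parameter fits across conditions are expressed by
  pooling observations into one dataset).
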