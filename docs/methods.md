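# Methods

## Model

The package implements global (and, via arbitrary compartment schemes,
target) analysis of time-resolved difference spectra under three standard
assumptions: the data are a linear superposition of a discrete set of
transient species with fixed spectra (bilinearity); the populations follow
first-order kinetics; residual noise is i.i.d. Gaussian. Systems that
violate these — lifetime distributions, continuously shifting spectra,
bimolecular or higher-order kinetics, vibrational coherences — are outside
the model class, and no amount of uncertainty analysis inside the class
detects that; model validation requires residual diagnostics and control
experiments, which this package does not attempt.

A kinetic scheme declares N species, inter-species transitions, decays to
the ground state, and the initially excited species (vector J, entries
taken literally, conventionally 0 or 1, never renormalized). Rates enter
as lifetimes τᵢ = 1/kᵢ. The transfer matrix T carries the transition
rates off-diagonal and minus the total decay out of each species on the
diagonal, so column sums are −(ground-state decay) ≤ 0. The excitation
pulse is a unit-area Gaussian with center t₀ and width FWHM = √(8 ln 2)·σ.

### Analytic populations

Because the system is linear and time-invariant, the populations are
computed in closed form: diagonalize T, propagate each eigenmode as a
Gaussian-convolved exponential

    c(t) = ½ · e^{σ²k²/2 − k(t−t₀)} · erfc((σk − (t−t₀)/σ)/√2),

and recombine. The convolved exponential is evaluated through the scaled
complementary error function wherever the plain form would overflow, so it
is stable for arbitrarily large σk (slow pulses / fast decays) and for the
absurd rate values a log-space optimizer visits in early iterations. For
k = 0 it reduces to the Gaussian CDF; as σ → 0 it reduces to a sharp
exponential. The solver is validated against stiff ODE integration
(Radau, Gaussian source sampled densely) to 1e−6 relative tolerance.

Numerical choices:

- **Near-degenerate eigenvalues** (relative gap < 1e−8): the involved
  lifetimes are perturbed by a 1e−6 multiplicative factor before
  decomposition. Exact t·e^{−kt} degenerate modes are therefore
  approximated, not solved in closed form; the error is well below the
  uncertainties of any realistic fit.
- **Complex eigenvalues** (possible only for cyclic schemes, which
  first-order photophysics does not produce) raise `NotImplementedError`
  rather than returning silently truncated populations.
- **Time grids** are arbitrary strictly-increasing vectors; no
  interpolation is ever applied to data. All times are picoseconds
  internally (the natural center of the fs–ns dynamic range); readers
  convert declared units on ingestion and log every conversion.

## Variable projection and χ²

The spectra Aᵢ(λ) are not parametrized. At every θ they are set to the
exact unweighted least-squares solution A = ΔA·X⁺ (per-wavelength
`lstsq`), making the objective a function of θ alone. The projection
remains unweighted even when per-point σᵢⱼ are declared — fidelity to the
standard formulation; rank-deficient populations (e.g. two numerically
identical curves) fall back to the minimum-norm solution with a warning,
keeping surface scans total. χ² uses the declared noise; the reduced
χ²_ν divides by (N_samples − N_vars) where N_vars counts only the free
nonlinear parameters, treating the spectra as profiled nuisance
parameters. The ε-surface variant is ½·(unweighted residual sum), so
ε = χ²σ²/2 under uniform noise.

## Fitting

Optimization runs in transformed space: strictly positive parameters
(lifetimes, FWHM) are log-transformed; t₀ is shifted by +1 ps before the
log, so t₀ → −1 ps as the transformed variable → −∞. This bounds the
domain naturally and equalizes scales across orders of magnitude.
Minimization is Levenberg–Marquardt (MINPACK via
`scipy.optimize.least_squares`) on the weighted residual vector, from
`n_starts` random starting points (default 50; log-uniform over
user-declared ranges, or [min Δt, 10·t_max] for lifetimes absent any
guidance) — multi-exponential objectives have many local minima and
multi-start is the only reliable defense. Tolerances (ftol = xtol = 1e−12,
gtol = 1e−10) are deliberately tight so that any residual optimizer
shortfall is visible to the MCMC convergence check rather than masked.
Lifetime ordering is never enforced during optimization; for parallel
schemes the labels are sorted ascending afterward.

## Posterior sampling

With Gaussian noise, P(θ|D) ∝ exp(−χ²/2)·π(θ). Priors are uniform boxes
in transformed space, wide enough by default (lifetimes in
[1e−3·median Δt, 1e3·t_max]) that a well-constrained posterior never
feels them, plus an indicator constraint τ₁ ≤ τ₂ for parallel schemes to
remove the label-swap degeneracy. Sampling uses emcee's stretch move
(a = 2) with max(32, 4·dim) walkers initialized in a relative 1e−4
Gaussian ball around the best fit, projected into the prior support if
the optimizer endpoint drifted past a bound.

Two diagnostics guard the summaries:

- **Convergence / restart.** An ensemble seeded at a premature optimizer
  endpoint drifts downhill instead of sampling. The run compares the
  minimum χ² in its first and last quartiles; a drop beyond
  max(0.01, 1e−4·χ²_min) triggers a restart from the best θ encountered
  (which is also the improved point estimate), up to 5 rounds.
- **Thinning.** Summaries are computed only after discarding the first
  quarter as burn-in and thinning by the ceiling of the maximum
  integrated autocorrelation time (emcee's estimator, tol = 0). A failed
  or non-finite estimate raises with advice to lengthen the chain —
  never silent summaries.

Summaries are reported in natural units: mean, std, CI = mean ± 2·std,
relative uncertainty 2·std/|mean|. The **evaporation flag** fires when
≥ 1% of the thinned marginal lies within 1% (of the transformed
bound-to-bound width) of a prior bound: the posterior has escaped along a
flat cost direction to the edge of the prior, meaning the parameter is
effectively unconstrained by the data (typical for lifetimes much longer
than the measurement window). The flag propagates into reports as an
explicit "unconstrained parameter" warning.

## Surfaces and subset comparisons

`scan_surface` evaluates the (by default reduced) χ² on a log-spaced
lifetime grid with the remaining parameters pinned, re-profiling the
spectra at every grid point; the τ₁ > τ₂ triangle is NaN-masked for
parallel schemes. Cells within Δ = 6 of the minimum are
connected-component labeled; a component touching the grid boundary
raises an "unbounded valley" warning — the one-component limit where a
lifetime slides to 0 or ∞. `compare_global_vs_single` runs the full
fit + sample pipeline per wavelength subset and globally, quantifying how
much simultaneous wavelengths shrink the posterior.

## Synthetic data

The generator produces exactly what the model assumes: per-species sums
of Gaussian bands (amplitude/center/width) times analytic populations,
plus i.i.d. Gaussian noise. Noise is specified either as σ directly or
as a target SNR = Σ signal² / Σ noise², in which case
σ = √(Σ signal² / (SNR · n)) so the realized SNR matches the target in
expectation (within ~2% in the mean for ≥ 1e3 points; single small
datasets scatter with the χ²ₙ distribution of the noise sum of squares).
SNR is computed on the final IRF-convolved noiseless signal matrix.

The scenario library fixes the study conditions used across the test
suite: a single-wavelength biexponential (τ = 1.5, 4.6 ps, FWHM 100 fs,
t₀ = 0) at SNR 100 or 20; a similar-lifetimes ladder (0.8, 8), (1.5, 4.6),
(2.8, 4.2), (3.5, 4) ps at σ = 0.03; a two-species multiwavelength
dataset with partially overlapping Gaussian bands (centers 450/550 nm,
widths 40/50 nm, amplitudes 1.0/0.8 — synthetic stand-ins, since no
canonical shapes exist for this benchmark); and a single slow species
(2–50 ns) observed over a 1 ns window with no added noise and an
analyst-declared σ (0.05 "high", 5e−4 "low" for the unit-amplitude
signal). Default time grids mimic delay-stage practice: linear through
the IRF, log-spaced to t_max.

What passing tests on these data do **not** show: robustness to
correlated noise between wavelengths (real detectors have it; it
over-counts the effective data and over-tightens posteriors), chirp or
coherent artifacts near t₀, or misspecified model order.

## Problem sizes

The validation suite scales the benchmark down to keep the full run in
minutes on one CPU: the multiwavelength studies use 200–500 wavelengths ×
60–100 time points (the statistic being checked — relative posterior
width at fixed global SNR — is insensitive to the wavelength count at
these sizes), chains are 800–2500 steps with 16–32 walkers, and the
acceptance script uses 300 × 100 with 1000 steps. The 2% recovery check
runs at 500 × 100, where estimator scatter is comfortably below the
tolerance; smaller unit-test fixtures assert correspondingly looser
bounds.

## Known limitations

- Exactly degenerate sequential rates are approximated by perturbation.
- The projection step is unweighted; a σ-weighted projection is not
  implemented (the profiled spectra would otherwise differ from the
  published convention).
- No wavelength-dependent IRF, dispersion/chirp curves, coherent
  artifacts, or oscillatory components.
- No Bayes-factor model selection; the number of species is the user's
  choice, and over-parametrized models will happily fit structure that
  is not a distinct physical species.
- MCMC summaries assume the sampler explored the relevant region; for
  strongly degenerate pairs (the closest ladder rung) different arms of
  the τ₁→0 / τ₂→∞ valley mix slowly, and short chains can understate
  the spread. The convergence check catches downhill drift but not slow
  mixing between arms; the surface scan is the cross-check.
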