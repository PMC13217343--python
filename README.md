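# kinfit

Global and target kinetic analysis of time-resolved difference spectra —
femtosecond transient absorption of chromophores, photoacids, fluorescent
proteins — with honest, MCMC-calibrated parameter uncertainties.

## The problem

A pump–probe experiment measures ΔA(λ, t), the change in absorbance after
photoexcitation. Global analysis models the whole matrix as a bilinear
product of a few transient species,

    ψ(λ, t) = Σᵢ Aᵢ(λ) Xᵢ(t),

where the populations Xᵢ(t) follow first-order compartment kinetics driven
by a Gaussian excitation pulse (the instrument response function, IRF):

    dXᵢ/dt = Σⱼ Tᵢⱼ Xⱼ + Jᵢ · IRF(t),      IRF(t) = N(t₀, σ²),  FWHM = √(8 ln 2)·σ.

The spectra Aᵢ(λ) enter linearly and are profiled out exactly at every
choice of the nonlinear parameters θ = (lifetimes τᵢ, t₀, FWHM) via the
Moore–Penrose pseudoinverse — variable projection. The objective is

    χ²(θ) = Σᵢⱼ (ψ_θ(λᵢ, tⱼ) − ΔA(λᵢ, tⱼ))² / σᵢⱼ²,

minimized by multi-start Levenberg–Marquardt in log-transformed parameter
space. Because multi-exponential objectives are notoriously sloppy —
curved minima inside long valleys running to τ→0 and τ→∞ — covariance
matrices from the optimizer underestimate the real uncertainty. kinfit
instead samples the posterior

    P(θ | D) ∝ exp(−χ²(θ)/2) · π(θ)

with an affine-invariant ensemble (stretch-move) MCMC sampler under wide
uniform priors, monitors the χ² trace for premature-optimizer relaxation,
thins by the integrated autocorrelation time, and reports every parameter
as mean ± 2σ with a "parameter evaporation" flag when the posterior piles
up against a prior bound (the signature of an effectively unconstrained
parameter, e.g. a lifetime much longer than the measurement window).

## Worked example

```python
import numpy as np
from kinfit import (FitConfig, SamplerConfig, default_theta_spec, fit,
                    make_scenario, run_mcmc, thin_and_summarize)

# two parallel species, lifetimes 1.5 / 4.6 ps, 100 fs IRF, SNR 100
data, truth = make_scenario("two_species_multiwavelength", seed=1,
                            n_wavelengths=300, n_times=100)

spec = default_theta_spec(truth.scheme, data.times)
res = fit(data, truth.scheme, FitConfig(n_starts=8, rng_seed=2), theta_spec=spec)
samples = run_mcmc(res.theta_best, data, truth.scheme,
                   SamplerConfig(n_steps=1000, rng_seed=3))
summary = thin_and_summarize(samples)
for p in summary.parameters:
    print(f"{p.name}: {p.mean:.4g} +/- {2*p.std:.2g} "
          f"({100*p.relative_uncertainty:.2g}% at 2 sigma)")
```

prints (exact numbers vary slightly with the seed):

```
tau1: 1.481 +/- 0.023 (1.5% at 2 sigma)
tau2: 4.615 +/- 0.068 (1.5% at 2 sigma)
t0: -0.0001041 +/- 0.00042 (4.1e+02% at 2 sigma)
fwhm: 0.1003 +/- 0.0014 (1.4% at 2 sigma)
```

Both lifetimes are recovered within ~1.5% of the generating values and
their 2σ uncertainties are around one percent — the kind of precision a
multiwavelength dataset at SNR 100 supports. (t₀'s *relative* uncertainty
is meaningless here only because its true value is 0; the absolute ±0.4 fs
interval is the informative number.)

The same machinery exposes a CLI (`kinfit simulate|fit|sample|surface|report`)
for shell-driven workflows, χ² surface scans over lifetime pairs with
valley/boundary diagnostics (`kinfit.scan_surface`), and single-wavelength
versus global comparisons (`kinfit.compare_global_vs_single`).

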