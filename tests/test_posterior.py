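"""Posterior sampling: priors, stretch-move runs, convergence, summaries.

Independent oracles: analytic Gaussian moments for a quadratic target, and
grid-normalized exp(-chi^2/2) histograms for a one-parameter kinetic model.
"""

import numpy as np
import pytest

from kinfit import (
    FitConfig,
    KineticScheme,
    Prior,
    SamplerConfig,
    check_convergence,
    default_theta_spec,
    fit,
    log_posterior,
    run_mcmc,
    sample,
    thin_and_summarize,
)
from kinfit.parameters import ParameterSpec, ThetaSpec, ThetaVector
from kinfit.posterior import PosteriorSamples


def toy_spec(bounds=(-30.0, 30.0)):
    """Two free 'lifetime' parameters with wide transformed bounds."""
    lo, hi = np.exp(bounds[0]), np.exp(bounds[1])
    return ThetaSpec(
        entries=(
            ParameterSpec("tau1", "lifetime", lower=lo, upper=hi),
            ParameterSpec("tau2", "lifetime", lower=lo, upper=hi),
        ),
        scheme=None,
    )


class TestPrior:
    def test_outside_box_is_minus_inf(self):
        spec = toy_spec()
        prior = Prior.from_spec(spec, order_lifetimes=False)
        assert prior.log_density(np.array([0.0, 0.0])) == 0.0
        assert prior.log_density(np.array([40.0, 0.0])) == -np.inf

    def test_lifetime_ordering_indicator(self):
        spec = toy_spec()
        prior = Prior.from_spec(spec, order_lifetimes=True)
        assert prior.log_density(np.array([0.0, 1.0])) == 0.0
        assert prior.log_density(np.array([1.0, 0.0])) == -np.inf


class TestLogPosterior:
    def test_outside_prior_support(self, noisy_dataset):
        data, truth = noisy_dataset
        spec = default_theta_spec(truth.scheme, data.times).with_fixed(t0=0.0, fwhm=0.1)
        prior = Prior.from_spec(spec)
        theta = ThetaVector(raw=np.array([1e3, 1e3]), spec=spec)
        assert log_posterior(theta, data, truth.scheme, prior) == -np.inf

    def test_equal_chi2_equal_posterior(self, noisy_dataset):
        data, truth = noisy_dataset
        spec = default_theta_spec(truth.scheme, data.times).with_fixed(t0=0.0, fwhm=0.1)
        prior = Prior.from_spec(spec, order_lifetimes=False)
        a = spec.encode({"tau1": 1.5, "tau2": 4.6})
        b = spec.encode({"tau1": 4.6, "tau2": 1.5})  # label swap, same model
        la = log_posterior(a, data, truth.scheme, prior)
        lb = log_posterior(b, data, truth.scheme, prior)
        assert la == pytest.approx(lb, rel=1e-12)


class TestStretchMoveSampler:
    def test_gaussian_target_moments(self):
        """Synthetic quadratic chi2 = sum(theta^2)/s^2 -> Gaussian with
        std s per coordinate."""
        s = 0.35
        spec = toy_spec()
        prior = Prior.from_spec(spec, order_lifetimes=False)
        start = ThetaVector(raw=np.array([0.01, -0.02]), spec=spec)
        cfg = SamplerConfig(n_walkers=32, n_steps=4000, rng_seed=5, init_ball_width=1e-2)
        res = sample(start, cfg, prior=prior,
                     log_prob=lambda x: -0.5 * np.sum(x**2) / s**2)
        kept = res.chains[500::10].reshape(-1, 2)
        assert np.std(kept[:, 0]) == pytest.approx(s, rel=0.03)
        assert np.std(kept[:, 1]) == pytest.approx(s, rel=0.03)
        assert np.mean(kept) == pytest.approx(0.0, abs=0.02)

    def test_seeded_determinism(self):
        spec = toy_spec()
        prior = Prior.from_spec(spec, order_lifetimes=False)
        start = ThetaVector(raw=np.zeros(2), spec=spec)
        cfg = SamplerConfig(n_walkers=8, n_steps=50, rng_seed=7)
        lp = lambda x: -0.5 * np.sum(x**2)  # noqa: E731
        a = sample(start, cfg, prior=prior, log_prob=lp)
        b = sample(start, cfg, prior=prior, log_prob=lp)
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_ordering_constraint_never_violated(self, noisy_dataset):
        data, truth = noisy_dataset
        spec = default_theta_spec(truth.scheme, data.times).with_fixed(t0=0.0, fwhm=0.1)
        prior = Prior.from_spec(spec)  # parallel scheme -> tau1 <= tau2
        assert prior.order_lifetimes
        start = spec.encode({"tau1": 1.5, "tau2": 4.6})
        cfg = SamplerConfig(n_walkers=8, n_steps=150, rng_seed=3)
        res = sample(start, cfg, data, truth.scheme, prior)
        flat = res.flat_raw
        assert np.all(flat[:, 0] <= flat[:, 1])

    def test_start_outside_support_rejected(self):
        spec = toy_spec()
        prior = Prior.from_spec(spec, order_lifetimes=True)
        start = ThetaVector(raw=np.array([1.0, 0.0]), spec=spec)
        with pytest.raises(ValueError, match="support"):
            sample(start, SamplerConfig(n_walkers=8, n_steps=10), prior=prior,
                   log_prob=lambda x: 0.0)

    def test_marginal_matches_grid_posterior(self):
        """One-parameter kinetic model: thinned MCMC histogram vs the
        grid-normalized exp(-chi^2/2) density, within binomial error."""
        from kinfit import (
            GaussianBand,
            IRFParameters,
            KineticParameters,
            NoiseSpec,
            SpectrumSpec,
            chi_squared,
            generate_dataset,
        )

        scheme = KineticScheme.parallel(1)
        t = np.linspace(0.2, 10.0, 40)
        data, truth = generate_dataset(
            scheme,
            KineticParameters((2.0,), IRFParameters(0.0, 0.1)),
            SpectrumSpec(bands=((GaussianBand(1.0, 500.0, 50.0),),)),
            np.array([500.0]),
            t,
            NoiseSpec("sigma", 0.05, rng_seed=2),
        )
        spec = default_theta_spec(scheme, t).with_fixed(t0=0.0, fwhm=0.1)
        prior = Prior.from_spec(spec)
        start = spec.encode({"tau1": 2.0})
        cfg = SamplerConfig(n_walkers=16, n_steps=3000, rng_seed=4)
        res = sample(start, cfg, data, scheme, prior)
        kept = res.chains[750::5].reshape(-1)

        grid = np.linspace(kept.min(), kept.max(), 120)
        chi2_grid = np.array(
            [chi_squared(ThetaVector(raw=np.array([g]), spec=spec), data, scheme).chi2
             for g in grid]
        )
        dens = np.exp(-0.5 * (chi2_grid - chi2_grid.min()))
        dens /= np.trapezoid(dens, grid)

        edges = np.linspace(grid[0], grid[-1], 13)
        hist, _ = np.histogram(kept, bins=edges)
        n = kept.size
        for b in range(12):
            lo, hi = edges[b], edges[b + 1]
            m = (grid >= lo) & (grid <= hi)
            if m.sum() < 2:
                continue
            p = np.trapezoid(dens[m], grid[m])
            expected = n * p
            # autocorrelation inflates sampling error; allow 5 x binomial sd
            tol = 5.0 * np.sqrt(max(expected * (1 - p), 1.0)) + 0.02 * n
            assert abs(hist[b] - expected) < tol


class TestConvergence:
    def _samples(self, trace):
        spec = toy_spec()
        steps, walkers = trace.shape
        chains = np.zeros((steps, walkers, 2))
        return PosteriorSamples(
            chains=chains,
            chi2_trace=trace,
            acceptance_fraction=0.5,
            spec=spec,
            prior=Prior.from_spec(spec, order_lifetimes=False),
        )

    def test_flat_trace_converged(self):
        ok, best = check_convergence(self._samples(np.full((100, 4), 10.0)))
        assert ok and best is None

    def test_decreasing_trace_restarts_at_argmin(self):
        trace = np.linspace(100.0, 1.0, 100)[:, None] * np.ones((1, 4))
        samples = self._samples(trace)
        ok, best = check_convergence(samples)
        assert not ok
        step, walker = np.unravel_index(np.argmin(trace), trace.shape)
        np.testing.assert_array_equal(best.raw, samples.chains[step, walker])

    def test_offset_start_restarts_then_converges(self, small_dataset):
        data, truth = small_dataset
        spec = default_theta_spec(truth.scheme, data.times).with_fixed(t0=0.0, fwhm=0.1)
        prior = Prior.from_spec(spec)
        # noiseless data needs a realistic working sigma for a finite-width
        # posterior; declare one well above the numerical floor
        from kinfit import SpectralDataset

        data = SpectralDataset(
            wavelengths=data.wavelengths, times=data.times, values=data.values,
            noise=0.01,
        )
        off = spec.encode({"tau1": 1.0, "tau2": 7.0})  # deliberately offset
        cfg = SamplerConfig(n_walkers=8, n_steps=300, rng_seed=6)
        first = sample(off, cfg, data, truth.scheme, prior)
        ok_first, best = check_convergence(first)
        assert not ok_first
        second = sample(best, SamplerConfig(n_walkers=8, n_steps=300, rng_seed=7),
                        data, truth.scheme, prior)
        ok_second, _ = check_convergence(second)
        assert ok_second


class TestThinAndSummarize:
    def _iid_samples(self, rng_seed=0, n=2000, mean=(0.5, 1.5), std=(0.1, 0.2)):
        spec = toy_spec()
        rng = np.random.default_rng(rng_seed)
        chains = rng.standard_normal((n, 8, 2)) * np.array(std) + np.array(mean)
        return PosteriorSamples(
            chains=chains,
            chi2_trace=np.ones((n, 8)),
            acceptance_fraction=0.5,
            spec=spec,
            prior=Prior.from_spec(spec, order_lifetimes=False),
        )

    def test_iid_chains_need_no_thinning(self):
        summary = thin_and_summarize(self._iid_samples())
        assert summary.thin <= 2
        assert np.all(summary.autocorrelation_times < 2.0)

    def test_gaussian_ci_halfwidth(self):
        """Transformed-space Gaussian with std s -> natural-unit CI
        half-width approx 2 * s * mean for small s."""
        summary = thin_and_summarize(self._iid_samples(std=(0.01, 0.01)))
        p = summary["tau1"]
        # lognormal with sigma = 0.01: relative 2-sigma width = 2 * 0.01
        assert p.relative_uncertainty == pytest.approx(0.02, rel=0.05)

    def test_summaries_in_natural_units(self):
        summary = thin_and_summarize(self._iid_samples(std=(0.01, 0.01)))
        assert summary["tau2"].mean == pytest.approx(np.exp(1.5), rel=0.01)
        p = summary["tau1"]
        assert p.ci_low == pytest.approx(p.mean - 2 * p.std)
        assert p.ci_high == pytest.approx(p.mean + 2 * p.std)

    def test_evaporation_flag_on_mass_at_bound(self):
        spec = toy_spec(bounds=(-5.0, 5.0))
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((1500, 8, 2)) * 0.05
        # park 5% of tau2 samples at the upper bound region
        mask = rng.random((1500, 8)) < 0.05
        chains[:, :, 1][mask] = 4.96
        samples = PosteriorSamples(
            chains=chains,
            chi2_trace=np.ones((1500, 8)),
            acceptance_fraction=0.5,
            spec=spec,
            prior=Prior.from_spec(spec, order_lifetimes=False),
        )
        summary = thin_and_summarize(samples)
        assert summary["tau2"].evaporated
        assert not summary["tau1"].evaporated
        assert summary.any_evaporated

    def test_too_short_chain_errors(self):
        spec = toy_spec()
        samples = PosteriorSamples(
            chains=np.zeros((4, 8, 2)),
            chi2_trace=np.ones((4, 8)),
            acceptance_fraction=0.5,
            spec=spec,
            prior=Prior.from_spec(spec, order_lifetimes=False),
        )
        with pytest.raises(RuntimeError):
            thin_and_summarize(samples)


def test_temperature_scaling_of_sampled_chi2(small_dataset):
    """sigma^2 acts as a temperature: the mean excess epsilon above the
    minimum scales proportionally to sigma^2 (doubling sigma quadruples
    the accessible epsilon range)."""
    from kinfit import SpectralDataset

    data0, truth = small_dataset
    spec = default_theta_spec(truth.scheme, data0.times).with_fixed(t0=0.0, fwhm=0.1)
    prior = Prior.from_spec(spec)
    start = spec.encode({"tau1": 1.5, "tau2": 4.6})
    excess = []
    for sigma in (0.005, 0.01):
        data = SpectralDataset(
            wavelengths=data0.wavelengths, times=data0.times, values=data0.values,
            noise=sigma,
        )
        cfg = SamplerConfig(n_walkers=16, n_steps=800, rng_seed=11)
        res = sample(start, cfg, data, truth.scheme, prior)
        eps_trace = 0.5 * res.chi2_trace[200:] * sigma**2  # epsilon = chi2 sigma^2 / 2
        excess.append(np.mean(eps_trace - eps_trace.min()))
    assert excess[1] / excess[0] == pytest.approx(4.0, rel=0.35)
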