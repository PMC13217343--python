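"""Posterior sampling of the kinetic parameters.

With Gaussian measurement noise, P(theta | D) ∝ exp(-chi^2(theta)/2) pi(theta);
the species spectra are profiled at every theta, so the posterior lives in
the low-dimensional nonlinear-parameter space alone.  Sampling uses the
affine-invariant ensemble "stretch move" (emcee).  Because an ensemble
started at a premature optimizer endpoint relaxes downhill rather than
sampling, the chi-squared trace is monitored: if the minimum found late in
the run undercuts the early minimum, the run is restarted from the best
point encountered, until the trace is flat.  Summaries are computed on
chains thinned by the integrated autocorrelation time, in natural units,
with intervals quoted as mean +/- 2 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np

from .kinetics import KineticScheme
from .parameters import ThetaSpec, ThetaVector
from .projection import SpectralDataset, chi_squared

__all__ = [
    "Prior",
    "SamplerConfig",
    "PosteriorSamples",
    "ParameterSummary",
    "UncertaintySummary",
    "log_posterior",
    "make_log_posterior",
    "sample",
    "check_convergence",
    "thin_and_summarize",
    "run_mcmc",
]


@dataclass(frozen=True)
class Prior:
    """Uniform prior: a box in transformed space plus optional indicator
    constraints (e.g. tau1 <= tau2 for parallel schemes, which removes the
    label-swap degeneracy)."""

    bounds: np.ndarray  # (n_free, 2) transformed-space box
    order_lifetimes: bool = False
    lifetime_indices: tuple = ()

    @classmethod
    def from_spec(cls, spec: ThetaSpec, order_lifetimes: bool = None) -> "Prior":
        if order_lifetimes is None:
            order_lifetimes = (
                spec.scheme is not None and spec.scheme.scheme_kind == "parallel"
            )
        idx = tuple(
            i for i, e in enumerate(spec.free) if e.role == "lifetime"
        )
        return cls(
            bounds=spec.transformed_bounds(),
            order_lifetimes=bool(order_lifetimes) and len(idx) > 1,
            lifetime_indices=idx,
        )

    def log_density(self, raw: np.ndarray) -> float:
        raw = np.asarray(raw, dtype=float)
        if np.any(raw < self.bounds[:, 0]) or np.any(raw > self.bounds[:, 1]):
            return -np.inf
        if self.order_lifetimes:
            taus = raw[list(self.lifetime_indices)]
            if np.any(np.diff(taus) < 0):
                return -np.inf
        return 0.0

    def project(self, raw: np.ndarray) -> np.ndarray:
        """Nearest point (coordinate-wise) inside the support: clip into the
        box with a small interior margin and sort ordered lifetimes.  Used to
        seed sampling from an optimizer endpoint that drifted past a bound."""
        raw = np.asarray(raw, dtype=float).copy()
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        raw = np.clip(raw, lo + 1e-9 * width, hi - 1e-9 * width)
        if self.order_lifetimes:
            idx = list(self.lifetime_indices)
            raw[idx] = np.sort(raw[idx])
        return raw


@dataclass(frozen=True)
class SamplerConfig:
    n_walkers: int = None  # default max(32, 4 * dim)
    n_steps: int = 5000
    stretch_a: float = 2.0
    rng_seed: int = 0
    max_restart_rounds: int = 5
    init_ball_width: float = 1e-4  # relative, transformed space


@dataclass(frozen=True)
class PosteriorSamples:
    """Raw chains (steps x walkers x dim, transformed space) plus diagnostics."""

    chains: np.ndarray
    chi2_trace: np.ndarray  # steps x walkers
    acceptance_fraction: float
    spec: ThetaSpec
    prior: Prior

    @property
    def n_steps(self) -> int:
        return self.chains.shape[0]

    @property
    def flat_raw(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def autocorrelation_times(self) -> np.ndarray:
        try:
            return np.atleast_1d(
                emcee.autocorr.integrated_time(self.chains, tol=0, quiet=False)
            )
        except emcee.autocorr.AutocorrError as exc:
            raise RuntimeError(
                "could not estimate the autocorrelation time; run a longer chain"
            ) from exc


@dataclass(frozen=True)
class ParameterSummary:
    name: str
    mean: float
    std: float
    ci_low: float
    ci_high: float
    relative_uncertainty: float
    evaporated: bool


@dataclass(frozen=True)
class UncertaintySummary:
    parameters: tuple
    autocorrelation_times: np.ndarray
    thin: int
    n_effective: int

    def __getitem__(self, name: str) -> ParameterSummary:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def any_evaporated(self) -> bool:
        return any(p.evaporated for p in self.parameters)


def log_posterior(
    theta: ThetaVector,
    data: SpectralDataset,
    scheme: KineticScheme,
    prior: Prior,
) -> float:
    """-chi^2(theta)/2 + log pi(theta); -inf outside the prior support."""
    lp = prior.log_density(theta.raw)
    if not np.isfinite(lp):
        return -np.inf
    chi2 = chi_squared(theta, data, scheme).chi2
    if not np.isfinite(chi2):
        raise ValueError(f"non-finite chi-squared inside the prior at {theta.decode()}")
    return -0.5 * chi2 + lp


def make_log_posterior(data, scheme, spec, prior):
    """Vector-argument closure for the ensemble sampler."""

    def fn(raw):
        return log_posterior(ThetaVector(raw=raw, spec=spec), data, scheme, prior)

    return fn


def _init_walkers(start_raw, n_walkers, prior, rng, width):
    dim = start_raw.size
    scale = width * np.maximum(1.0, np.abs(start_raw))
    walkers = np.empty((n_walkers, dim))
    for i in range(n_walkers):
        for _ in range(1000):
            p = start_raw + scale * rng.standard_normal(dim)
            if np.isfinite(prior.log_density(p)):
                walkers[i] = p
                break
        else:
            raise RuntimeError("could not initialize walkers inside the prior")
    return walkers


def sample(
    start: ThetaVector,
    config: SamplerConfig,
    data: SpectralDataset = None,
    scheme: KineticScheme = None,
    prior: Prior = None,
    log_prob=None,
) -> PosteriorSamples:
    """One stretch-move run from a small ball around ``start``.

    ``log_prob`` (raw-vector -> float) overrides the default projected
    chi-squared posterior; useful for sampling analytic targets.
    """
    spec = start.spec
    prior = prior or Prior.from_spec(spec)
    if not np.isfinite(prior.log_density(start.raw)):
        raise ValueError("start point lies outside the prior support")
    dim = spec.n_free
    n_walkers = config.n_walkers or max(32, 4 * dim)
    if n_walkers < 2 * dim:
        raise ValueError("need at least 2 * dim walkers")
    rng = np.random.RandomState(config.rng_seed)
    walkers = _init_walkers(
        start.raw, n_walkers, prior, rng, config.init_ball_width
    )
    if log_prob is None:
        log_prob = make_log_posterior(data, scheme, spec, prior)
    sampler = emcee.EnsembleSampler(
        n_walkers,
        dim,
        log_prob,
        moves=emcee.moves.StretchMove(a=config.stretch_a),
    )
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(walkers, config.n_steps, progress=False)
    chains = sampler.get_chain()
    lp = sampler.get_log_prob()
    return PosteriorSamples(
        chains=chains,
        chi2_trace=-2.0 * lp,  # log prior is 0 inside the support
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        spec=spec,
        prior=prior,
    )


def check_convergence(samples: PosteriorSamples, tol: float = None):
    """Flat-trace test: compare the minimum chi^2 in the first and last
    quartiles of the run.  A decrease beyond max(0.01, 1e-4 * chi2_min)
    means the ensemble was still relaxing toward the minimum; the caller
    should restart from the best theta found (returned here), which is also
    a better point estimate than the optimizer's.
    """
    trace = samples.chi2_trace
    if trace.size == 0:
        raise ValueError("empty chains")
    q = max(1, samples.n_steps // 4)
    first = float(np.min(trace[:q]))
    last = float(np.min(trace[-q:]))
    chi2_min = float(np.min(trace))
    if tol is None:
        tol = max(0.01, 1e-4 * abs(chi2_min))
    if first - last > tol:
        step, walker = np.unravel_index(np.argmin(trace), trace.shape)
        best = ThetaVector(raw=samples.chains[step, walker], spec=samples.spec)
        return False, best
    return True, None


def thin_and_summarize(
    samples: PosteriorSamples,
    discard: int = None,
    evaporation_mass: float = 0.01,
    evaporation_margin: float = 0.01,
) -> UncertaintySummary:
    """Summaries on autocorrelation-thinned flat samples, in natural units.

    The evaporation flag fires for a parameter when at least
    ``evaporation_mass`` of the thinned marginal lies within
    ``evaporation_margin`` of a prior bound, measured as a fraction of the
    bound-to-bound width in transformed space — the signature of a
    posterior escaping along a flat cost direction to the edge of the prior
    ("parameter evaporation": the parameter is effectively unconstrained).
    """
    taus = samples.autocorrelation_times()
    if not np.all(np.isfinite(taus)):
        raise RuntimeError(
            "autocorrelation time estimate failed (non-finite); run a longer chain"
        )
    thin = max(1, int(np.ceil(np.max(taus))))
    if discard is None:
        discard = samples.n_steps // 4
    kept = samples.chains[discard::thin].reshape(-1, samples.chains.shape[-1])
    if kept.shape[0] < 10:
        raise RuntimeError("too few thinned samples; run a longer chain")

    bounds = samples.prior.bounds
    out = []
    for i, entry in enumerate(samples.spec.free):
        raw_i = kept[:, i]
        nat = np.exp(raw_i) - entry.shift
        mean, std = float(np.mean(nat)), float(np.std(nat))
        lo, hi = bounds[i]
        evaporated = False
        if np.isfinite(lo) and np.isfinite(hi):
            margin = evaporation_margin * (hi - lo)
            edge = np.mean((raw_i - lo < margin) | (hi - raw_i < margin))
            evaporated = bool(edge >= evaporation_mass)
        out.append(
            ParameterSummary(
                name=entry.name,
                mean=mean,
                std=std,
                ci_low=mean - 2.0 * std,
                ci_high=mean + 2.0 * std,
                relative_uncertainty=2.0 * std / abs(mean) if mean != 0 else np.inf,
                evaporated=evaporated,
            )
        )
    return UncertaintySummary(
        parameters=tuple(out),
        autocorrelation_times=taus,
        thin=thin,
        n_effective=kept.shape[0],
    )


def run_mcmc(
    start: ThetaVector,
    data: SpectralDataset,
    scheme: KineticScheme,
    config: SamplerConfig = None,
    prior: Prior = None,
) -> PosteriorSamples:
    """Sample with the convergence-restart protocol: rerun from the best
    theta found whenever the chi-squared trace still decreases, up to
    ``max_restart_rounds`` times."""
    config = config or SamplerConfig()
    prior = prior or Prior.from_spec(start.spec)
    current = ThetaVector(raw=prior.project(start.raw), spec=start.spec)
    for round_ in range(config.max_restart_rounds + 1):
        cfg = SamplerConfig(
            n_walkers=config.n_walkers,
            n_steps=config.n_steps,
            stretch_a=config.stretch_a,
            rng_seed=config.rng_seed + round_,
            max_restart_rounds=config.max_restart_rounds,
            init_ball_width=config.init_ball_width,
        )
        samples = sample(current, cfg, data, scheme, prior)
        converged, best = check_convergence(samples)
        if converged:
            return samples
        current = best
    return samples
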