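"""Multi-start Levenberg-Marquardt minimization of the projected chi-squared.

Nonlinear least squares on the weighted residual vector in transformed
(log) parameter space, repeated from randomized starting points to escape
the local minima that plague multi-exponential fitting.  The linear
spectral parameters never appear: they are profiled out inside the
residual (variable projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticScheme, PopulationMatrix
from .parameters import ThetaSpec, ThetaVector, default_theta_spec
from .projection import (
    ChiSquaredResult,
    SpectralDataset,
    SpeciesSpectra,
    chi_squared,
    model_prediction,
)

__all__ = ["FitConfig", "StartRecord", "FitResult", "FitError", "fit", "encode", "decode"]


class FitError(RuntimeError):
    """All starts failed; carries the per-start diagnostics."""

    def __init__(self, message, records):
        super().__init__(message)
        self.records = records


def encode(values: dict, spec: ThetaSpec) -> ThetaVector:
    """Natural-unit parameter values -> transformed theta vector."""
    return spec.encode(values)


def decode(theta: ThetaVector) -> dict:
    """Transformed theta vector -> all parameters in natural units."""
    return theta.decode()


@dataclass(frozen=True)
class FitConfig:
    """Multi-start settings.

    ``start_ranges`` maps parameter name -> (lo, hi) in natural units;
    starts are drawn log-uniformly (in transformed space) within them.
    Absent an entry, lifetimes span [min dt, 10 * t_max] and t0 / fwhm
    start at their encoded initial guess with 20% transformed jitter.
    """

    n_starts: int = 50
    rng_seed: int = 0
    start_ranges: dict = field(default_factory=dict)
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-10
    max_nfev: int = 2000


@dataclass(frozen=True)
class StartRecord:
    start_raw: np.ndarray
    final_raw: np.ndarray
    chi2: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class FitResult:
    theta_best: ThetaVector
    chi2: ChiSquaredResult
    spectra: SpeciesSpectra
    populations: PopulationMatrix
    starts: tuple

    @property
    def parameters(self) -> dict:
        """Best-fit parameters in natural units."""
        return self.theta_best.decode()


def _residuals(raw, spec, data, scheme):
    theta = ThetaVector(raw=raw, spec=spec)
    try:
        _, _, psi = model_prediction(theta, data, scheme)
    except (ValueError, FloatingPointError):
        return np.full(data.n_samples, 1e150)
    r = (psi - data.values) / data.sigma_matrix
    if not np.all(np.isfinite(r)):
        return np.full(data.n_samples, 1e150)
    return r.ravel()


def _draw_starts(spec: ThetaSpec, data: SpectralDataset, config: FitConfig, rng):
    t = data.times
    dt_min = float(np.min(np.diff(t))) if t.size > 1 else 1e-3
    t_max = float(t.max())
    starts = []
    for _ in range(config.n_starts):
        raw = []
        for e in spec.free:
            if e.name in config.start_ranges:
                lo, hi = config.start_ranges[e.name]
                lo_r, hi_r = np.log(lo + e.shift), np.log(hi + e.shift)
                raw.append(rng.uniform(lo_r, hi_r))
            elif e.role == "lifetime":
                raw.append(rng.uniform(np.log(max(dt_min, 1e-6)), np.log(10.0 * t_max)))
            elif e.role == "t0":
                raw.append(np.log(e.shift) + 0.2 * rng.standard_normal())
            else:  # fwhm: start near the finest time step
                raw.append(np.log(max(dt_min, 1e-3)) + 0.2 * rng.standard_normal())
        starts.append(np.array(raw))
    return starts


def fit(
    data: SpectralDataset,
    scheme: KineticScheme,
    config: FitConfig = None,
    theta_spec: ThetaSpec = None,
    initial: dict = None,
) -> FitResult:
    """Find the best-fit nonlinear parameters by seeded multi-start LM.

    ``initial`` (natural units, free parameters) adds one deterministic
    start at that point in addition to the random ones.
    """
    config = config or FitConfig()
    spec = theta_spec or default_theta_spec(scheme, data.times)
    rng = np.random.default_rng(config.rng_seed)
    starts = _draw_starts(spec, data, config, rng)
    if initial is not None:
        starts.insert(0, spec.encode(initial).raw)

    records = []
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals,
                x0,
                args=(spec, data, scheme),
                method="lm",
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
            chi2 = 2.0 * sol.cost
            records.append(
                StartRecord(
                    start_raw=x0,
                    final_raw=sol.x,
                    chi2=float(chi2),
                    converged=bool(sol.success) and chi2 < 1e200,
                    message=sol.message,
                )
            )
        except Exception as exc:  # keep the multi-start loop total
            records.append(
                StartRecord(
                    start_raw=x0,
                    final_raw=x0,
                    chi2=np.inf,
                    converged=False,
                    message=str(exc),
                )
            )
    good = [r for r in records if r.converged and np.isfinite(r.chi2)]
    if not good:
        raise FitError("no start converged", tuple(records))
    best = min(good, key=lambda r: r.chi2)
    raw_best = np.array(best.final_raw, dtype=float)
    # lifetime labels in a parallel scheme are arbitrary: sort ascending post
    # hoc (ordering is never enforced during optimization)
    if scheme.scheme_kind == "parallel":
        idx = [i for i, e in enumerate(spec.free) if e.role == "lifetime"]
        raw_best[idx] = np.sort(raw_best[idx])
    theta_best = ThetaVector(raw=raw_best, spec=spec)
    X, A, _ = model_prediction(theta_best, data, scheme)
    return FitResult(
        theta_best=theta_best,
        chi2=chi_squared(theta_best, data, scheme),
        spectra=A,
        populations=X,
        starts=tuple(records),
    )
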