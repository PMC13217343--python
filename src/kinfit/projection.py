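"""The bilinear model and its variable-projection objective.

The measured difference spectrum is modeled as psi(lambda, t) =
sum_i A_i(lambda) X_i(t): parametrized kinetics times non-parametrized
species spectra.  For any choice of the nonlinear parameters theta the
spectra are the exact linear least-squares solution (Moore-Penrose
pseudoinverse), so the chi-squared objective depends on theta alone —
the separable / variable-projection formulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import KineticScheme, PopulationMatrix, solve_populations
from .parameters import ThetaVector

__all__ = [
    "SpectralDataset",
    "SpeciesSpectra",
    "ModelPrediction",
    "ChiSquaredResult",
    "project_spectra",
    "predict",
    "model_prediction",
    "chi_squared",
    "epsilon_surface_value",
]

log = logging.getLogger(__name__)

#: spectra label by scheme kind (evolution- / decay- / species-associated)
SPECTRA_KIND = {"sequential": "EADS", "parallel": "DADS", "target": "SADS"}


@dataclass(frozen=True)
class SpectralDataset:
    """Difference-absorption matrix with its grids and noise model.

    ``values`` is n_wavelengths x n_times in OD; ``noise`` is either a
    scalar sigma or a strictly positive matrix of per-point sigmas.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    noise: float | np.ndarray = 1.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.times, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape != (wl.size, t.size):
            raise ValueError(
                f"values shape {v.shape} != (n_wavelengths={wl.size}, n_times={t.size})"
            )
        if wl.size > 1 and not (np.all(np.diff(wl) > 0) or np.all(np.diff(wl) < 0)):
            raise ValueError("wavelength grid must be strictly monotone")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(f"non-finite value at wavelength row {bad[0]}, time col {bad[1]}")
        noise = self.noise
        if np.ndim(noise) == 0:
            if not float(noise) > 0:
                raise ValueError("noise must be strictly positive")
            noise = float(noise)
        else:
            noise = np.asarray(noise, dtype=float)
            if noise.shape != v.shape or not np.all(noise > 0):
                raise ValueError("noise matrix must match data shape and be > 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "noise", noise)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def sigma_matrix(self) -> np.ndarray:
        if np.ndim(self.noise) == 0:
            return np.full(self.values.shape, float(self.noise))
        return self.noise


@dataclass(frozen=True)
class SpeciesSpectra:
    """A: N x n_wavelengths difference spectra, one row per species."""

    A: np.ndarray
    labels: tuple = ()
    kind: str = "SADS"

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if not np.all(np.isfinite(A)):
            raise ValueError("non-finite spectra")
        labels = self.labels or tuple(f"S{i + 1}" for i in range(A.shape[0]))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_species(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class ModelPrediction:
    psi: np.ndarray


@dataclass(frozen=True)
class ChiSquaredResult:
    chi2: float
    n_samples: int
    n_vars: int

    def __post_init__(self):
        if self.n_samples <= self.n_vars:
            raise ValueError("need more data points than free parameters")

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / (self.n_samples - self.n_vars)


def project_spectra(
    X: PopulationMatrix, data: SpectralDataset, labels=(), kind="SADS"
) -> SpeciesSpectra:
    """Best-fit species spectra A given populations: the minimizer of
    ||A^T X - dA||_F^2, via the pseudoinverse (minimum-norm on rank
    deficiency).  Unweighted, matching the published formulation, even when
    the dataset declares per-point noise."""
    if not np.array_equal(X.times, data.times):
        raise ValueError("populations and dataset must share the time grid")
    # per wavelength row d: d ~= X^T a  ->  solve for a stacked over rows
    A, _, rank, _ = np.linalg.lstsq(X.X.T, data.values.T, rcond=None)
    if rank < X.n_species:
        # warnings (not logging) so repeated hits during a surface scan or
        # multi-start fit collapse to one message per call site
        warnings.warn(
            f"rank-deficient populations (rank {rank} < {X.n_species} species); "
            "returning the minimum-norm spectra",
            RuntimeWarning,
            stacklevel=2,
        )
    return SpeciesSpectra(A=A, labels=labels, kind=kind)


def predict(A: SpeciesSpectra, X: PopulationMatrix) -> ModelPrediction:
    """psi = A^T X (n_wavelengths x n_times)."""
    if A.n_species != X.n_species:
        raise ValueError("spectra / populations species-count mismatch")
    return ModelPrediction(psi=A.A.T @ X.X)


def model_prediction(
    theta: ThetaVector, data: SpectralDataset, scheme: KineticScheme
):
    """(populations, profiled spectra, psi) at theta — the variable-projection core."""
    params = theta.kinetic_parameters()
    X = solve_populations(scheme, params, data.times)
    if not np.all(np.isfinite(X.X)):
        raise ValueError(f"non-finite populations at {theta.decode()}")
    A = project_spectra(X, data, kind=SPECTRA_KIND[scheme.scheme_kind])
    psi = predict(A, X).psi
    return X, A, psi


def chi_squared(
    theta: ThetaVector, data: SpectralDataset, scheme: KineticScheme
) -> ChiSquaredResult:
    """chi^2(theta) = sum_ij (psi_theta - dA)^2 / sigma_ij^2 with the spectra
    re-profiled at this theta."""
    _, _, psi = model_prediction(theta, data, scheme)
    r = psi - data.values
    if np.ndim(data.noise) == 0:
        chi2 = float(np.sum(r * r)) / float(data.noise) ** 2
    else:
        chi2 = float(np.sum((r / data.noise) ** 2))
    return ChiSquaredResult(chi2=chi2, n_samples=data.n_samples, n_vars=theta.n_free)


def epsilon_surface_value(
    theta: ThetaVector, data: SpectralDataset, scheme: KineticScheme
) -> float:
    """Half the unweighted squared residual, i.e. chi^2 with sigma = 1 and a
    1/2 prefactor (so epsilon = chi2 * sigma^2 / 2 under uniform noise)."""
    _, _, psi = model_prediction(theta, data, scheme)
    r = psi - data.values
    return 0.5 * float(np.sum(r * r))
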