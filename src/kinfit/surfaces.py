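"""Identifiability diagnostics: chi-squared surfaces and wavelength-subset
comparisons.

Multi-exponential objectives typically show a curved minimum inside a long
valley extending toward tau -> 0 and tau -> infinity; scanning the reduced
chi-squared over lifetime pairs (spectra re-profiled at every grid point)
makes those valleys visible, and a connected-component analysis of the
near-minimum region flags unbounded directions.  Comparing single-
wavelength fits against the global fit quantifies how much the
simultaneous wavelengths constrain the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fitting import FitConfig, FitResult, fit
from .kinetics import KineticScheme
from .parameters import ThetaSpec, ThetaVector, default_theta_spec
from .posterior import (
    Prior,
    SamplerConfig,
    UncertaintySummary,
    run_mcmc,
    thin_and_summarize,
)
from .projection import SpectralDataset, chi_squared

__all__ = ["SurfaceScan", "scan_surface", "compare_global_vs_single"]


@dataclass(frozen=True)
class SurfaceScan:
    """Reduced chi-squared over a (log-spaced) lifetime grid.

    ``surface`` is NaN on masked cells (the tau1 > tau2 triangle for
    parallel schemes); ``mask`` is True there.  1D scans have ``tau2_values
    = None`` and a 1 x n surface.
    """

    tau1_values: np.ndarray
    tau2_values: np.ndarray | None
    surface: np.ndarray  # (n_tau2, n_tau1), rows indexed by tau2
    mask: np.ndarray
    statistic: str  # "reduced_chi2" | "chi2" | "epsilon"
    fixed: dict
    min_location: tuple  # (tau1, tau2 or None) at the unmasked minimum

    @property
    def min_value(self) -> float:
        return float(np.nanmin(self.surface))

    def below_threshold(self, delta: float = 6.0, raw_chi2_scale: float = None):
        """Boolean map of cells within ``delta`` of the minimum (same
        statistic as the surface unless ``raw_chi2_scale`` converts)."""
        surf = self.surface if raw_chi2_scale is None else self.surface * raw_chi2_scale
        return surf <= (np.nanmin(surf) + delta)

    def valley_components(self, delta: float = 6.0, raw_chi2_scale: float = None):
        """Connected components of the below-threshold region; warns when a
        component touches the grid boundary (an unbounded valley: the data
        cannot pin the parameter on that side)."""
        below = self.below_threshold(delta, raw_chi2_scale) & ~self.mask
        labels, n = ndimage.label(below)
        touches = []
        for comp in range(1, n + 1):
            cells = labels == comp
            touch = (
                cells[0].any()
                or cells[-1].any()
                or cells[:, 0].any()
                or cells[:, -1].any()
            )
            touches.append(bool(touch))
            if touch:
                warnings.warn(
                    "near-minimum region touches the grid boundary: "
                    "an unbounded valley (lifetime sliding to 0 or infinity)",
                    stacklevel=2,
                )
        return labels, touches


def scan_surface(
    data: SpectralDataset,
    scheme: KineticScheme,
    tau1_values,
    tau2_values=None,
    fixed: dict = None,
    statistic: str = "reduced_chi2",
    theta_spec: ThetaSpec = None,
) -> SurfaceScan:
    """Evaluate the objective on a lifetime grid with everything else fixed.

    ``fixed`` must pin every nonlinear parameter that is not a scanned
    lifetime (typically t0 and fwhm).  For parallel schemes the tau1 > tau2
    triangle is masked with NaN, never a fake value.
    """
    if statistic not in ("reduced_chi2", "chi2", "epsilon"):
        raise ValueError(f"unknown statistic {statistic!r}")
    tau1_values = np.asarray(tau1_values, dtype=float)
    if np.any(tau1_values <= 0):
        raise ValueError("grid covers non-positive lifetimes")
    fixed = dict(fixed or {})
    spec = theta_spec or default_theta_spec(scheme, data.times)
    one_d = tau2_values is None
    if not one_d:
        tau2_values = np.asarray(tau2_values, dtype=float)
        if np.any(tau2_values <= 0):
            raise ValueError("grid covers non-positive lifetimes")

    scanned = ("tau1",) if one_d else ("tau1", "tau2")
    frozen = {e.name: fixed[e.name] for e in spec.entries if e.name not in scanned}
    missing = [n for n in frozen if frozen[n] is None]
    if missing:
        raise ValueError(f"fixed values required for {missing}")
    base = spec.with_fixed(**frozen)
    mask_parallel = scheme.scheme_kind == "parallel" and not one_d

    n1 = tau1_values.size
    n2 = 1 if one_d else tau2_values.size
    surface = np.full((n2, n1), np.nan)
    mask = np.zeros((n2, n1), dtype=bool)
    for j2 in range(n2):
        for j1 in range(n1):
            point = {"tau1": tau1_values[j1]}
            if not one_d:
                point["tau2"] = tau2_values[j2]
                if mask_parallel and point["tau1"] > point["tau2"]:
                    mask[j2, j1] = True
                    continue
            theta = base.encode(point)
            if statistic == "epsilon":
                from .projection import epsilon_surface_value

                surface[j2, j1] = epsilon_surface_value(theta, data, scheme)
            else:
                res = chi_squared(theta, data, scheme)
                if statistic == "chi2":
                    surface[j2, j1] = res.chi2
                else:
                    surface[j2, j1] = res.reduced_chi2

    flat = np.where(mask, np.inf, np.where(np.isnan(surface), np.inf, surface))
    j2, j1 = np.unravel_index(np.argmin(flat), flat.shape)
    min_loc = (float(tau1_values[j1]), None if one_d else float(tau2_values[j2]))
    return SurfaceScan(
        tau1_values=tau1_values,
        tau2_values=None if one_d else tau2_values,
        surface=surface,
        mask=mask,
        statistic=statistic,
        fixed=frozen,
        min_location=min_loc,
    )


def compare_global_vs_single(
    data: SpectralDataset,
    scheme: KineticScheme,
    wavelength_subsets,
    fit_config: FitConfig = None,
    sampler_config: SamplerConfig = None,
    theta_spec: ThetaSpec = None,
) -> dict:
    """Fit + sample each wavelength subset and the full set.

    ``wavelength_subsets`` maps a label to an index array into the
    wavelength grid.  Returns label -> (FitResult, UncertaintySummary);
    the full dataset is always included under the label "global".
    """
    results = {}
    subsets = dict(wavelength_subsets)
    subsets.setdefault("global", np.arange(data.wavelengths.size))
    spec_full = theta_spec
    for label, idx in subsets.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"subset {label!r} is empty")
        sub = SpectralDataset(
            wavelengths=data.wavelengths[idx],
            times=data.times,
            values=data.values[idx],
            noise=data.noise if np.ndim(data.noise) == 0 else data.noise[idx],
        )
        spec = spec_full or default_theta_spec(scheme, sub.times)
        if sub.n_samples <= spec.n_free:
            raise ValueError(f"subset {label!r} has fewer points than parameters")
        fr = fit(sub, scheme, fit_config, theta_spec=spec)
        prior = Prior.from_spec(spec)
        samples = run_mcmc(fr.theta_best, sub, scheme, sampler_config, prior)
        results[label] = (fr, thin_and_summarize(samples))
    return results
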