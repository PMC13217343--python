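"""Dataset and scheme file I/O, plus report generation.

Two delimited-text dataset dialects are supported:

``matrix_csv``
    First row: time delays; first column: wavelengths; body: dA values.
    Rows are wavelengths (the package's wavelength-major convention).

``time_explicit``
    The transposed layout used by several global-analysis tools: first row
    wavelengths, first column times.

Units are declared at read time (wavelengths nm; times fs/ps/ns; values
OD/mOD) and normalized to nm / ps / OD on ingestion; every conversion is
logged, never silent.

Kinetic schemes are YAML documents::

    species: [S1, S2]
    kind: sequential
    transitions:
      - "S1 -> S2 : tau1"
      - "S2 -> ground : tau2"
    excitation: [S1]
    irf: {t0: 0.0, fwhm: 0.1, units: ps}
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .kinetics import IRFParameters, KineticScheme
from .posterior import UncertaintySummary
from .projection import SpectralDataset, SpeciesSpectra
from .surfaces import SurfaceScan

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_scheme",
    "write_scheme",
    "write_spectra",
    "write_surface",
    "subsample_wavelengths",
    "run_report",
]

log = logging.getLogger(__name__)

TIME_FACTORS = {"fs": 1e-3, "ps": 1.0, "ns": 1e3}
VALUE_FACTORS = {"OD": 1.0, "mOD": 1e-3}


def _check_monotone(x, name, strictly_increasing=True):
    d = np.diff(x)
    if strictly_increasing and not np.all(d > 0):
        bad = int(np.argmax(d <= 0))
        raise ValueError(f"{name} grid not strictly increasing at index {bad + 1}")


def read_dataset(
    path,
    dialect: str = "matrix_csv",
    time_units: str = "ps",
    value_units: str = "OD",
    delimiter: str = ",",
    noise=1.0,
) -> SpectralDataset:
    """Read a delimited dA(lambda, t) matrix and normalize units to ps / OD."""
    raw = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if dialect == "matrix_csv":
        times = raw[0, 1:]
        wavelengths = raw[1:, 0]
        values = raw[1:, 1:]
    elif dialect == "time_explicit":
        wavelengths = raw[0, 1:]
        times = raw[1:, 0]
        values = raw[1:, 1:].T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at wavelength row {bad[0]}, time column {bad[1]}"
        )
    tf = TIME_FACTORS[time_units]
    vf = VALUE_FACTORS[value_units]
    if tf != 1.0:
        log.info("converting times from %s to ps (x%g)", time_units, tf)
    if vf != 1.0:
        log.info("converting values from %s to OD (x%g)", value_units, vf)
    times = times * tf
    values = values * vf
    _check_monotone(times, "time")
    if wavelengths.size > 1:
        d = np.diff(wavelengths)
        if not (np.all(d > 0) or np.all(d < 0)):
            bad = int(np.argmax(~(d > 0) if d[0] > 0 else ~(d < 0)))
            raise ValueError(f"wavelength grid not monotone at index {bad + 1}")
    return SpectralDataset(
        wavelengths=wavelengths, times=times, values=values, noise=noise
    )


def write_dataset(path, data: SpectralDataset, dialect: str = "matrix_csv"):
    """Write to full float precision so read(write(x)) is lossless."""
    if dialect == "matrix_csv":
        top = np.concatenate([[np.nan], data.times])
        body = np.column_stack([data.wavelengths, data.values])
        out = np.vstack([top, body])
    elif dialect == "time_explicit":
        top = np.concatenate([[np.nan], data.wavelengths])
        body = np.column_stack([data.times, data.values.T])
        out = np.vstack([top, body])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    np.savetxt(path, out, delimiter=",", fmt="%.17g")


def read_scheme(path):
    """Parse a YAML kinetic scheme; returns (KineticScheme, IRFParameters,
    lifetime-name order)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    species = list(doc["species"])
    index = {s: i for i, s in enumerate(species)}
    transitions, decays, tau_names = [], [], []

    def tau_index(name):
        if name not in tau_names:
            tau_names.append(name)
        return tau_names.index(name)

    for line in doc.get("transitions", []):
        left, tau = (p.strip() for p in line.split(":"))
        frm, to = (p.strip() for p in left.split("->"))
        if frm not in index:
            raise ValueError(f"unknown species {frm!r}")
        if to == "ground":
            decays.append((index[frm], tau_index(tau)))
        else:
            transitions.append((index[frm], index[to], tau_index(tau)))
    excitation = [1.0 if s in set(doc.get("excitation", species[:1])) else 0.0 for s in species]
    scheme = KineticScheme(
        n_species=len(species),
        transitions=tuple(transitions),
        ground_decays=tuple(decays),
        initial_excitation=tuple(excitation),
        scheme_kind=doc.get("kind", "target"),
        species_labels=tuple(species),
    )
    irf_doc = doc.get("irf", {})
    tf = TIME_FACTORS[irf_doc.get("units", "ps")]
    irf = IRFParameters(
        t0=float(irf_doc.get("t0", 0.0)) * tf, fwhm=float(irf_doc.get("fwhm", 0.1)) * tf
    )
    return scheme, irf, tuple(tau_names)


def write_scheme(path, scheme: KineticScheme, irf: IRFParameters, tau_names=None):
    names = list(tau_names) if tau_names else [f"tau{i + 1}" for i in range(scheme.n_rates)]
    lines = [
        f"{scheme.species_labels[f]} -> {scheme.species_labels[t]} : {names[r]}"
        for f, t, r in scheme.transitions
    ] + [
        f"{scheme.species_labels[s]} -> ground : {names[r]}"
        for s, r in scheme.ground_decays
    ]
    doc = {
        "species": list(scheme.species_labels),
        "kind": scheme.scheme_kind,
        "transitions": lines,
        "excitation": [
            s for s, j in zip(scheme.species_labels, scheme.initial_excitation) if j > 0
        ],
        "irf": {"t0": float(irf.t0), "fwhm": float(irf.fwhm), "units": "ps"},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_spectra(path, wavelengths, spectra: SpeciesSpectra):
    """Wavelength column plus one column per species, labeled by kind
    (EADS / DADS / SADS)."""
    header = "wavelength_nm," + ",".join(
        f"{spectra.kind}_{lab}" for lab in spectra.labels
    )
    out = np.column_stack([np.asarray(wavelengths), spectra.A.T])
    np.savetxt(path, out, delimiter=",", header=header, comments="", fmt="%.10g")


def write_surface(path, scan: SurfaceScan):
    """Delimited surface grid with a metadata header; masked cells are 'nan'."""
    meta = {
        "statistic": scan.statistic,
        "fixed": {k: float(v) for k, v in scan.fixed.items()},
        "min_location": list(v for v in scan.min_location if v is not None),
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# tau1: " + ",".join(f"{v:.10g}" for v in scan.tau1_values) + "\n")
        if scan.tau2_values is not None:
            fh.write("# tau2: " + ",".join(f"{v:.10g}" for v in scan.tau2_values) + "\n")
        np.savetxt(fh, scan.surface, delimiter=",", fmt="%.10g")


def subsample_wavelengths(data: SpectralDataset, stride: int) -> SpectralDataset:
    """Keep every ``stride``-th wavelength — a quick robustness probe: wider
    error bars with similar best fits indicate the extra wavelengths were
    informative but partially redundant."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride >= data.wavelengths.size:
        raise ValueError("stride leaves no wavelengths")
    idx = np.arange(0, data.wavelengths.size, stride)
    return SpectralDataset(
        wavelengths=data.wavelengths[idx],
        times=data.times,
        values=data.values[idx],
        noise=data.noise if np.ndim(data.noise) == 0 else data.noise[idx],
    )


def run_report(fit_result, summary: UncertaintySummary = None, scan: SurfaceScan = None):
    """Machine-readable dict + human-readable text for a completed analysis."""
    params = fit_result.parameters
    doc = {
        "parameters": {k: float(v) for k, v in params.items()},
        "chi2": float(fit_result.chi2.chi2),
        "reduced_chi2": float(fit_result.chi2.reduced_chi2),
        "n_samples": int(fit_result.chi2.n_samples),
        "n_vars": int(fit_result.chi2.n_vars),
        "starts": [
            {"chi2": float(r.chi2), "converged": bool(r.converged)}
            for r in fit_result.starts
        ],
    }
    lines = ["# kinfit analysis report", ""]
    if summary is not None:
        doc["uncertainty"] = {
            p.name: {
                "mean": p.mean,
                "std": p.std,
                "ci_2sigma": [p.ci_low, p.ci_high],
                "relative_uncertainty": p.relative_uncertainty,
                "evaporated": p.evaporated,
            }
            for p in summary.parameters
        }
        doc["autocorrelation_times"] = [float(t) for t in summary.autocorrelation_times]
        for p in summary.parameters:
            lines.append(
                f"{p.name}: {p.mean:.6g} +/- {2 * p.std:.2g} "
                f"(2 sigma; {100 * p.relative_uncertainty:.2g}% relative)"
            )
            if p.evaporated:
                lines.append(
                    f"  WARNING: unconstrained parameter — {p.name} evaporates "
                    "to the prior bound"
                )
    else:
        for k, v in params.items():
            lines.append(f"{k}: {v:.6g} (best fit, no uncertainty run)")
    lines.append(f"chi2 = {doc['chi2']:.6g}, reduced chi2 = {doc['reduced_chi2']:.6g}")
    if scan is not None:
        doc["surface_min"] = {
            "statistic": scan.statistic,
            "value": scan.min_value,
            "location": [v for v in scan.min_location if v is not None],
        }
        lines.append(
            f"surface minimum ({scan.statistic}) = {scan.min_value:.6g} "
            f"at tau = {doc['surface_min']['location']}"
        )
    n_conv = sum(1 for r in fit_result.starts if r.converged)
    lines.append(f"multi-start: {n_conv}/{len(fit_result.starts)} starts converged")
    return doc, "\n".join(lines) + "\n"
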