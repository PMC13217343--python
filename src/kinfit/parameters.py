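"""Log-transformed nonlinear parameter bookkeeping.

The nonlinear parameters theta — lifetimes, time zero, IRF width — span
many orders of magnitude, so all fitting and sampling happens in a
transformed space: strictly positive parameters are log-transformed, and
sign-ambiguous parameters (time zero) are shifted by a constant before the
log, so that the natural value approaches ``-shift`` as the transformed
variable goes to minus infinity.  Individual parameters may be frozen; the
free (varying) ones form the raw vector optimizers and samplers see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import IRFParameters, KineticParameters, KineticScheme

__all__ = ["ParameterSpec", "ThetaSpec", "ThetaVector", "default_theta_spec"]

DEFAULT_T0_SHIFT = 1.0  # ps


@dataclass(frozen=True)
class ParameterSpec:
    """One nonlinear parameter: its role, transform shift, and bounds.

    ``shift`` is 0 for strictly positive parameters (lifetimes, fwhm) and a
    positive constant for signed ones (t0), giving transform
    ``raw = ln(value + shift)``.  Bounds are in natural units.
    """

    name: str
    role: str  # "lifetime" | "t0" | "fwhm"
    shift: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf
    vary: bool = True
    value: float = None  # natural-unit value used when frozen

    def encode_value(self, value: float) -> float:
        if not value + self.shift > 0:
            raise ValueError(
                f"parameter {self.name}: value {value} is at/below the "
                f"domain edge {-self.shift}"
            )
        return float(np.log(value + self.shift))

    def decode_value(self, raw: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(raw) - self.shift)


@dataclass(frozen=True)
class ThetaSpec:
    """Ordered set of :class:`ParameterSpec` tied to a kinetic scheme."""

    entries: tuple
    scheme: KineticScheme = None

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def free(self) -> tuple:
        return tuple(e for e in self.entries if e.vary)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def names(self) -> tuple:
        return tuple(e.name for e in self.entries)

    @property
    def free_names(self) -> tuple:
        return tuple(e.name for e in self.free)

    def encode(self, values: dict) -> "ThetaVector":
        """Natural-unit values (by name, free parameters only) -> raw vector."""
        raw = np.array([e.encode_value(values[e.name]) for e in self.free])
        return ThetaVector(raw=raw, spec=self)

    def decode_raw(self, raw) -> dict:
        """Raw vector -> all parameters in natural units (frozen ones included)."""
        raw = np.asarray(raw, dtype=float)
        if raw.size != self.n_free:
            raise ValueError(f"expected {self.n_free} raw values, got {raw.size}")
        out, i = {}, 0
        for e in self.entries:
            if e.vary:
                out[e.name] = e.decode_value(raw[i])
                i += 1
            else:
                out[e.name] = e.value
        return out

    def kinetic_parameters(self, raw) -> KineticParameters:
        vals = self.decode_raw(raw)
        n_rates = self.scheme.n_rates
        taus = tuple(vals[f"tau{i + 1}"] for i in range(n_rates))
        return KineticParameters(taus, IRFParameters(t0=vals["t0"], fwhm=vals["fwhm"]))

    def with_fixed(self, **values) -> "ThetaSpec":
        """Freeze the named parameters at the given natural-unit values."""
        entries = []
        for e in self.entries:
            if e.name in values:
                entries.append(replace(e, vary=False, value=float(values[e.name])))
            else:
                entries.append(e)
        return ThetaSpec(entries=tuple(entries), scheme=self.scheme)

    def transformed_bounds(self) -> np.ndarray:
        """(n_free, 2) prior box in transformed space."""
        out = []
        for e in self.free:
            lo = -np.inf if e.lower + e.shift <= 0 else np.log(e.lower + e.shift)
            hi = np.inf if not np.isfinite(e.upper) else np.log(e.upper + e.shift)
            out.append((lo, hi))
        return np.array(out)


@dataclass(frozen=True)
class ThetaVector:
    """A point in transformed parameter space together with its spec."""

    raw: np.ndarray
    spec: ThetaSpec

    def __post_init__(self):
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    def decode(self) -> dict:
        return self.spec.decode_raw(self.raw)

    def kinetic_parameters(self) -> KineticParameters:
        return self.spec.kinetic_parameters(self.raw)


def default_theta_spec(
    scheme: KineticScheme,
    times=None,
    t0_shift: float = DEFAULT_T0_SHIFT,
) -> ThetaSpec:
    """Spec with one lifetime per rate plus t0 and fwhm.

    Default prior bounds are deliberately wide so that well-constrained
    posteriors never feel them: lifetimes in [1e-3 * median dt, 1e3 * t_max],
    t0 in (-shift, t_max], fwhm in [1e-3, t_max] (ps).  Tighten or freeze
    via :meth:`ThetaSpec.with_fixed` / dataclasses.replace.
    """
    if times is not None:
        t = np.asarray(times, dtype=float)
        t_max = float(t.max())
        dt_med = float(np.median(np.diff(t))) if t.size > 1 else 1e-3
        tau_lo, tau_hi = 1e-3 * dt_med, 1e3 * t_max
        fwhm_hi = t_max
    else:
        tau_lo, tau_hi, t_max, fwhm_hi = 1e-12, 1e12, 1e12, 1e12
    entries = [
        ParameterSpec(f"tau{i + 1}", "lifetime", lower=tau_lo, upper=tau_hi)
        for i in range(scheme.n_rates)
    ]
    entries.append(
        ParameterSpec("t0", "t0", shift=t0_shift, lower=-t0_shift + 1e-12, upper=t_max)
    )
    entries.append(ParameterSpec("fwhm", "fwhm", lower=1e-3, upper=fwhm_hi))
    return ThetaSpec(entries=tuple(entries), scheme=scheme)
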