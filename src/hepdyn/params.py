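"""Parameter sets for the liver-inflammation model.

The computational core of the package works with the *dimensionless* system
(23 rate/saturation constants).  The dimensional parameterization exists as a
front-end: :func:`nondimensionalize` maps a dimensional parameter set onto the
dimensionless groups and the variable scalings under which the two forms of
the model agree.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "DimensionlessParameters",
    "DimensionalParameters",
    "ScaleSet",
    "default_parameters",
    "nondimensionalize",
    "rescale_for_ka",
    "load_parameters",
    "save_parameters",
]

#: Canonical ordering of the 23 dimensionless parameters.
PARAM_NAMES: tuple[str, ...] = (
    "nu", "phi", "phi_2",
    "gamma_a", "gamma_m", "gamma_m2", "gamma_g", "gamma_e", "gamma_h",
    "k_n", "k_g", "k_h", "k_m", "k_m1", "k_m2",
    "beta_a", "beta_n", "beta_c", "beta_g",
    "nu_2", "chi_h", "r_1", "r_2",
)


class InvalidParameterError(ValueError):
    """A parameter value violates the model's domain (negative, or a zero denominator)."""


@dataclass(frozen=True)
class DimensionlessParameters:
    """The 23 dimensionless rate and saturation constants of the model.

    All parameters are non-negative.  The saturation constants ``beta_a``,
    ``beta_n``, ``beta_c``, ``beta_g`` and the anti-inflammatory decay rate
    ``gamma_g`` must be strictly positive (they appear in denominators of the
    vector field and of the healthy steady state g = k_h / gamma_g).
    """

    nu: float
    phi: float
    phi_2: float
    gamma_a: float
    gamma_m: float
    gamma_m2: float
    gamma_g: float
    gamma_e: float
    gamma_h: float
    k_n: float
    k_g: float
    k_h: float
    k_m: float
    k_m1: float
    k_m2: float
    beta_a: float
    beta_n: float
    beta_c: float
    beta_g: float
    nu_2: float
    chi_h: float
    r_1: float
    r_2: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"parameter {name}={v!r} must be a finite non-negative real")
        for name in ("beta_a", "beta_n", "beta_c", "beta_g", "gamma_g"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"parameter {name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        """Values in the canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DimensionlessParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise InvalidParameterError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **overrides: float) -> "DimensionlessParameters":
        """Return a copy with some parameters overridden by name."""
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional rates, saturation constants and population sizes.

    Units follow the model's dimensional formulation (rates per day, cell and
    mediator densities per mm^3).  ``gamma_c`` sets the time scale of the
    nondimensionalization and must be positive, as must every parameter that
    appears in a denominator of a dimensionless group.
    """

    phi: float
    nu: float
    chi_n: float
    chi_m: float
    gamma_a: float
    gamma_c: float
    gamma_g: float
    gamma_m: float
    k_a: float
    k_g: float
    k_n: float
    beta_a: float
    beta_n: float
    beta_c: float
    beta_g: float
    beta_gc: float
    phi_2: float
    k_m: float
    k_m1: float
    k_m2: float
    gamma_m2: float
    nu_2: float
    chi_h: float
    gamma_e: float
    gamma_h: float
    k_ha: float
    k_h: float
    h_T: float
    r_1: float
    r_2: float
    s_T: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"parameter {f.name}={v!r} must be a finite non-negative real")
        for name in ("gamma_c", "k_a", "k_ha", "beta_gc", "chi_n", "chi_m", "h_T", "s_T"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(
                    f"parameter {name} must be strictly positive (it appears in a scaling denominator)"
                )


@dataclass(frozen=True)
class ScaleSet:
    """Multiplicative scales relating dimensional to dimensionless variables.

    ``dimensional value = scale * dimensionless value`` for each state
    variable, and ``t_dimensional = time * t_dimensionless`` (time = 1/gamma_c).
    """

    time: float
    n: float
    a: float
    m_i: float
    m_r: float
    c: float
    g: float
    h: float
    h_a: float
    e: float
    s: float
    s_a: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise InvalidParameterError(f"scale {f.name} must be strictly positive")

    def as_state_array(self) -> np.ndarray:
        """Per-variable scales in the canonical state ordering."""
        return np.array(
            [self.n, self.a, self.m_i, self.m_r, self.c, self.g,
             self.h, self.h_a, self.e, self.s, self.s_a], dtype=float)


#: Baseline dimensionless parameter values used throughout the analysis.
_DEFAULTS: dict[str, float] = {
    "nu": 0.1, "phi": 0.1, "phi_2": 10.0,
    "gamma_a": 1.0, "gamma_m": 0.01, "gamma_m2": 0.01,
    "gamma_g": 1.0, "gamma_e": 0.1, "gamma_h": 0.1,
    "k_n": 0.01, "k_g": 0.1, "k_h": 0.1, "k_m": 0.0001,
    "k_m1": 30.0, "k_m2": 0.3,
    "beta_a": 0.1, "beta_n": 0.1, "beta_c": 0.12, "beta_g": 0.01,
    "nu_2": 0.01, "chi_h": 1.0, "r_1": 1.0, "r_2": 1.0,
}


def default_parameters() -> DimensionlessParameters:
    """Baseline dimensionless parameter set used in all simulations.

    These are the default values of the model: the inflammatory-component
    rates carried over from earlier generic-inflammation modelling, plus the
    liver-specific estimates (macrophage phenotype switching an order of
    magnitude faster forward than backward, weak macrophage pro-inflammatory
    feedback k_m, hepatocyte/ECM turnover intermediate between neutrophil
    lysis and macrophage loss).
    """
    return DimensionlessParameters(**_DEFAULTS)


def nondimensionalize(dp: DimensionalParameters) -> tuple[DimensionlessParameters, ScaleSet]:
    """Map a dimensional parameter set onto the dimensionless groups.

    Time is scaled by the pro-inflammatory mediator decay rate gamma_c;
    mediator concentrations by the necrosis release magnitude k_a (for c) and
    the recruitment-saturation constant beta_gc (for g); cell populations by
    the recruitment rates chi_n, chi_m; hepatocytes/ECM by h_T k_a gamma_c / k_ha;
    stellate cells by the total population s_T.

    Returns the dimensionless parameters together with the :class:`ScaleSet`
    under which the dimensional and dimensionless vector fields agree.
    """
    gc = dp.gamma_c
    if gc <= 0:
        raise InvalidParameterError("gamma_c must be strictly positive (it sets the time scale)")
    p = DimensionlessParameters(
        nu=dp.nu / gc,
        phi=dp.phi * dp.chi_m * dp.k_a / gc**2,
        phi_2=dp.phi_2,
        gamma_a=dp.gamma_a / gc,
        gamma_m=dp.gamma_m / gc,
        gamma_m2=dp.gamma_m2 * dp.chi_m * dp.k_a / gc,
        gamma_g=dp.gamma_g / gc,
        gamma_e=dp.gamma_e / gc,
        gamma_h=dp.gamma_h / gc,
        k_n=dp.k_n / (dp.k_a * gc),
        k_g=dp.k_g * dp.chi_m * dp.k_a / (dp.beta_gc * gc**2),
        k_h=dp.k_h * dp.k_a / (dp.k_ha * dp.beta_gc),
        k_m=dp.k_m * dp.chi_m / gc**2,
        k_m1=dp.k_m1 * dp.chi_n / dp.chi_m,
        k_m2=dp.k_m2 / gc,
        beta_a=dp.beta_a * gc / (dp.chi_n * dp.k_a),
        beta_n=dp.beta_n * gc / (dp.chi_n * dp.k_a),
        beta_c=dp.beta_c / dp.k_a,
        beta_g=dp.beta_g / dp.beta_gc,
        nu_2=dp.nu_2 * dp.k_a / gc,
        chi_h=dp.chi_h,
        r_1=dp.r_1 * dp.k_a / gc,
        r_2=dp.r_2 / gc,
    )
    cell_n = dp.chi_n * dp.k_a / gc
    cell_m = dp.chi_m * dp.k_a / gc
    hep = dp.h_T * dp.k_a * gc / dp.k_ha
    scales = ScaleSet(
        time=1.0 / gc,
        n=cell_n, a=cell_n,
        m_i=cell_m, m_r=cell_m,
        c=dp.k_a, g=dp.beta_gc,
        h=hep, h_a=hep, e=hep,
        s=dp.s_T, s_a=dp.s_T,
    )
    return p, scales


# Dimensionless groups proportional / inversely proportional to dimensional k_a.
_KA_MULTIPLY = ("phi", "nu_2", "r_1", "k_g", "k_h", "gamma_m2")
_KA_DIVIDE = ("beta_c", "beta_a", "beta_n", "k_n")

_warned_ka_prose = False


def rescale_for_ka(p: DimensionlessParameters, factor: float) -> DimensionlessParameters:
    """Dimensionless parameters after multiplying *dimensional* k_a by ``factor``.

    k_a (the pro-inflammatory release on apoptotic-neutrophil necrosis) is
    scaled out by the nondimensionalization, so varying it acts on every
    dimensionless group in which it appears: phi, nu_2, r_1, k_g, k_h and
    gamma_m2 scale with k_a, while beta_c, beta_a, beta_n and k_n scale
    inversely.  All other groups are unchanged.

    Note: gamma_m2 here follows its defining group (proportional to k_a).
    Discussions of this rescaling sometimes group gamma_m2 with the
    inversely-scaling saturation constants; that direction is inconsistent
    with the group definition and is not used.
    """
    global _warned_ka_prose
    if not np.isfinite(factor) or factor <= 0:
        raise InvalidParameterError(f"k_a rescaling factor must be positive, got {factor!r}")
    if not _warned_ka_prose:
        warnings.warn(
            "rescale_for_ka scales gamma_m2 proportionally to k_a, following its "
            "dimensionless group definition.", stacklevel=2)
        _warned_ka_prose = True
    updates = {name: getattr(p, name) * factor for name in _KA_MULTIPLY}
    updates.update({name: getattr(p, name) / factor for name in _KA_DIVIDE})
    return p.replace(**updates)


def save_parameters(p: DimensionlessParameters, path: str | Path) -> None:
    """Write a parameter set as a flat JSON key-value file."""
    Path(path).write_text(json.dumps(p.to_dict(), indent=1) + "\n")


def load_parameters(path: str | Path) -> DimensionlessParameters:
    """Read a parameter set from a flat JSON key-value file."""
    return DimensionlessParameters.from_dict(json.loads(Path(path).read_text()))
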