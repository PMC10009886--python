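"""State variables and vector fields of the liver-inflammation model.

The model couples the acute inflammatory response (active and apoptotic
neutrophils n, a; pro-inflammatory and restorative macrophages m_i, m_r;
lumped pro- and anti-inflammatory mediators c, g) to the liver tissue itself
(healthy and damaged hepatocytes h, h_a; extracellular matrix e; quiescent and
activated stellate cells s, s_a).  Two conservation laws are built into the
equations: total tissue h + h_a + e and total stellate population s + s_a are
constant along trajectories.

The eleven dimensionless equations are the computational core.  The
dimensional form is provided for parameter front-end purposes only; under the
scalings of :func:`hepdyn.params.nondimensionalize` the two agree exactly.

The right-hand side is written once, in :func:`_field_terms`, over generic
arithmetic, so the same expressions serve float evaluation, the sympy-derived
analytic Jacobians, and the reduced (9-variable) system obtained by
eliminating e and s_a through the conservation laws.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .params import PARAM_NAMES, DimensionalParameters, DimensionlessParameters

__all__ = [
    "STATE_NAMES",
    "REDUCED_NAMES",
    "State",
    "InitialConditions",
    "initial_state",
    "rhs",
    "rhs_dimensional",
    "rhs_reduced",
    "reduce_state",
    "expand_state",
    "jacobian_reduced",
    "jacobian_full",
    "ConservationError",
]

#: Canonical state ordering, matching the order of the governing equations.
STATE_NAMES: tuple[str, ...] = ("n", "a", "m_i", "m_r", "c", "g", "h", "h_a", "e", "s", "s_a")

#: Ordering of the reduced (conservation-eliminated) state.
REDUCED_NAMES: tuple[str, ...] = ("n", "a", "m_i", "m_r", "c", "g", "h", "h_a", "s")

#: Indices of the reduced variables within the full state.
REDUCED_INDICES: tuple[int, ...] = tuple(STATE_NAMES.index(k) for k in REDUCED_NAMES)

#: Absolute tolerance on the conservation laws for state reduction/expansion.
CONSERVATION_TOL = 1e-6


class ConservationError(ValueError):
    """A state violates the tissue or stellate conservation law beyond tolerance."""


@dataclass(frozen=True)
class State:
    """The eleven dimensionless populations and mediator concentrations."""

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

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "State":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(STATE_NAMES),):
            raise ValueError(f"expected a state vector of length {len(STATE_NAMES)}, got shape {x.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, x))))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in STATE_NAMES}


@dataclass(frozen=True)
class InitialConditions:
    """A damage stimulus: healthy quiescent tissue hit by a mediator burst c0."""

    c0: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.c0) or self.c0 < 0:
            raise ValueError(f"stimulus strength c0 must be a finite non-negative real, got {self.c0!r}")

    @property
    def state(self) -> State:
        return initial_state(self.c0)


def initial_state(c0: float) -> State:
    """Healthy tissue (h = 1, s = 1) stimulated by pro-inflammatory burst c(0) = c0."""
    if not np.isfinite(c0) or c0 < 0:
        raise ValueError(f"stimulus strength c0 must be a finite non-negative real, got {c0!r}")
    return State(n=0.0, a=0.0, m_i=0.0, m_r=0.0, c=float(c0), g=0.0,
                 h=1.0, h_a=0.0, e=0.0, s=1.0, s_a=0.0)


def _field_terms(n, a, m_i, m_r, c, g, h, h_a, e, s, s_a, p):
    """The eleven dimensionless time derivatives, over generic arithmetic.

    ``p`` is any object exposing the 23 dimensionless parameters as
    attributes (floats or sympy symbols).
    """
    # Neutrophil apoptosis is promoted by the anti-inflammatory mediator and
    # suppressed by the pro-inflammatory one.
    apoptosis = p.nu * (1 + g / p.beta_g) / (1 + c / p.beta_c) * n
    phag = m_i + p.phi_2 * m_r          # effective phagocyte density
    d_n = c / (1 + g) - apoptosis
    d_a = apoptosis - p.gamma_a * a - p.phi * a * phag
    d_m_i = c - p.k_m1 * p.phi * a * m_i + p.k_m2 * m_r - p.gamma_m * m_i * (1 + p.gamma_m2 * m_r)
    d_m_r = p.k_m1 * p.phi * a * m_i - p.k_m2 * m_r - p.gamma_m * m_r
    d_c = (p.gamma_a * a**2 / (p.beta_a**2 + a**2)
           + p.k_n * n**2 / (p.beta_n**2 + n**2)
           + h_a + p.k_m * m_i - c)
    d_g = p.k_g * m_r + p.k_h * h - p.gamma_g * g
    removal = p.chi_h * p.phi * h_a * phag     # macrophage clearance of damaged hepatocytes
    d_h = removal * s + p.gamma_e * e - p.nu_2 * h * c + p.gamma_h * h_a * s
    d_h_a = p.nu_2 * h * c - removal - p.gamma_h * h_a
    d_e = removal * s_a - p.gamma_e * e + p.gamma_h * h_a * s_a
    d_s = p.r_2 * s_a * (1 + g) - p.r_1 * s * c
    d_s_a = p.r_1 * s * c - p.r_2 * s_a * (1 + g)
    return (d_n, d_a, d_m_i, d_m_r, d_c, d_g, d_h, d_h_a, d_e, d_s, d_s_a)


def rhs(x, p: DimensionlessParameters) -> np.ndarray:
    """Time derivatives of the full 11-variable dimensionless system.

    ``x`` may be a :class:`State` or an array in :data:`STATE_NAMES` order.
    Negative components are *not* clipped; the vector field is evaluated as
    written.
    """
    if isinstance(x, State):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state passed to rhs")
    return np.array(_field_terms(*x, p), dtype=float)


def rhs_dimensional(x, dp: DimensionalParameters) -> np.ndarray:
    """Time derivatives of the dimensional form of the model."""
    if isinstance(x, State):
        x = x.as_array()
    n, a, m_i, m_r, c, g, h, h_a, e, s, s_a = np.asarray(x, dtype=float)
    apoptosis = dp.nu * (1 + g / dp.beta_g) / (1 + c / dp.beta_c) * n
    phag = m_i + dp.phi_2 * m_r
    d_n = dp.chi_n * c / (1 + g / dp.beta_gc) - apoptosis
    d_a = apoptosis - dp.gamma_a * a - dp.phi * a * phag
    d_m_i = (dp.chi_m * c - dp.k_m1 * dp.phi * a * m_i + dp.k_m2 * m_r
             - dp.gamma_m * m_i * (1 + dp.gamma_m2 * m_r))
    d_m_r = dp.k_m1 * dp.phi * a * m_i - dp.k_m2 * m_r - dp.gamma_m * m_r
    d_c = (dp.k_a * dp.gamma_a * a**2 / (dp.beta_a**2 + a**2)
           + dp.k_n * n**2 / (dp.beta_n**2 + n**2)
           + dp.k_ha * h_a / dp.h_T + dp.k_m * m_i - dp.gamma_c * c)
    d_g = dp.k_g * m_r + dp.k_h * h / dp.h_T - dp.gamma_g * g
    removal = dp.chi_h * dp.phi * h_a * phag
    d_h = removal * s / dp.s_T + dp.gamma_e * e - dp.nu_2 * h * c + dp.gamma_h * h_a * s / dp.s_T
    d_h_a = dp.nu_2 * h * c - removal - dp.gamma_h * h_a
    d_e = removal * s_a / dp.s_T - dp.gamma_e * e + dp.gamma_h * h_a * s_a / dp.s_T
    d_s = dp.r_2 * s_a * (1 + g / dp.beta_gc) - dp.r_1 * s * c
    d_s_a = dp.r_1 * s * c - dp.r_2 * s_a * (1 + g / dp.beta_gc)
    return np.array([d_n, d_a, d_m_i, d_m_r, d_c, d_g, d_h, d_h_a, d_e, d_s, d_s_a])


def reduce_state(x, h_total: float = 1.0, s_total: float = 1.0,
                 tol: float = CONSERVATION_TOL) -> np.ndarray:
    """Project a full state onto the 9 reduced coordinates (n, a, m_i, m_r, c, g, h, h_a, s).

    The conservation laws h + h_a + e = h_total and s + s_a = s_total must
    hold to within ``tol``; e and s_a then carry no independent information.
    """
    if isinstance(x, State):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    if abs(x[6] + x[7] + x[8] - h_total) > tol:
        raise ConservationError(
            f"h + h_a + e = {x[6] + x[7] + x[8]!r} deviates from {h_total} by more than {tol}")
    if abs(x[9] + x[10] - s_total) > tol:
        raise ConservationError(
            f"s + s_a = {x[9] + x[10]!r} deviates from {s_total} by more than {tol}")
    return x[list(REDUCED_INDICES)].copy()


def expand_state(y, h_total: float = 1.0, s_total: float = 1.0,
                 tol: float = CONSERVATION_TOL) -> State:
    """Reconstruct the full state from reduced coordinates via the conservation laws."""
    y = np.asarray(y, dtype=float)
    if y.shape != (9,):
        raise ValueError(f"expected a reduced state of length 9, got shape {y.shape}")
    n, a, m_i, m_r, c, g, h, h_a, s = map(float, y)
    if h + h_a > h_total + tol:
        raise ConservationError(f"h + h_a = {h + h_a!r} exceeds the tissue total {h_total}")
    if s > s_total + tol:
        raise ConservationError(f"s = {s!r} exceeds the stellate total {s_total}")
    return State(n=n, a=a, m_i=m_i, m_r=m_r, c=c, g=g,
                 h=h, h_a=h_a, e=h_total - h - h_a, s=s, s_a=s_total - s)


class _SymbolView:
    """Expose a dict of sympy symbols through attribute access for _field_terms."""

    def __init__(self, symbols: dict[str, sp.Symbol]):
        self._symbols = symbols

    def __getattr__(self, name: str) -> sp.Symbol:
        try:
            return self._symbols[name]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(name) from exc


@lru_cache(maxsize=1)
def _symbolic_reduced():
    """Sympy expressions for the reduced field and its state Jacobian, lambdified.

    Returns (f, J) with signatures f(y9, params23, h_total, s_total) and
    J(y9, params23, h_total, s_total).
    """
    y = sp.symbols(" ".join(f"y{i}" for i in range(9)), real=True)
    prm = sp.symbols(" ".join(PARAM_NAMES), positive=True)
    h_tot, s_tot = sp.symbols("h_total s_total", positive=True)
    pview = _SymbolView(dict(zip(PARAM_NAMES, prm)))
    n, a, m_i, m_r, c, g, h, h_a, s = y
    full = _field_terms(n, a, m_i, m_r, c, g, h, h_a,
                        h_tot - h - h_a, s, s_tot - s, pview)
    reduced = sp.Matrix([full[i] for i in REDUCED_INDICES])
    jac = reduced.jacobian(sp.Matrix(y))
    f = sp.lambdify((y, prm, h_tot, s_tot), reduced, modules="numpy")
    J = sp.lambdify((y, prm, h_tot, s_tot), jac, modules="numpy")
    return f, J


@lru_cache(maxsize=1)
def _symbolic_full_jacobian():
    """Lambdified 11x11 state Jacobian of the full system (for stiff integrators)."""
    xs = sp.symbols(" ".join(f"x{i}" for i in range(11)), real=True)
    prm = sp.symbols(" ".join(PARAM_NAMES), positive=True)
    pview = _SymbolView(dict(zip(PARAM_NAMES, prm)))
    exprs = sp.Matrix(_field_terms(*xs, pview))
    jac = exprs.jacobian(sp.Matrix(xs))
    return sp.lambdify((xs, prm), jac, modules="numpy")


def rhs_reduced(y, p: DimensionlessParameters,
                h_total: float = 1.0, s_total: float = 1.0) -> np.ndarray:
    """Time derivatives of the reduced 9-variable system.

    Equal, by construction, to the corresponding components of :func:`rhs`
    evaluated on the expanded state.
    """
    y = np.asarray(y, dtype=float)
    n, a, m_i, m_r, c, g, h, h_a, s = y
    full = _field_terms(n, a, m_i, m_r, c, g, h, h_a,
                        h_total - h - h_a, s, s_total - s, p)
    return np.array([full[i] for i in REDUCED_INDICES], dtype=float)


def jacobian_reduced(y, p: DimensionlessParameters, method: str = "analytic",
                     h_total: float = 1.0, s_total: float = 1.0) -> np.ndarray:
    """9x9 Jacobian of the reduced vector field with respect to the state.

    ``method="analytic"`` evaluates exact symbolic partial derivatives;
    ``method="finite_difference"`` uses central differences (step scaled to
    the state magnitude), provided as an independent cross-check.
    """
    y = np.asarray(y, dtype=float)
    if method == "analytic":
        _, J = _symbolic_reduced()
        return np.asarray(J(y, p.as_array(), h_total, s_total), dtype=float)
    if method == "finite_difference":
        J = np.empty((9, 9))
        for j in range(9):
            step = 1e-6 * max(1.0, abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += step
            ym[j] -= step
            J[:, j] = (rhs_reduced(yp, p, h_total, s_total)
                       - rhs_reduced(ym, p, h_total, s_total)) / (2 * step)
        return J
    raise ValueError(f"unknown Jacobian method {method!r}")


def jacobian_full(x, p: DimensionlessParameters) -> np.ndarray:
    """11x11 Jacobian of the full vector field (singular along the conserved directions)."""
    if isinstance(x, State):
        x = x.as_array()
    J = _symbolic_full_jacobian()
    return np.asarray(J(np.asarray(x, dtype=float), p.as_array()), dtype=float)
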