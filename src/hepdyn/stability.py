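"""Equilibria of the reduced system and their stability.

The healthy (resolved) equilibrium — all inflammatory components zero, tissue
fully hepatocellular — admits a closed form, and its stability reduces to a
cubic characteristic factor in the four parameters (gamma_h, gamma_m, k_m,
nu_2) coupling macrophage and hepatocyte feedbacks.  The Routh–Hurwitz
conditions on that cubic give explicit thresholds in nu_2 (hepatocyte damage
susceptibility) and k_m (macrophage pro-inflammatory feedback) beyond which
resolution is impossible.  Chronic equilibria (c > 0) have no tractable closed
form and are found numerically by damped-Newton iteration from multistart
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .model import (State, expand_state, jacobian_reduced, rhs_reduced)
from .params import DimensionlessParameters, InvalidParameterError

__all__ = [
    "STABILITY_TOL",
    "CubicCoefficients",
    "StabilityReport",
    "Equilibrium",
    "healthy_steady_state",
    "jacobian",
    "healthy_cubic",
    "healthy_is_stable",
    "critical_nu2",
    "critical_km",
    "newton_equilibrium",
    "find_steady_states",
    "stability_report",
    "report_to_dict",
]

#: An equilibrium is "stable" iff max Re(lambda) < -STABILITY_TOL, "unstable"
#: iff > +STABILITY_TOL, and "marginal" in between (so that transcritical and
#: Hopf points are never misclassified by round-off).
STABILITY_TOL = 1e-9

#: A steady state is "chronic" when its pro-inflammatory mediator level
#: exceeds this (the healthy branch has c identically zero).
CHRONIC_C_MIN = 1e-7


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the cubic factor lambda^3 + a2 lambda^2 + a1 lambda + a0
    of the healthy-state characteristic polynomial."""

    a2: float
    a1: float
    a0: float

    def roots(self) -> np.ndarray:
        return np.roots([1.0, self.a2, self.a1, self.a0])


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue stability of an equilibrium of the reduced system."""

    equilibrium: State
    eigenvalues: np.ndarray          # 9 complex eigenvalues, descending real part
    is_stable: bool
    is_marginal: bool
    leading_pair: np.ndarray         # eigenvalue(s) attaining the max real part
    routh_hurwitz: "CubicCoefficients | None" = None
    routh_hurwitz_conditions: "dict[str, float] | None" = None  # per-condition margins

    @property
    def max_real_part(self) -> float:
        return float(self.eigenvalues[0].real)


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the reduced system, labelled healthy or chronic."""

    state: State
    kind: str                        # "healthy" | "chronic"
    stability: StabilityReport
    residual: float = field(default=0.0)


def healthy_steady_state(p: DimensionlessParameters) -> Equilibrium:
    """The resolved equilibrium: h = s = 1, g = k_h / gamma_g, all else zero.

    At this state hepatocyte-derived anti-inflammatory tone balances mediator
    decay exactly; the vector field vanishes identically.
    """
    if p.gamma_g <= 0:
        raise InvalidParameterError("gamma_g must be positive for the healthy steady state")
    y = np.zeros(9)
    y[5] = p.k_h / p.gamma_g  # g
    y[6] = 1.0                # h
    y[8] = 1.0                # s
    rep = stability_report(y, p, routh_hurwitz=True)
    return Equilibrium(state=expand_state(y), kind="healthy", stability=rep,
                       residual=float(np.max(np.abs(rhs_reduced(y, p)))))


def jacobian(y, p: DimensionlessParameters, method: str = "analytic") -> np.ndarray:
    """9x9 Jacobian of the reduced vector field (analytic or central finite differences)."""
    return jacobian_reduced(np.asarray(y, dtype=float), p, method=method)


def healthy_cubic(p: DimensionlessParameters) -> CubicCoefficients:
    """The cubic factor of the characteristic polynomial at the healthy state.

    Six of the nine eigenvalues are negative for all admissible parameters;
    the remaining three are the roots of
    lambda^3 + a2 lambda^2 + a1 lambda + a0 with

        a2 = 1 + gamma_h + gamma_m
        a1 = gamma_h + gamma_m - k_m - nu_2 + gamma_h gamma_m
        a0 = gamma_h gamma_m - gamma_h k_m - gamma_m nu_2
    """
    return CubicCoefficients(
        a2=1.0 + p.gamma_h + p.gamma_m,
        a1=p.gamma_h + p.gamma_m - p.k_m - p.nu_2 + p.gamma_h * p.gamma_m,
        a0=p.gamma_h * p.gamma_m - p.gamma_h * p.k_m - p.gamma_m * p.nu_2,
    )


def _routh_hurwitz_margins(p: DimensionlessParameters) -> dict[str, float]:
    """Margins (LHS - RHS) of the three healthy-state stability inequalities.

    The conditions a0, a1, a2 > 0 and a1 a2 > a0 on the cubic expand to:

      (i)   (gamma_h+gamma_m)^2 + (gamma_h+gamma_m)(gamma_h gamma_m + 1)
              > k_m (gamma_m + 1) + nu_2 (gamma_h + 1)
      (ii)  gamma_h + gamma_m + gamma_h gamma_m > k_m + nu_2
      (iii) gamma_m (1 - nu_2/gamma_h) > k_m

    All must hold strictly for a resolved outcome to be permissible.
    Condition (iii) is returned in the product form
    gamma_m (gamma_h - nu_2) - gamma_h k_m > 0 (equivalent for gamma_h > 0,
    and well defined at gamma_h = 0).
    """
    gh, gm, km, n2 = p.gamma_h, p.gamma_m, p.k_m, p.nu_2
    return {
        "a1a2_gt_a0": (gh + gm) ** 2 + (gh + gm) * (gh * gm + 1) - km * (gm + 1) - n2 * (gh + 1),
        "a1_positive": gh + gm + gh * gm - km - n2,
        "a0_positive": gm * (gh - n2) - gh * km,
    }


def healthy_is_stable(p: DimensionlessParameters) -> tuple[bool, dict[str, float]]:
    """Whether the healthy state is linearly stable, with per-condition margins.

    Returns ``(verdict, margins)`` where each margin is the (strictly
    positive, if satisfied) slack of the corresponding Routh–Hurwitz
    inequality.
    """
    margins = _routh_hurwitz_margins(p)
    return all(m > 0 for m in margins.values()), margins


def critical_nu2(p: DimensionlessParameters) -> float:
    """Hepatocyte-damage threshold nu_2* = gamma_h (1 - k_m / gamma_m).

    For nu_2 above this value the healthy state is a saddle (the constant
    coefficient a0 of the characteristic cubic changes sign) and chronic
    outcomes are guaranteed.
    """
    if p.gamma_m <= 0:
        raise InvalidParameterError("gamma_m must be positive for the nu_2 threshold")
    return p.gamma_h * (1.0 - p.k_m / p.gamma_m)


def critical_km(p: DimensionlessParameters) -> float:
    """Macrophage-feedback threshold k_m* = gamma_m (1 - nu_2 / gamma_h).

    For k_m above this value the healthy state is unstable regardless of the
    phagocytosis rate phi, so chronic damage is the only permissible outcome.
    """
    if p.gamma_h <= 0:
        raise InvalidParameterError("gamma_h must be positive for the k_m threshold")
    return p.gamma_m * (1.0 - p.nu_2 / p.gamma_h)


def stability_report(y, p: DimensionlessParameters, routh_hurwitz: bool = False) -> StabilityReport:
    """Eigenvalue stability of the reduced Jacobian at a state ``y``."""
    y = np.asarray(y, dtype=float)
    J = jacobian_reduced(y, p)
    eig = np.linalg.eigvals(J)
    order = np.argsort(-eig.real)
    eig = eig[order]
    mx = eig[0].real
    leading = eig[np.isclose(eig.real, mx, rtol=0.0, atol=1e-12)]
    rh = healthy_cubic(p) if routh_hurwitz else None
    margins = _routh_hurwitz_margins(p) if routh_hurwitz else None
    return StabilityReport(
        equilibrium=expand_state(y, tol=np.inf),
        eigenvalues=eig,
        is_stable=bool(mx < -STABILITY_TOL),
        is_marginal=bool(abs(mx) <= STABILITY_TOL),
        leading_pair=leading,
        routh_hurwitz=rh,
        routh_hurwitz_conditions=margins,
    )


def newton_equilibrium(y0, p: DimensionlessParameters, max_iter: int = 200,
                       tol: float = 1e-12, max_halvings: int = 8) -> np.ndarray | None:
    """Damped Newton iteration on the reduced vector field.

    Step halving (at most ``max_halvings`` times per iteration) enforces a
    decrease of the residual infinity-norm.  Returns the root, or ``None`` on
    non-convergence.
    """
    y = np.asarray(y0, dtype=float).copy()
    with np.errstate(all="ignore"):
        f = rhs_reduced(y, p)
        fn = np.max(np.abs(f))
        for _ in range(max_iter):
            if fn < tol:
                return y
            J = jacobian_reduced(y, p)
            if not np.all(np.isfinite(J)):
                return None
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            for _ in range(max_halvings + 1):
                y_new = y + lam * step
                f_new = rhs_reduced(y_new, p)
                fn_new = np.max(np.abs(f_new))
                if np.isfinite(fn_new) and fn_new < fn:
                    break
                lam *= 0.5
            else:
                return None
            y, f, fn = y_new, f_new, fn_new
    return y if fn < tol else None


def find_steady_states(p: DimensionlessParameters, n_starts: int = 64,
                       domain_box: np.ndarray | None = None,
                       seed: int = 0) -> list[Equilibrium]:
    """Multistart Newton search for equilibria of the reduced system.

    Starting points are a Latin-hypercube sample over ``domain_box`` (default:
    [0, 5] for the immune variables and mediators, [0, 1] for h, h_a, s —
    chronic states sit at O(1)–O(10) immune scales).  Converged roots are
    deduplicated at infinity-norm distance 1e-6; the healthy state is always
    included.  Roots with h + h_a outside [0, 1] or negative components
    (beyond round-off) are discarded as unphysical.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    if domain_box is None:
        lo = np.zeros(9)
        hi = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 1.0, 1.0, 1.0])
    else:
        domain_box = np.asarray(domain_box, dtype=float)
        lo, hi = domain_box[:, 0], domain_box[:, 1]
    sampler = qmc.LatinHypercube(d=9, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)

    healthy = healthy_steady_state(p)
    roots = [reduce_y(healthy.state)]
    for y0 in starts:
        y = newton_equilibrium(y0, p)
        if y is None:
            continue
        if np.min(y) < -1e-8 or y[6] + y[7] > 1.0 + 1e-8 or y[8] > 1.0 + 1e-8:
            continue
        if all(np.max(np.abs(y - r)) > 1e-6 for r in roots):
            roots.append(y)

    out = [healthy]
    for y in roots[1:]:
        kind = "chronic" if y[4] > CHRONIC_C_MIN else "healthy"
        out.append(Equilibrium(
            state=expand_state(np.clip(y, 0.0, None), tol=1e-5),
            kind=kind,
            stability=stability_report(y, p),
            residual=float(np.max(np.abs(rhs_reduced(y, p)))),
        ))
    return out


def report_to_dict(eq: Equilibrium) -> dict:
    """JSON-serializable view of an equilibrium and its stability report."""
    rep = eq.stability
    out = {
        "kind": eq.kind,
        "state": eq.state.to_dict(),
        "residual": eq.residual,
        "is_stable": rep.is_stable,
        "is_marginal": rep.is_marginal,
        "eigenvalues": [[float(l.real), float(l.imag)] for l in rep.eigenvalues],
    }
    if rep.routh_hurwitz is not None:
        out["routh_hurwitz"] = {
            "a2": rep.routh_hurwitz.a2, "a1": rep.routh_hurwitz.a1,
            "a0": rep.routh_hurwitz.a0,
            "condition_margins": rep.routh_hurwitz_conditions,
        }
    return out


def reduce_y(state: State) -> np.ndarray:
    """Reduced coordinates of a full state (no conservation check; equilibria only)."""
    x = state.as_array()
    return x[[0, 1, 2, 3, 4, 5, 6, 7, 9]]
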