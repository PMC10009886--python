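"""Numerical bifurcation analysis: branch continuation and event location.

Equilibrium branches are traced by pseudo-arclength continuation (secant
predictor, Newton corrector on the bordered system), which follows folds.
Along a branch, Hopf points are detected by sign changes of the real part of
the leading complex eigenvalue pair, and zero crossings of real eigenvalues
(saddle-node or, on the healthy c = 0 branch, transcritical points) by sign
changes of the Jacobian determinant; each event is located by bisection to an
indicator tolerance of 1e-8.

Hopf criticality is classified empirically, by simulating on the
unstable-equilibrium side of the located point: a small bounded oscillation
around the equilibrium indicates a supercritical Hopf (stable emergent
orbit), escape to a remote attractor indicates a subcritical one.

Two-parameter Hopf loci are traced by re-locating the one-parameter Hopf at
each scan value via bracketed bisection seeded from the previous point.
Periodic branches are characterized by direct simulation with attractor
hand-off between parameter values; saddle-node-of-periodic-orbits windows are
flagged by up/down-sweep hysteresis and homoclinic approaches by period
blow-up — both heuristically (bracketed, not point-located).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import expand_state, jacobian_reduced, rhs_reduced
from .params import DimensionlessParameters
from .simulate import (NotOscillatoryError, classify_outcome, integrate,
                       metrics_from_trajectory)
from .stability import (StabilityReport, healthy_is_stable, newton_equilibrium,
                        stability_report)

__all__ = [
    "Branch",
    "BifurcationPoint",
    "HopfLocus",
    "PeriodicBranch",
    "continue_branch",
    "detect_and_locate_bifurcations",
    "classify_hopf",
    "locate_hopf_bisection",
    "trace_hopf_two_param",
    "periodic_branch",
    "chronic_equilibrium",
]

#: Newton corrector tolerance on the reduced vector field along a branch.
CORRECTOR_TOL = 1e-10
#: Bisection tolerance on bifurcation indicators.
INDICATOR_TOL = 1e-8
#: Eigenvalues with |Im| above this count as a complex pair.
COMPLEX_IM_MIN = 1e-8


@dataclass
class Branch:
    """A continuation curve of equilibria in one free parameter."""

    param: str
    values: np.ndarray                     # (npts,) free-parameter values (folds allowed)
    states: np.ndarray                     # (npts, 9) reduced equilibria
    reports: list[StabilityReport]
    termination: str = "range_end"         # range_end | min_step | max_points
    n_corrector_failures: int = 0

    def __len__(self) -> int:
        return len(self.values)

    @property
    def stable(self) -> np.ndarray:
        return np.array([r.is_stable for r in self.reports])

    @property
    def residuals(self) -> np.ndarray:
        return np.array([
            np.max(np.abs(rhs_reduced(self.states[i], self._params_at(i))))
            for i in range(len(self))])

    # filled in by continue_branch for residual re-evaluation
    base_params: DimensionlessParameters | None = None

    def _params_at(self, i: int) -> DimensionlessParameters:
        return self.base_params.replace(**{self.param: float(self.values[i])})


@dataclass
class BifurcationPoint:
    """A located codimension-one event on a branch."""

    type: str                               # hopf | saddle_node | transcritical | snpo | homoclinic | fold_hopf
    param: str
    value: float
    state: np.ndarray                       # reduced equilibrium at the event (if applicable)
    omega: float = 0.0                      # |Im| of the crossing pair (Hopf only)
    criticality: str = "unclassified"       # sub | super | unclassified (Hopf only)
    indicator: float = 0.0                  # residual indicator value at the located point


@dataclass
class HopfLocus:
    """A polyline of Hopf points in a two-parameter plane, with region labels."""

    scan_param: str
    locate_param: str
    scan_values: np.ndarray
    locate_values: np.ndarray
    states: np.ndarray                      # (npts, 9)
    region_low: str = ""                    # label on the low-locate_param side
    region_high: str = ""
    termination: str = "range_end"


@dataclass
class PeriodicBranch:
    """Amplitude/period of the oscillatory attractor along a parameter sweep."""

    param: str
    values: np.ndarray
    amplitude_up: np.ndarray                # 0 where the up-sweep found no oscillation
    period_up: np.ndarray
    amplitude_down: np.ndarray
    period_down: np.ndarray
    snpo_flags: np.ndarray                  # hysteresis between sweeps (bool per point)
    homoclinic_flag: bool = False
    homoclinic_bracket: tuple[float, float] | None = None
    termination: str = "range_end"


def _with(p: DimensionlessParameters, name: str, value: float) -> DimensionlessParameters:
    return p.replace(**{name: float(value)})


def _dF_dparam(y: np.ndarray, p: DimensionlessParameters, name: str) -> np.ndarray:
    """Central-difference derivative of the reduced field w.r.t. one parameter."""
    v = getattr(p, name)
    h = 1e-7 * max(1.0, abs(v))
    fp = rhs_reduced(y, _with(p, name, v + h))
    fm = rhs_reduced(y, _with(p, name, v - h))
    return (fp - fm) / (2 * h)


def _corrector(y_pred: np.ndarray, a_pred: float, tangent: np.ndarray,
               weights: np.ndarray, p: DimensionlessParameters, name: str,
               max_iter: int = 12, max_scaled_step: float = 1.0
               ) -> tuple[np.ndarray, float] | None:
    """Newton on the bordered system: F(y, a) = 0 plus the pseudo-arclength
    constraint <tangent, (z - z_pred)> = 0 in the scaled coordinates z = weights*(y, a)."""
    y, a = y_pred.copy(), a_pred
    with np.errstate(all="ignore"):
        for _ in range(max_iter):
            if a < 0:
                return None  # all model parameters are non-negative
            pa = _with(p, name, a)
            F = rhs_reduced(y, pa)
            if not np.all(np.isfinite(F)):
                return None
            con = float(np.dot(tangent[:9], weights[:9] * (y - y_pred))
                        + tangent[9] * weights[9] * (a - a_pred))
            if max(np.max(np.abs(F)), abs(con)) < CORRECTOR_TOL:
                return y, a
            M = np.empty((10, 10))
            M[:9, :9] = jacobian_reduced(y, pa)
            M[:9, 9] = _dF_dparam(y, pa, name)
            M[9, :9] = tangent[:9] * weights[:9]
            M[9, 9] = tangent[9] * weights[9]
            rhs_vec = -np.concatenate([F, [con]])
            try:
                d = np.linalg.solve(M, rhs_vec)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(d)):
                return None
            # a correction much larger than the predictor step means the
            # predictor left the basin: fail, so the caller shrinks the step
            if np.max(np.abs(d * weights)) > max_scaled_step:
                return None
            y = y + d[:9]
            a = a + d[9]
    return None


def continue_branch(p: DimensionlessParameters, free_param: str,
                    prange: tuple[float, float], start_equilibrium: np.ndarray,
                    step0: float = 1e-3, min_step: float = 1e-7,
                    max_step: float = 5e-2, max_points: int = 4000) -> Branch:
    """Trace an equilibrium branch in ``free_param`` over ``prange``.

    ``start_equilibrium`` must solve the reduced system at ``prange[0]`` (it
    is Newton-polished first).  Arclength is measured in scaled coordinates:
    state components are scaled relative to their magnitude at the current
    point, the parameter relative to the range width, so the step bounds are
    range-independent.  The step shrinks (x0.5) on corrector failure and grows
    (x1.3, capped) after fast convergence.  A :class:`StabilityReport` is
    attached at every accepted point.
    """
    a_start, a_end = float(prange[0]), float(prange[1])
    lo, hi = min(a_start, a_end), max(a_start, a_end)
    span = hi - lo
    if span <= 0:
        raise ValueError("parameter range must have positive width")

    y0 = newton_equilibrium(np.asarray(start_equilibrium, dtype=float),
                            _with(p, free_param, a_start), tol=CORRECTOR_TOL)
    if y0 is None:
        raise ValueError("start_equilibrium does not converge to an equilibrium at the range start")

    def scale_weights(y: np.ndarray) -> np.ndarray:
        w = np.empty(10)
        w[:9] = 1.0 / np.maximum(1.0, np.abs(y))
        w[9] = 1.0 / span
        return w

    values = [a_start]
    states = [y0]
    reports = [stability_report(y0, _with(p, free_param, a_start))]
    failures = 0
    termination = "max_points"

    # initial tangent from the equilibrium condition: J dy = -F_a
    pa = _with(p, free_param, a_start)
    w = scale_weights(y0)
    try:
        dyda = np.linalg.solve(jacobian_reduced(y0, pa), -_dF_dparam(y0, pa, free_param))
        t = np.concatenate([dyda * w[:9] / w[9], [1.0]])
    except np.linalg.LinAlgError:
        t = np.concatenate([np.zeros(9), [1.0]])
    t = t / np.linalg.norm(t)
    if t[9] * np.sign(a_end - a_start) < 0:
        t = -t

    ds = step0
    while len(values) < max_points:
        y_prev, a_prev = states[-1], values[-1]
        w = scale_weights(y_prev)
        # predictor
        y_pred = y_prev + ds * t[:9] / w[:9]
        a_pred = a_prev + ds * t[9] / w[9]
        res = _corrector(y_pred, a_pred, t, w, p, free_param)
        if res is None:
            failures += 1
            ds *= 0.5
            if ds < min_step:
                termination = "min_step"
                break
            continue
        y_new, a_new = res
        # reject steps that double back onto the branch
        w_chk = scale_weights(y_new)
        sec_chk = np.concatenate([(y_new - y_prev) * w_chk[:9], [(a_new - a_prev) * w_chk[9]]])
        nrm_chk = np.linalg.norm(sec_chk)
        if nrm_chk == 0 or np.dot(sec_chk / nrm_chk, t) < 0.1:
            failures += 1
            ds *= 0.5
            if ds < min_step:
                termination = "min_step"
                break
            continue
        if a_new < lo - 1e-12 or a_new > hi + 1e-12:
            # land exactly on the range boundary with a fixed-parameter solve
            a_bound = lo if a_new < lo else hi
            y_b = newton_equilibrium(y_new, _with(p, free_param, a_bound), tol=CORRECTOR_TOL)
            if y_b is not None:
                values.append(a_bound)
                states.append(y_b)
                reports.append(stability_report(y_b, _with(p, free_param, a_bound)))
            termination = "range_end"
            break
        values.append(a_new)
        states.append(y_new)
        reports.append(stability_report(y_new, _with(p, free_param, a_new)))
        # secant tangent for the next step
        w = scale_weights(y_new)
        sec = np.concatenate([(y_new - y_prev) * w[:9], [(a_new - a_prev) * w[9]]])
        nrm = np.linalg.norm(sec)
        if nrm > 0:
            t = sec / nrm
        ds = min(ds * 1.3, max_step)

    br = Branch(param=free_param, values=np.array(values), states=np.array(states),
                reports=reports, termination=termination, n_corrector_failures=failures)
    br.base_params = p
    return br


def _hopf_indicator(report: StabilityReport) -> float:
    """Max real part over the complex-pair eigenvalues (nan if none)."""
    eig = report.eigenvalues
    cplx = eig[np.abs(eig.imag) > COMPLEX_IM_MIN]
    return float(np.max(cplx.real)) if len(cplx) else np.nan


def _det_indicator(y: np.ndarray, p: DimensionlessParameters) -> float:
    return float(np.linalg.det(jacobian_reduced(y, p)))


def _segment_solve(p: DimensionlessParameters, name: str,
                   p0: tuple[np.ndarray, float], p1: tuple[np.ndarray, float],
                   tau: float) -> tuple[np.ndarray, float] | None:
    """Equilibrium on the secant hyperplane a fraction ``tau`` along a branch segment."""
    y0, a0 = p0
    y1, a1 = p1
    y_pred = y0 + tau * (y1 - y0)
    a_pred = a0 + tau * (a1 - a0)
    w = np.empty(10)
    w[:9] = 1.0 / np.maximum(1.0, np.abs(y_pred))
    w[9] = 1.0 / max(abs(a1 - a0), 1e-12)
    sec = np.concatenate([(y1 - y0) * w[:9], [(a1 - a0) * w[9]]])
    seg_len = np.linalg.norm(sec)
    sec = sec / seg_len
    res = _corrector(y_pred, a_pred, sec, w, p, name, max_iter=25, max_scaled_step=10.0)
    if res is None:
        return None
    y_s, a_s = res
    # reject convergence onto a different solution sheet far from the segment
    dist = np.linalg.norm(np.concatenate([(y_s - y_pred) * w[:9], [(a_s - a_pred) * w[9]]]))
    if dist > 2.0 * seg_len + 1e-9:
        return None
    return res


def _locate_fold(p: DimensionlessParameters, name: str, y0: np.ndarray, a0: float,
                 max_iter: int = 40, tol: float = 1e-11
                 ) -> tuple[np.ndarray, float] | None:
    """Newton on the bordered fold system F = 0, J v = 0, <v, v0> = 1.

    Locates a saddle-node (zero real eigenvalue with tangency in the
    parameter) to machine accuracy, seeded from a nearby branch point and the
    approximate null vector.
    """
    J0 = jacobian_reduced(y0, _with(p, name, a0))
    evals, vecs = np.linalg.eig(J0)
    k = np.argmin(np.abs(evals))
    v0 = np.real(vecs[:, k])
    v0 = v0 / np.linalg.norm(v0)

    z = np.concatenate([y0, [a0], v0])

    def G(z):
        y, a, v = z[:9], z[9], z[10:]
        pa = _with(p, name, max(a, 0.0))
        J = jacobian_reduced(y, pa)
        return np.concatenate([rhs_reduced(y, pa), J @ v, [np.dot(v, v0) - 1.0]])

    g = G(z)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            y, a, v = z[:9], z[9], z[10:]
            return y, float(a)
        M = np.empty((19, 19))
        for j in range(19):
            h = 1e-7 * max(1.0, abs(z[j]))
            zp, zm = z.copy(), z.copy()
            zp[j] += h
            zm[j] -= h
            M[:, j] = (G(zp) - G(zm)) / (2 * h)
        try:
            dz = np.linalg.solve(M, -g)
        except np.linalg.LinAlgError:
            return None
        z = z + dz
        if z[9] < 0 or not np.all(np.isfinite(z)):
            return None
        g = G(z)
    return None


def detect_and_locate_bifurcations(branch: Branch) -> list[BifurcationPoint]:
    """Scan a branch for Hopf and zero-eigenvalue events and locate each by bisection.

    A Hopf is flagged where the leading complex-pair real part changes sign; a
    saddle-node or transcritical where the Jacobian determinant changes sign.
    Each event is refined by bisection along the branch segment (corrector on
    the secant hyperplane, so folds are handled) until the indicator magnitude
    drops below 1e-8.  A zero-eigenvalue event on the healthy branch (c = 0)
    is labelled transcritical, elsewhere saddle-node.
    """
    if len(branch) < 2:
        raise ValueError("branch must contain at least 2 points")
    p = branch.base_params
    name = branch.param
    events: list[BifurcationPoint] = []

    hopf_ind = np.array([_hopf_indicator(r) for r in branch.reports])
    det_ind = np.array([_det_indicator(branch.states[i], branch._params_at(i))
                        for i in range(len(branch))])

    def bisect(i: int, indicator) -> tuple[np.ndarray, float, float] | None:
        seg0 = (branch.states[i], float(branch.values[i]))
        seg1 = (branch.states[i + 1], float(branch.values[i + 1]))
        f_lo = indicator(*seg0)
        da_seg = abs(seg1[1] - seg0[1])
        lo_t, hi_t = 0.0, 1.0
        sol = None
        for _ in range(100):
            mid = 0.5 * (lo_t + hi_t)
            res = _segment_solve(p, name, seg0, seg1, mid)
            if res is None:
                # corrector hiccup at this hyperplane: nudge the trial point
                for frac in (0.45, 0.55, 0.35, 0.65):
                    trial = lo_t + frac * (hi_t - lo_t)
                    res = _segment_solve(p, name, seg0, seg1, trial)
                    if res is not None:
                        mid = trial
                        break
                else:
                    return sol
            y_m, a_m = res
            f_m = indicator(y_m, a_m)
            sol = (y_m, a_m, f_m)
            if abs(f_m) < INDICATOR_TOL and (hi_t - lo_t) * max(da_seg, 1e-12) < 1e-11:
                return sol
            if np.sign(f_m) == np.sign(f_lo):
                lo_t = mid
            else:
                hi_t = mid
        return sol

    for i in range(len(branch) - 1):
        if (np.isfinite(hopf_ind[i]) and np.isfinite(hopf_ind[i + 1])
                and np.sign(hopf_ind[i]) != np.sign(hopf_ind[i + 1])):
            def h_ind(y, a):
                return _hopf_indicator(stability_report(y, _with(p, name, a)))
            sol = bisect(i, h_ind)
            if sol is not None:
                y_h, a_h, f_h = sol
                rep = stability_report(y_h, _with(p, name, a_h))
                eig = rep.eigenvalues
                cplx = eig[np.abs(eig.imag) > COMPLEX_IM_MIN]
                lead = cplx[np.argmax(cplx.real)]
                omega = abs(float(lead.imag))
                # a complex pair merging onto the real axis flips the indicator
                # discontinuously without any eigenvalue crossing the imaginary
                # axis: that is not a bifurcation
                if omega > 1e-6 and abs(f_h) < INDICATOR_TOL:
                    events.append(BifurcationPoint(
                        type="hopf", param=name, value=a_h, state=y_h,
                        omega=omega, indicator=f_h))
        if np.sign(det_ind[i]) != np.sign(det_ind[i + 1]):
            def d_ind(y, a):
                return _det_indicator(y, _with(p, name, a))
            sol = bisect(i, d_ind)
            if sol is not None and abs(sol[2]) >= INDICATOR_TOL:
                # hyperplane bisection stalls when the zero eigenvalue sits at a
                # fold (both sheets intersect the hyperplane): switch to the
                # bordered fold system
                fold = _locate_fold(p, name, *sol[:2])
                if fold is not None:
                    y_f, a_f = fold
                    sol = (y_f, a_f, d_ind(y_f, a_f))
            if sol is not None:
                y_z, a_z, f_z = sol
                kind = "transcritical" if abs(y_z[4]) < 1e-6 else "saddle_node"
                events.append(BifurcationPoint(
                    type=kind, param=name, value=a_z, state=y_z, indicator=f_z))
    events.sort(key=lambda e: e.value)
    return events


def chronic_equilibrium(p: DimensionlessParameters, c0: float = 1.0,
                        t_settle: float = 4000.0, y_guess: np.ndarray | None = None
                        ) -> np.ndarray | None:
    """A chronic (c > 0) equilibrium, found by settling a simulation and Newton-polishing.

    Reliable wherever the chronic state is attracting; ``y_guess`` (reduced)
    skips the simulation.
    """
    if y_guess is None:
        traj = integrate(p, c0, t_end=t_settle, rtol=1e-10, atol=1e-12)
        x_end = traj.states[-1]
        y_guess = x_end[[0, 1, 2, 3, 4, 5, 6, 7, 9]]
    y = newton_equilibrium(np.asarray(y_guess, dtype=float), p, tol=CORRECTOR_TOL)
    if y is None or y[4] <= 1e-7:
        return None
    return y


def locate_hopf_bisection(p: DimensionlessParameters, free_param: str,
                          bracket: tuple[float, float], y_seed: np.ndarray,
                          xtol: float = 1e-12) -> tuple[float, np.ndarray] | None:
    """Locate a Hopf point by direct bisection in the parameter.

    Independent of arclength continuation: at each trial value the equilibrium
    is re-solved by Newton from the nearest known state and the sign of the
    leading complex-pair real part is evaluated.  Requires the branch to be
    parameterizable by ``free_param`` across the bracket (no fold inside).
    """
    lo, hi = float(bracket[0]), float(bracket[1])

    def eval_at(a: float, seed: np.ndarray):
        y = newton_equilibrium(seed, _with(p, free_param, a), tol=CORRECTOR_TOL)
        if y is None:
            return None
        return y, _hopf_indicator(stability_report(y, _with(p, free_param, a)))

    res_lo = eval_at(lo, y_seed)
    res_hi = eval_at(hi, res_lo[0] if res_lo else y_seed)
    if res_lo is None or res_hi is None:
        return None
    y_lo, f_lo = res_lo
    y_hi, f_hi = res_hi
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or np.sign(f_lo) == np.sign(f_hi):
        return None
    while hi - lo > xtol * max(1.0, abs(hi)):
        mid = 0.5 * (lo + hi)
        res = eval_at(mid, y_lo if abs(mid - lo) < abs(mid - hi) else y_hi)
        if res is None:
            return None
        y_m, f_m = res
        if abs(f_m) < INDICATOR_TOL:
            return mid, y_m
        if np.sign(f_m) == np.sign(f_lo):
            lo, y_lo, f_lo = mid, y_m, f_m
        else:
            hi, y_hi, f_hi = mid, y_m, f_m
    return 0.5 * (lo + hi), y_lo


def classify_hopf(p: DimensionlessParameters, free_param: str, hopf_value: float,
                  hopf_state: np.ndarray, delta_rel: float = 0.01,
                  t_probe: float = 6000.0, max_refinements: int = 3) -> str:
    """Empirical sub/supercritical classification by two-sided simulation.

    The equilibrium is continued a fraction ``delta_rel`` of ``hopf_value`` to
    each side; on the side where it is unstable, a trajectory is launched from
    a small perturbation along the leading eigenvector.  A bounded,
    small-amplitude sustained oscillation around the equilibrium indicates a
    supercritical Hopf; escape towards a remote attractor (the resolved state
    or a large orbit) indicates a subcritical one.  The offset is enlarged and
    the horizon extended if the probe is inconclusive; if it remains so the
    verdict is ``"unclassified"`` (never guessed).
    """
    delta = delta_rel * abs(hopf_value)
    for _ in range(max_refinements + 1):
        verdict = _hopf_probe(p, free_param, hopf_value, hopf_state, delta, t_probe)
        if verdict in ("sub", "super"):
            return verdict
        delta *= 2.0
        t_probe *= 1.5
    return "unclassified"


def _hopf_probe(p: DimensionlessParameters, name: str, a_h: float,
                y_h: np.ndarray, delta: float, t_probe: float) -> str:
    for side in (+1.0, -1.0):
        a = a_h + side * delta
        pa = _with(p, name, a)
        y = newton_equilibrium(y_h, pa, tol=CORRECTOR_TOL)
        if y is None:
            continue
        rep = stability_report(y, pa)
        if rep.max_real_part <= 0:
            continue  # probe only the unstable-equilibrium side
        eig = rep.eigenvalues
        cplx = eig[np.abs(eig.imag) > COMPLEX_IM_MIN]
        if len(cplx) == 0:
            continue
        lead = cplx[np.argmax(cplx.real)]
        J = jacobian_reduced(y, pa)
        _, vecs = np.linalg.eig(J)
        evals, _ = np.linalg.eig(J)
        v = vecs[:, np.argmin(np.abs(evals - lead))].real
        v = v / np.max(np.abs(v))
        c_star = y[4]
        scale = max(abs(c_star), 0.1)
        x0_red = y + 0.02 * scale * v
        x0_red = np.clip(x0_red, 0.0, None)
        x0 = expand_state(x0_red, tol=np.inf).as_array()
        traj = integrate(pa, 0.0, t_end=t_probe, x0=x0, rtol=1e-9, atol=1e-11,
                         n_samples=4001)
        dev = np.abs(traj.column("c") - c_star)
        escape = 0.6 * scale
        if np.max(dev) > escape:
            return "sub"
        tail = traj.states[int(0.75 * len(traj.times)):]
        tail_c = tail[:, 4]
        tail_amp = float(np.ptp(tail_c))
        grown = tail_amp > 0.25 * 0.02 * scale
        settled = abs(np.max(np.abs(tail_c - c_star)) - np.max(dev)) < 0.5 * np.max(dev) + 1e-12
        if grown and np.max(dev) < escape and settled:
            return "super"
        return "inconclusive"
    return "inconclusive"


def trace_hopf_two_param(p: DimensionlessParameters, scan_param: str,
                         locate_param: str, scan_range: tuple[float, float],
                         n_points: int, seed_hopf: tuple[float, np.ndarray],
                         bracket_rel: float = 0.25) -> HopfLocus:
    """Trace the Hopf locus in the (scan_param, locate_param) plane.

    At each scan value the Hopf is re-located in ``locate_param`` by bracketed
    bisection seeded from the previous point (bracket half-width a fraction
    ``bracket_rel`` of the previous locate value, widened up to 4x on bracket
    failure).  Terminates with reason ``"fold_hopf_or_boundary"`` when the
    locus leaves the bracketable window (e.g. the Hopf is destroyed at a
    fold–Hopf point).
    """
    scan_values = np.linspace(scan_range[0], scan_range[1], n_points)
    loc_prev, y_prev = float(seed_hopf[0]), np.asarray(seed_hopf[1], dtype=float)
    out_scan, out_loc, out_states = [], [], []
    termination = "range_end"
    for sv in scan_values:
        ps = _with(p, scan_param, sv)
        found = None
        width = bracket_rel * max(abs(loc_prev), 1e-6)
        for _ in range(4):
            lo = max(loc_prev - width, 1e-12)
            hi = loc_prev + width
            found = locate_hopf_bisection(ps, locate_param, (lo, hi), y_prev)
            if found is not None:
                break
            width *= 2.0
        if found is None:
            termination = "fold_hopf_or_boundary"
            break
        loc_prev, y_prev = found
        out_scan.append(sv)
        out_loc.append(loc_prev)
        out_states.append(y_prev)

    locus = HopfLocus(scan_param=scan_param, locate_param=locate_param,
                      scan_values=np.array(out_scan), locate_values=np.array(out_loc),
                      states=np.array(out_states) if out_states else np.empty((0, 9)),
                      termination=termination)
    if out_scan:
        mid = len(out_scan) // 2
        locus.region_low = _region_label(
            _with(p, scan_param, out_scan[mid]), locate_param,
            out_loc[mid] * 0.9, out_states[mid])
        locus.region_high = _region_label(
            _with(p, scan_param, out_scan[mid]), locate_param,
            out_loc[mid] * 1.1, out_states[mid])
    return locus


def _region_label(p: DimensionlessParameters, name: str, value: float,
                  y_seed: np.ndarray) -> str:
    """Outcome-region label at a parameter point: B, M:Res, M:Chr or Osc.

    Healthy stability comes from the closed-form conditions; chronic
    stability from the Newton-continued chronic equilibrium (a missing or
    unstable chronic equilibrium with an unstable healthy state indicates the
    oscillatory regime).
    """
    pa = _with(p, name, value)
    healthy_ok, _ = healthy_is_stable(pa)
    y = newton_equilibrium(y_seed, pa, tol=CORRECTOR_TOL)
    chronic_stable = False
    if y is not None and y[4] > 1e-7:
        chronic_stable = stability_report(y, pa).is_stable
    if healthy_ok and chronic_stable:
        return "B"
    if healthy_ok:
        return "M:Res"
    if chronic_stable:
        return "M:Chr"
    return "Osc"


def _measure_attractor(p: DimensionlessParameters, x0: np.ndarray,
                       t_end: float) -> tuple[str, float, float, np.ndarray]:
    """(outcome label, amplitude, period, final state) of the attractor reached from x0."""
    traj = integrate(p, 0.0, t_end=t_end, x0=x0, n_samples=max(4001, int(t_end)))
    outcome = classify_outcome(traj)
    if outcome.label != "oscillatory":
        return outcome.label, 0.0, 0.0, traj.states[-1]
    try:
        m = metrics_from_trajectory(traj)
    except NotOscillatoryError:
        return outcome.label, float(outcome.tail_c_range), 0.0, traj.states[-1]
    return "oscillatory", m.amplitude, m.wavelength, traj.states[-1]


def periodic_branch(p: DimensionlessParameters, free_param: str,
                    prange: tuple[float, float], n_points: int,
                    x_start: np.ndarray | None = None,
                    t_end: float = 3000.0) -> PeriodicBranch:
    """Characterize the periodic attractor along a parameter sweep.

    The sweep runs in both directions with attractor hand-off (the final state
    at one value seeds the next), so coexisting attractors are visible as
    hysteresis between the up- and down-sweeps: such points are flagged as an
    SNPO window.  A period exceeding 10x the branch median adjacent to the
    loss of oscillations raises the homoclinic-approach flag, with the
    bracketing parameter interval recorded.  Non-oscillatory points are
    recorded with zero amplitude.
    """
    values = np.linspace(prange[0], prange[1], n_points)
    from .model import initial_state
    if x_start is None:
        x_start = initial_state(0.3).as_array()

    def sweep(vals):
        amps = np.zeros(len(vals))
        pers = np.zeros(len(vals))
        x = x_start.copy()
        for i, v in enumerate(vals):
            label, amp, per, x_new = _measure_attractor(_with(p, free_param, v), x, t_end)
            if amp == 0.0 and label in ("undetermined", "chronic_steady"):
                # long-period orbits (homoclinic approach) need a longer window
                label, amp, per, x_new = _measure_attractor(
                    _with(p, free_param, v), x_new, 12 * t_end)
            amps[i], pers[i] = amp, per
            x = x_new if np.all(np.isfinite(x_new)) else x_start.copy()
        return amps, pers

    amp_up, per_up = sweep(values)
    amp_dn_rev, per_dn_rev = sweep(values[::-1])
    amp_dn, per_dn = amp_dn_rev[::-1], per_dn_rev[::-1]

    scale = max(np.max(amp_up), np.max(amp_dn), 1e-12)
    snpo = np.abs(amp_up - amp_dn) > 0.1 * scale

    osc = (amp_up > 0) | (amp_dn > 0)
    periods = np.where(per_up > 0, per_up, per_dn)
    homoclinic = False
    bracket = None
    pos = periods[periods > 0]
    if len(pos) >= 3:
        med = float(np.median(pos))
        for i in range(len(values)):
            if periods[i] > 10 * med:
                # period blow-up adjacent to loss of oscillation
                nbrs = [j for j in (i - 1, i + 1) if 0 <= j < len(values)]
                if any(not osc[j] for j in nbrs) or i in (0, len(values) - 1):
                    homoclinic = True
                    j_lo = max(i - 1, 0)
                    j_hi = min(i + 1, len(values) - 1)
                    bracket = (float(min(values[j_lo], values[j_hi])),
                               float(max(values[j_lo], values[j_hi])))
                    break
    return PeriodicBranch(param=free_param, values=values,
                          amplitude_up=amp_up, period_up=per_up,
                          amplitude_down=amp_dn, period_down=per_dn,
                          snpo_flags=snpo, homoclinic_flag=homoclinic,
                          homoclinic_bracket=bracket)
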