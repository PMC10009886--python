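"""Time integration of the model and classification of long-term outcomes.

A damage stimulus c(0) = c0 either resolves (all pro-inflammatory components
settle at zero and the tissue returns to h = 1), settles into a chronic
steady state with persistently positive mediator levels, or enters sustained
oscillations.  Classification operates on the tail of the trajectory;
undetermined runs (slow transients) are re-integrated with doubled horizon.

The default tolerances are tight (rtol 1e-9, atol 1e-11) because outcome
classification near bifurcation boundaries is tolerance-sensitive; the slow
macrophage decay (gamma_m = 0.01) sets a ~100-unit relaxation scale, hence a
default horizon of 2000 dimensionless time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import (STATE_NAMES, InitialConditions, State, jacobian_full, rhs)
from .params import DimensionlessParameters

__all__ = [
    "Trajectory",
    "OutcomeLabel",
    "OscillationMetrics",
    "IntegrationError",
    "NotOscillatoryError",
    "integrate",
    "classify_outcome",
    "simulate_outcome",
    "oscillation_metrics",
]

#: A trajectory tail is "resolved" when every pro-inflammatory component
#: stays below this (far below the O(0.1-1) dynamical scales, far above
#: integrator noise).
RESOLUTION_THRESHOLD = 1e-5

#: Minimum sustained peak-to-peak range of c for an "oscillatory" verdict.
OSCILLATION_THRESHOLD = 1e-4

DEFAULT_T_END = 2000.0
MAX_T_END = 16000.0
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-11

#: Indices of the pro-inflammatory components checked for resolution.
_PRO_INFLAMMATORY = [STATE_NAMES.index(k) for k in ("n", "a", "m_i", "c", "h_a")]
_C = STATE_NAMES.index("c")


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the time at which integration stopped."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class NotOscillatoryError(RuntimeError):
    """Oscillation metrics were requested for a non-oscillatory trajectory."""


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: times, states (rows) and the run's configuration."""

    times: np.ndarray                  # (nt,)
    states: np.ndarray                 # (nt, 11) in STATE_NAMES order
    params: DimensionlessParameters
    init: InitialConditions
    conservation_drift: float = 0.0    # max deviation of the two conserved totals

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.times)
        return df


@dataclass(frozen=True)
class OutcomeLabel:
    """Long-term outcome of a trajectory, with tail diagnostics."""

    label: str                         # resolved | chronic_steady | oscillatory | undetermined
    tail_c_mean: float
    tail_c_range: float                # peak-to-peak range of c on the tail window
    n_peaks: int = 0


@dataclass(frozen=True)
class OscillationMetrics:
    """Amplitude (peak-to-trough in c) and wavelength (period) of a limit cycle."""

    amplitude: float
    wavelength: float
    wavelength_se: float = 0.0         # standard error of the period estimate
    n_cycles: int = 0


def integrate(p: DimensionlessParameters, init: InitialConditions | float,
              t_end: float = DEFAULT_T_END, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, n_samples: int = 2001,
              x0: np.ndarray | None = None, method: str = "LSODA") -> Trajectory:
    """Integrate the full 11-variable system with a stiff-capable adaptive solver.

    ``init`` is the stimulus (an :class:`InitialConditions` or a bare c0);
    ``x0`` optionally overrides the start state entirely (e.g. for attractor
    hand-off between parameter values).  The analytic Jacobian is supplied to
    the solver.  Samples are returned on a uniform grid of ``n_samples``
    points (dense output).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not isinstance(init, InitialConditions):
        init = InitialConditions(float(init))
    start = init.state.as_array() if x0 is None else np.asarray(x0, dtype=float)

    def f(t, x):
        return rhs(x, p)

    def jac(t, x):
        return jacobian_full(x, p)

    t_eval = np.linspace(0.0, t_end, max(int(n_samples), 2001))
    sol = solve_ivp(f, (0.0, t_end), start, method=method, jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", t_fail=float(sol.t[-1]))
    states = sol.y.T
    tissue = states[:, 6] + states[:, 7] + states[:, 8]
    stellate = states[:, 9] + states[:, 10]
    drift = max(float(np.max(np.abs(tissue - tissue[0]))),
                float(np.max(np.abs(stellate - stellate[0]))))
    return Trajectory(times=sol.t, states=states, params=p, init=init,
                      conservation_drift=drift)


def _tail(traj: Trajectory, fraction: float = 0.25) -> np.ndarray:
    n = len(traj.times)
    return traj.states[int(n * (1 - fraction)):]


def _count_peaks(c: np.ndarray) -> int:
    rng = float(np.ptp(c))
    if rng <= 0:
        return 0
    peaks, _ = find_peaks(c, prominence=0.2 * rng)
    return int(len(peaks))


def classify_outcome(traj: Trajectory, tail_fraction: float = 0.25) -> OutcomeLabel:
    """Classify the long-term outcome from the final ``tail_fraction`` of samples.

    resolved        — every pro-inflammatory component (n, a, m_i, c, h_a)
                      stays below 1e-5 on the tail;
    oscillatory     — the tail peak-to-peak range of c exceeds 1e-4 with at
                      least 3 complete peaks;
    chronic_steady  — the tail is near-constant with c above 1e-5;
    undetermined    — anything else (the caller should extend the horizon).
    """
    tail = _tail(traj, tail_fraction)
    c = tail[:, _C]
    c_mean = float(np.mean(c))
    c_range = float(np.ptp(c))
    if float(np.max(np.abs(tail[:, _PRO_INFLAMMATORY]))) < RESOLUTION_THRESHOLD:
        return OutcomeLabel("resolved", c_mean, c_range)
    n_peaks = _count_peaks(c)
    if c_range > OSCILLATION_THRESHOLD and n_peaks >= 3:
        return OutcomeLabel("oscillatory", c_mean, c_range, n_peaks)
    if c_range <= OSCILLATION_THRESHOLD and c_mean > RESOLUTION_THRESHOLD:
        return OutcomeLabel("chronic_steady", c_mean, c_range, n_peaks)
    return OutcomeLabel("undetermined", c_mean, c_range, n_peaks)


def simulate_outcome(p: DimensionlessParameters, c0: float,
                     t_end: float = DEFAULT_T_END,
                     max_t_end: float = MAX_T_END,
                     **kwargs) -> tuple[Trajectory, OutcomeLabel]:
    """Integrate and classify, doubling the horizon (up to ``max_t_end``)
    while the outcome is undetermined."""
    while True:
        traj = integrate(p, c0, t_end=t_end, **kwargs)
        outcome = classify_outcome(traj)
        if outcome.label != "undetermined" or t_end * 2 > max_t_end:
            return traj, outcome
        t_end *= 2


def _refined_peak_times(t: np.ndarray, c: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic refinement of discrete extrema: fit a parabola through the
    three samples around each peak index and return (times, values) at the vertex."""
    times, values = [], []
    for i in idx:
        if i == 0 or i == len(t) - 1:
            times.append(t[i])
            values.append(c[i])
            continue
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = c[i - 1], c[i], c[i + 1]
        denom = (y0 - 2 * y1 + y2)
        if denom == 0:
            times.append(t1)
            values.append(y1)
            continue
        dt = t1 - t0  # uniform grid
        shift = 0.5 * (y0 - y2) / denom
        times.append(t1 + shift * dt)
        values.append(y1 - 0.25 * (y0 - y2) * shift)
    return np.array(times), np.array(values)


def metrics_from_trajectory(traj: Trajectory, transient_fraction: float = 0.5
                            ) -> OscillationMetrics:
    """Oscillation amplitude and period measured on an already-solved trajectory.

    The first ``transient_fraction`` of the run is discarded; peaks and
    troughs of c are located on the dense output with quadratic refinement of
    the extremum times.  Raises :class:`NotOscillatoryError` when the
    trajectory is not oscillatory or carries fewer than two cycles.
    """
    outcome = classify_outcome(traj)
    if outcome.label != "oscillatory":
        raise NotOscillatoryError(
            f"trajectory outcome is {outcome.label!r}; oscillation metrics undefined")
    start = int(len(traj.times) * transient_fraction)
    t = traj.times[start:]
    c = traj.column("c")[start:]
    rng = float(np.ptp(c))
    peaks, _ = find_peaks(c, prominence=0.2 * rng)
    troughs, _ = find_peaks(-c, prominence=0.2 * rng)
    if len(peaks) < 2 or len(troughs) < 1:
        raise NotOscillatoryError("too few cycles on the attractor to measure")
    pt, pv = _refined_peak_times(t, c, peaks)
    _, tv = _refined_peak_times(t, -c, troughs)
    tv = -tv
    n_cyc = min(len(pv) - 1, len(tv))
    amplitude = float(np.mean(pv[-n_cyc:]) - np.mean(tv[-n_cyc:]))
    periods = np.diff(pt)
    wavelength = float(np.mean(periods))
    se = float(np.std(periods, ddof=1) / np.sqrt(len(periods))) if len(periods) > 1 else 0.0
    return OscillationMetrics(amplitude=amplitude, wavelength=wavelength,
                              wavelength_se=se, n_cycles=int(n_cyc))


def oscillation_metrics(p: DimensionlessParameters, init: InitialConditions | float,
                        t_end: float = DEFAULT_T_END, x0: np.ndarray | None = None,
                        min_cycles: int = 5, _max_doublings: int = 3,
                        **kwargs) -> OscillationMetrics:
    """Amplitude and period of the limit cycle reached from ``init``.

    Integrates, discards the first half as transient and measures c's peaks
    and troughs (see :func:`metrics_from_trajectory`).  The horizon is doubled
    (up to 2**3 times) until at least ``min_cycles`` full cycles fall in the
    measurement window.  Raises :class:`NotOscillatoryError` if the trajectory
    does not oscillate.
    """
    last_exc: NotOscillatoryError | None = None
    undetermined = False
    for attempt in range(_max_doublings + 1):
        traj = integrate(p, init, t_end=t_end, x0=x0,
                         n_samples=max(4001, int(t_end)), **kwargs)
        try:
            m = metrics_from_trajectory(traj)
        except NotOscillatoryError as exc:
            last_exc = exc
            undetermined = classify_outcome(traj).label == "undetermined"
            if undetermined or "too few" in str(exc):
                t_end *= 2
                continue
            raise
        if m.n_cycles >= min_cycles or attempt == _max_doublings:
            return m
        t_end *= 2
    raise last_exc if last_exc is not None else NotOscillatoryError("no oscillation found")
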