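import numpy as np
import pytest

from conftest import random_parameters
from hepdyn.model import rhs, rhs_reduced
from hepdyn.params import InvalidParameterError
from hepdyn.stability import (critical_km, critical_nu2, find_steady_states,
                              healthy_cubic, healthy_is_stable,
                              healthy_steady_state, jacobian, reduce_y,
                              stability_report)


class TestHealthySteadyState:
    def test_closed_form(self, p0):
        eq = healthy_steady_state(p0)
        s = eq.state
        assert s.g == pytest.approx(0.1)
        assert s.h == 1.0 and s.s == 1.0
        assert all(getattr(s, k) == 0.0 for k in ("n", "a", "m_i", "m_r", "c", "h_a", "e", "s_a"))
        assert eq.kind == "healthy"

    def test_zero_hepatocyte_feedback(self, p0):
        assert healthy_steady_state(p0.replace(k_h=0.0)).state.g == 0.0

    def test_fixed_point_for_random_parameters(self, rng):
        for _ in range(100):
            p = random_parameters(rng)
            eq = healthy_steady_state(p)
            assert np.max(np.abs(rhs(eq.state, p))) < 1e-14


class TestCharacteristicCubic:
    def test_baseline_coefficients(self, p0):
        cub = healthy_cubic(p0)
        assert cub.a2 == pytest.approx(1.11)
        assert cub.a1 == pytest.approx(0.1009)
        assert cub.a0 == pytest.approx(0.00089)

    def test_degenerate_limit(self, p0):
        p = p0.replace(gamma_h=0.0, gamma_m=0.0, k_m=0.0, nu_2=0.0)
        cub = healthy_cubic(p)
        assert (cub.a2, cub.a1, cub.a0) == (1.0, 0.0, 0.0)

    def test_roots_are_healthy_state_eigenvalues(self, p0):
        # the cubic factor must reproduce three of the nine Jacobian eigenvalues
        eq = healthy_steady_state(p0)
        eig = np.sort_complex(eq.stability.eigenvalues)
        roots = np.sort_complex(healthy_cubic(p0).roots())
        matched = [np.min(np.abs(eig - r)) for r in roots]
        assert max(matched) < 1e-8

    def test_six_noncubic_eigenvalues_are_real_negative(self, rng):
        for _ in range(50):
            p = random_parameters(rng)
            eig = healthy_steady_state(p).stability.eigenvalues
            roots = healthy_cubic(p).roots()
            remaining = list(eig)
            for r in roots:
                k = int(np.argmin(np.abs(np.array(remaining) - r)))
                remaining.pop(k)
            assert len(remaining) == 6
            assert all(abs(lam.imag) < 1e-9 and lam.real < 0 for lam in remaining)


class TestRouthHurwitz:
    def test_baseline_is_stable(self, p0):
        ok, margins = healthy_is_stable(p0)
        assert ok
        assert margins["a0_positive"] == pytest.approx(
            p0.gamma_m * (p0.gamma_h - p0.nu_2) - p0.gamma_h * p0.k_m)

    @pytest.mark.parametrize("override", [{"nu_2": 0.12}, {"k_m": 0.01}])
    def test_destabilizing_overrides(self, p0, override):
        assert not healthy_is_stable(p0.replace(**override))[0]

    def test_verdict_matches_full_spectrum_on_random_draws(self, rng):
        # 1000 draws: the closed-form conditions agree with the sign of the
        # maximal real part of the 9x9 Jacobian spectrum (boundary excepted)
        disagreements = 0
        for _ in range(1000):
            p = random_parameters(rng)
            verdict, margins = healthy_is_stable(p)
            max_re = healthy_steady_state(p).stability.max_real_part
            if verdict != (max_re < 0):
                disagreements += 1
                assert min(abs(m) for m in margins.values()) < 1e-10
        assert disagreements == 0


class TestCriticalThresholds:
    def test_baseline_values(self, p0):
        assert critical_nu2(p0) == pytest.approx(0.099, rel=1e-14)
        assert critical_km(p0) == pytest.approx(0.009, rel=1e-14)

    def test_a0_vanishes_at_threshold(self, p0, rng):
        for _ in range(20):
            p = random_parameters(rng)
            # thresholds can be negative (already-unstable regimes); only
            # admissible (non-negative) threshold values parameterize the model
            if critical_nu2(p) >= 0:
                assert abs(healthy_cubic(p.replace(nu_2=critical_nu2(p))).a0) < 1e-14
            if critical_km(p) >= 0:
                assert abs(healthy_cubic(p.replace(k_m=critical_km(p))).a0) < 1e-14

    def test_stability_flips_exactly_at_thresholds(self, p0):
        # bisection on the boolean verdict lands on the closed form
        for name, crit in (("nu_2", critical_nu2), ("k_m", critical_km)):
            lo, hi = 0.0, 1.0
            assert healthy_is_stable(p0.replace(**{name: lo}))[0]
            assert not healthy_is_stable(p0.replace(**{name: hi}))[0]
            while hi - lo > 1e-14:
                mid = 0.5 * (lo + hi)
                if healthy_is_stable(p0.replace(**{name: mid}))[0]:
                    lo = mid
                else:
                    hi = mid
            assert 0.5 * (lo + hi) == pytest.approx(crit(p0), abs=1e-12)

    def test_zero_denominators_rejected(self, p0):
        with pytest.raises(InvalidParameterError):
            critical_nu2(p0.replace(gamma_m=0.0))
        with pytest.raises(InvalidParameterError):
            critical_km(p0.replace(gamma_h=0.0))


class TestJacobianAtEquilibria:
    def test_mediator_decay_entry(self, p0):
        # the (c, c) entry at the healthy state is the unit decay rate of c
        y = reduce_y(healthy_steady_state(p0).state)
        J = jacobian(y, p0)
        assert J[4, 4] == pytest.approx(-1.0)


class TestFindSteadyStates:
    def test_low_phagocytosis_is_bistable(self, p0):
        eqs = find_steady_states(p0.replace(phi=0.001), n_starts=64, seed=1)
        stable_chronic = [e for e in eqs if e.kind == "chronic" and e.stability.is_stable]
        assert eqs[0].kind == "healthy"
        assert len(stable_chronic) >= 1
        assert all(e.residual < 1e-10 for e in eqs)
        assert all(e.state.c > 0 for e in stable_chronic)

    def test_baseline_phagocytosis_is_monostable(self, p0):
        eqs = find_steady_states(p0, n_starts=64, seed=1)
        assert not any(e.kind == "chronic" and e.stability.is_stable for e in eqs)

    def test_decoupled_healthy_limit(self, p0):
        eqs = find_steady_states(p0.replace(k_m=0.0, nu_2=0.0), n_starts=16, seed=1)
        healthy = eqs[0]
        assert healthy.kind == "healthy" and healthy.stability.is_stable

    def test_deduplication(self, p0):
        eqs = find_steady_states(p0.replace(phi=0.001), n_starts=128, seed=5)
        ys = [reduce_y(e.state) for e in eqs]
        for i in range(len(ys)):
            for j in range(i + 1, len(ys)):
                assert np.max(np.abs(ys[i] - ys[j])) > 1e-6
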