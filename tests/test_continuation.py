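import numpy as np
import pytest

from hepdyn.continuation import (chronic_equilibrium, classify_hopf,
                                 continue_branch,
                                 detect_and_locate_bifurcations,
                                 locate_hopf_bisection, periodic_branch,
                                 trace_hopf_two_param)
from hepdyn.simulate import simulate_outcome
from hepdyn.stability import (critical_nu2, healthy_steady_state, reduce_y)


@pytest.fixture(scope="module")
def phi_branch(p0):
    """Chronic equilibrium branch in the phagocytosis rate phi."""
    y0 = chronic_equilibrium(p0.replace(phi=0.001), c0=0.3)
    assert y0 is not None
    return continue_branch(p0, "phi", (0.001, 0.1), y0)


@pytest.fixture(scope="module")
def phi_events(phi_branch):
    return detect_and_locate_bifurcations(phi_branch)


class TestContinueBranch:
    def test_healthy_branch_is_trivial_and_stable(self, p0):
        # the healthy state is independent of phi and stable throughout
        y0 = reduce_y(healthy_steady_state(p0).state)
        br = continue_branch(p0, "phi", (0.001, 0.5), y0)
        assert br.termination == "range_end"
        assert np.max(np.abs(br.states[:, 4])) == 0.0         # c = 0
        assert np.allclose(br.states[:, 6], 1.0)              # h = 1
        assert all(r.is_stable for r in br.reports)

    def test_branch_residuals(self, phi_branch):
        assert np.max(phi_branch.residuals) < 1e-10

    def test_chronic_branch_loses_stability(self, phi_branch):
        stable = phi_branch.stable
        assert stable[0]
        assert not stable[-1]

    def test_folds_are_followed(self, p0, phi_branch):
        # the chronic branch folds back: parameter values are not monotone
        assert np.any(np.diff(phi_branch.values) < 0)


class TestBifurcationDetection:
    def test_phi_hopf_located(self, phi_events):
        hopfs = [e for e in phi_events if e.type == "hopf"]
        assert len(hopfs) == 1
        h = hopfs[0]
        assert abs(h.indicator) < 1e-8       # crossing pair real part at the point
        assert h.omega > 0.01                # genuinely complex pair
        assert 0.02 < h.value < 0.06

    def test_phi_saddle_node_located(self, phi_events):
        sns = [e for e in phi_events if e.type == "saddle_node"]
        assert len(sns) == 1
        assert abs(sns[0].indicator) < 1e-8

    def test_hopf_agrees_with_direct_eigenvalue_bisection(self, p0, phi_events):
        # independent re-location: bisection in the bare parameter with Newton
        # re-solves, no arclength machinery
        h = [e for e in phi_events if e.type == "hopf"][0]
        res = locate_hopf_bisection(p0, "phi", (0.9 * h.value, 1.1 * h.value), h.state)
        assert res is not None
        assert res[0] == pytest.approx(h.value, abs=1e-6)

    def test_healthy_branch_transcritical_matches_closed_form(self, p0, rng):
        # the zero eigenvalue on the c = 0 branch is the a0 = 0 boundary
        for _ in range(5):
            p = p0.replace(gamma_h=float(rng.uniform(0.05, 0.3)),
                           gamma_m=float(rng.uniform(0.005, 0.05)),
                           k_m=float(rng.uniform(0.00005, 0.002)))
            crit = critical_nu2(p)
            if not 0.005 < crit < 0.5:
                continue
            y0 = reduce_y(healthy_steady_state(p).state)
            br = continue_branch(p, "nu_2", (max(crit - 0.05, 1e-4), crit + 0.05), y0)
            trans = [e for e in detect_and_locate_bifurcations(br)
                     if e.type == "transcritical"]
            assert len(trans) == 1
            assert trans[0].value == pytest.approx(crit, abs=1e-10)


class TestHopfCriticality:
    def test_phi_hopf_is_subcritical(self, p0, phi_events):
        h = [e for e in phi_events if e.type == "hopf"][0]
        assert classify_hopf(p0, "phi", h.value, h.state) == "sub"

    def test_nu2_hopf_is_supercritical(self, p0):
        y0 = chronic_equilibrium(p0.replace(nu_2=3.0), c0=0.3)
        br = continue_branch(p0, "nu_2", (3.0, 0.1), y0)
        hopfs = [e for e in detect_and_locate_bifurcations(br) if e.type == "hopf"]
        assert len(hopfs) == 1
        assert 1.0 < hopfs[0].value < 2.0
        assert classify_hopf(p0, "nu_2", hopfs[0].value, hopfs[0].state) == "super"


@pytest.fixture(scope="module")
def phi_nu_locus(p0, phi_branch):
    h = [e for e in detect_and_locate_bifurcations(phi_branch) if e.type == "hopf"][0]
    return trace_hopf_two_param(p0, "nu", "phi", (0.1, 0.02), 5,
                                seed_hopf=(h.value, h.state))


@pytest.fixture(scope="module")
def nu2_sweep(p0):
    return periodic_branch(p0, "nu_2", (0.102, 1.6), 9)


class TestTwoParameterLocus:
    def test_locus_shape(self, p0, phi_nu_locus):
        locus = phi_nu_locus
        assert locus.termination == "range_end"
        assert len(locus.scan_values) == 5
        # lowering neutrophil apoptosis shrinks the guaranteed-resolution
        # region: the Hopf moves to larger phi
        assert np.all(np.diff(locus.locate_values) > 0)

    def test_region_labels_verified_by_simulation(self, p0, phi_nu_locus):
        locus = phi_nu_locus
        assert locus.region_low == "B"
        assert locus.region_high == "M:Res"
        i = len(locus.scan_values) // 2
        nu_v, phi_v = locus.scan_values[i], locus.locate_values[i]
        bistable = p0.replace(nu=nu_v, phi=0.9 * phi_v)
        labels = {simulate_outcome(bistable, c0)[1].label for c0 in (0.01, 3.0)}
        assert labels == {"resolved", "chronic_steady"}
        monostable = p0.replace(nu=nu_v, phi=1.1 * phi_v)
        for c0 in (0.1, 0.3, 1.0):
            assert simulate_outcome(monostable, c0)[1].label == "resolved"

    def test_oscillation_region_shrinks_with_km(self, p0):
        # the oscillatory region in (nu_2, phi) at elevated k_m is strictly
        # contained in the low-k_m region: at the phi = 0.25 slice the window
        # is non-empty at k_m = 1e-4 and empty at k_m = 2e-3
        def oscillates(km, nu2):
            p = p0.replace(phi=0.25, k_m=km, nu_2=nu2)
            return simulate_outcome(p, 0.3)[1].label == "oscillatory"

        assert any(oscillates(0.0001, v) for v in (0.2, 0.5, 1.0))
        assert not any(oscillates(0.002, v) for v in (0.2, 0.5, 1.0))
        # the chronic branch has a Hopf at low k_m but none at k_m = 2e-3
        p_hi = p0.replace(phi=0.25, k_m=0.002)
        y0 = chronic_equilibrium(p_hi.replace(nu_2=3.0), c0=0.3)
        br = continue_branch(p_hi, "nu_2", (3.0, 0.3), y0)
        assert not [e for e in detect_and_locate_bifurcations(br) if e.type == "hopf"]
        # and the guaranteed-resolution boundary also moves left
        assert (critical_nu2(p0.replace(k_m=0.002))
                < critical_nu2(p0.replace(k_m=0.0001)))


class TestPeriodicBranch:
    def test_amplitude_vanishes_at_supercritical_hopf(self, nu2_sweep):
        pb = nu2_sweep
        osc = pb.amplitude_up > 0
        assert osc[:-1].all()                 # oscillatory inside the window
        assert not osc[-1]                    # steady beyond the Hopf at ~1.43
        amps = pb.amplitude_up[osc]
        assert amps[-1] < 0.15 * np.max(amps)

    def test_period_blows_up_towards_homoclinic(self, nu2_sweep):
        pb = nu2_sweep
        periods = pb.period_up[pb.period_up > 0]
        assert pb.period_up[0] > 10 * np.median(periods)
        assert pb.homoclinic_flag
        assert pb.homoclinic_bracket is not None
        assert pb.homoclinic_bracket[0] <= 0.102 + 1e-9

    def test_two_hopf_window_has_no_homoclinic_flag(self, p0):
        # at phi = 0.25 the oscillations are bounded by two Hopf points
        pb = periodic_branch(p0.replace(phi=0.25), "nu_2", (0.11, 2.0), 7)
        osc = pb.amplitude_up > 0
        assert osc.any()
        assert not osc[0] and not osc[-1]     # window interior to the range
        assert not pb.homoclinic_flag
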