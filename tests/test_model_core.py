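"""Structural model: binding fraction, baseline correction, IRM dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmer.model_core import (EndpointSpec, EndpointState, SharedParams,
                             corrected_baseline, endpoint_rhs, enzyme_observation,
                             eshared, punbound, simulate_endpoint,
                             simulate_endpoint_ode)


class TestPunbound:
    @pytest.mark.parametrize("C, kss, expected", [
        (0.0, 1.0, 1.0),          # no drug: fully unbound
        (0.0, 123.4, 1.0),
        (2.5, 2.5, 0.5),          # C = K_SS is the EC50
        (9.0, 1.0, 0.1),          # 1 - 9/10
    ])
    def test_values(self, C, kss, expected):
        assert punbound(C, kss) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("C, kss", [(-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, C, kss):
        with pytest.raises(ValueError):
            punbound(C, kss)

    @given(st.floats(0.0, 1e4), st.floats(1e-3, 1e3), st.floats(1e-3, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_unit_interval(self, C, kss, dC):
        lo, hi = punbound(C + dC, kss), punbound(C, kss)
        assert 0.0 < lo < hi <= 1.0


class TestEshared:
    @pytest.mark.parametrize("en, p, expected", [
        (0.564, 1.0, 0.564),      # full unbound IFN-beta at baseline
        (0.564, 0.0, 0.0),        # complete suppression
        (0.5, 0.5, 0.25),
    ])
    def test_product(self, en, p, expected):
        assert eshared(en, p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            eshared(1.2, 0.5)
        with pytest.raises(ValueError):
            eshared(0.5, -0.1)


class TestCorrectedBaseline:
    def test_decreasing_endpoint(self):
        # CDASI-A typical: 28.3 * (1 - 0.564) / 1.03
        shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.03)
        assert corrected_baseline(28.3, -1.0, shared) == pytest.approx(
            11.98, abs=0.01)

    def test_increasing_endpoint(self):
        # MMT-8: 113 * (1 + 0.176*0.564) * 1.03
        shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.03)
        assert corrected_baseline(113.0, 0.176, shared) == pytest.approx(
            127.9, abs=0.1)

    def test_zero_emax_keeps_observed_baseline(self):
        # sign(0) = 0 so the placebo factor drops out entirely
        shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.7)
        assert corrected_baseline(48.2, 0.0, shared) == pytest.approx(48.2)


class TestDynamics:
    def setup_method(self):
        self.shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.0)

    def test_rhs_zero_at_altered_steady_state(self):
        state = EndpointState.at_baseline(28.3, -1.0, self.shared)
        assert endpoint_rhs(state, -1.0, self.shared, 1.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_placebo_trajectory_flat(self):
        t = np.linspace(0, 24, 25)
        traj = simulate_endpoint(None, self.shared, t, p_unbound=1.0,
                                 observed_baseline=28.3, emax=-1.0)
        assert np.allclose(traj, 28.3, rtol=1e-9)

    def test_placebo_effect_drifts_to_shifted_baseline(self):
        shared = SharedParams(k_out=0.246, emax_norm=0.564, e_plac=1.03)
        t = np.linspace(0, 300, 301)
        traj = simulate_endpoint(None, shared, t, p_unbound=1.0,
                                 observed_baseline=28.3, emax=-1.0)
        # monotone approach to baseline / E_plac for a decreasing endpoint
        assert np.all(np.diff(traj) <= 0) and traj[0] > traj[-1]
        assert traj[-1] == pytest.approx(28.3 / 1.03, rel=1e-6)

    def test_full_suppression_reaches_corrected_baseline(self):
        t = np.linspace(0, 400, 201)
        traj = simulate_endpoint(None, self.shared, t, p_unbound=0.0,
                                 observed_baseline=28.3, emax=-1.0)
        target = corrected_baseline(28.3, -1.0, self.shared)
        assert np.all(np.diff(traj) <= 0) and traj[0] > traj[-1]
        assert traj[-1] == pytest.approx(target, rel=1e-8)

    def test_halflife_of_transition(self):
        # linear ODE in the endpoint: approach rate k_out under suppression
        t = np.array([0.0, np.log(2) / 0.246])
        traj = simulate_endpoint(None, self.shared, t, p_unbound=0.0,
                                 observed_baseline=28.3, emax=-1.0)
        target = corrected_baseline(28.3, -1.0, self.shared)
        assert traj[1] - target == pytest.approx((28.3 - target) / 2,
                                                 rel=1e-9)

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 1.0])
    def test_longrun_closure(self, p):
        # steady state under constant drive: End_base / (1 + Emax*En*p)
        t = np.linspace(0, 500, 101)
        for emax in (-1.0, -0.5, 0.176):
            traj = simulate_endpoint(None, self.shared, t, p_unbound=p,
                                     observed_baseline=50.0, emax=emax)
            base = corrected_baseline(50.0, emax, self.shared)
            expected = base / (1.0 + emax * self.shared.emax_norm * p)
            assert traj[-1] == pytest.approx(expected, rel=1e-8)

    def test_direction_consistency(self):
        # full suppression moves the endpoint in the direction of Emax
        t = np.linspace(0, 60, 61)
        for emax in (-1.0, -0.3, 0.176, 1.0):
            traj = simulate_endpoint(None, self.shared, t, p_unbound=0.0,
                                     observed_baseline=50.0, emax=emax)
            assert np.sign(traj[-1] - 50.0) == np.sign(emax)

    def test_steady_state_monotone_in_punbound(self):
        t = np.linspace(0, 500, 51)
        finals = [simulate_endpoint(None, self.shared, t, p_unbound=p,
                                    observed_baseline=50.0, emax=-1.0)[-1]
                  for p in np.linspace(0, 1, 9)]
        assert np.all(np.diff(finals) > 0)

    def test_analytic_matches_ode_for_piecewise_profile(self):
        bk = np.array([0.0, 4.0, 8.0, 12.0])
        vals = np.array([0.05, 0.6, 0.2, 1.0])
        t = np.linspace(0, 24, 49)
        analytic = simulate_endpoint(None, self.shared, t,
                                     p_unbound=(bk, vals),
                                     observed_baseline=28.3, emax=-1.0)

        def p_fn(tt):
            return vals[min(np.searchsorted(bk, tt, side="right") - 1,
                            len(vals) - 1)]

        ode = simulate_endpoint_ode(None, self.shared, t, p_fn,
                                    observed_baseline=28.3, emax=-1.0,
                                    rtol=1e-10, atol=1e-12)
        assert np.allclose(analytic, ode, rtol=1e-6)


class TestEnzymeObservation:
    @pytest.mark.parametrize("R, eps, sd, uln, expected", [
        (1.19, 0.0, 0.352, 200.0, 238.0),
        (1.0, 0.0, 0.352, 123.0, 123.0),
        (1.19, 1.0, 0.352, 100.0, 154.2),
    ])
    def test_denormalization(self, R, eps, sd, uln, expected):
        assert enzyme_observation(R, eps, sd, uln) == pytest.approx(expected)

    def test_rejects_nonpositive_uln(self):
        with pytest.raises(ValueError):
            enzyme_observation(1.0, 0.0, 0.1, 0.0)


class TestEndpointSpec:
    def test_rejects_emax_outside_unit_interval(self):
        with pytest.raises(ValueError, match="emax"):
            EndpointSpec(name="x", range_lo=0, range_hi=10,
                         improvement_direction="lower", emax=1.5,
                         baseline=5.0, ruv_sd=1.0)

    def test_rejects_baseline_outside_range(self):
        with pytest.raises(ValueError, match="baseline"):
            EndpointSpec(name="x", range_lo=0, range_hi=10,
                         improvement_direction="lower", emax=0.0,
                         baseline=11.0, ruv_sd=1.0)
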