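"""Forward model: Stehfest inversion oracles, Hertz contact, derived markers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma

from viscoclass.rheology import (
    CreepCurve,
    IndentationProtocol,
    RheologyError,
    ViscoParams,
    creep_compliance,
    derived_markers,
    hertz_compliance,
    hertz_indentation,
    laplace_modulus,
    local_loglog_slope,
)

TIMES = np.geomspace(0.02, 10.0, 60)


def params_strategy():
    return st.builds(
        ViscoParams,
        e1=st.floats(20.0, 2000.0),
        e2=st.floats(20.0, 4000.0),
        e3=st.floats(20.0, 4000.0),
        eta=st.floats(5.0, 1500.0),
        alpha_l=st.floats(0.52, 0.98),
        alpha_r=st.floats(0.11, 0.34),
    )


class TestLaplaceModulus:
    def test_elastic_limit_returns_network_modulus(self):
        p = ViscoParams(0.0, 0.0, 456.1, 0.0, 0.6, 0.2)
        for s in (0.01, 1.0, 250.0):
            assert laplace_modulus(p, s) == pytest.approx(456.1)

    def test_single_springpot_closed_form(self):
        p = ViscoParams(100.0, 0.0, 0.0, 0.0, 0.5, 0.2)
        assert laplace_modulus(p, 4.0) == pytest.approx(200.0)

    def test_sum_of_branches_at_reference_rate(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        assert laplace_modulus(p, 1.0) == pytest.approx(506.1)

    def test_rejects_non_positive_rate(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        with pytest.raises(RheologyError):
            laplace_modulus(p, 0.0)

    @given(params_strategy())
    @settings(max_examples=25, deadline=None)
    def test_strictly_increasing_in_rate(self, p):
        s = np.geomspace(1e-2, 1e3, 50)
        g = laplace_modulus(p, s)
        assert (np.diff(g) > 0).all()


class TestCreepCompliance:
    def test_hookean_spring_limit(self):
        p = ViscoParams(0.0, 0.0, 456.1, 0.0, 0.6, 0.2)
        j = creep_compliance(p, TIMES).values
        assert np.allclose(j, 1.0 / 456.1, rtol=5e-3)

    def test_newtonian_dashpot_limit(self):
        p = ViscoParams(0.0, 0.0, 0.0, 50.0, 0.6, 0.2)
        j = creep_compliance(p, TIMES).values
        assert np.allclose(j, TIMES / 50.0, rtol=5e-3)

    def test_single_springpot_power_law(self):
        # J(t) = t^0.6 / (E1 * Gamma(1.6)), Stehfest must agree to 0.5%
        p = ViscoParams(100.0, 0.0, 0.0, 0.0, 0.6, 0.2)
        j = creep_compliance(p, TIMES).values
        exact = TIMES**0.6 / (100.0 * gamma(1.6))
        assert np.max(np.abs(j / exact - 1.0)) < 5e-3

    def test_rejects_out_of_range_times(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        with pytest.raises(RheologyError):
            creep_compliance(p, np.array([1e-4, 1.0, 10.0] + [float(i) for i in range(2, 7)]))

    @given(params_strategy())
    @settings(max_examples=25, deadline=None)
    def test_positive_and_non_decreasing(self, p):
        j = creep_compliance(p, TIMES).values
        assert (j > 0).all()
        assert (np.diff(j) >= -1e-12 * j[:-1]).all()


class TestHertzContact:
    def test_hand_evaluated_compliance(self, protocol):
        proto = IndentationProtocol(force=1e-8, probe_radius=1e-5, poisson=0.5)
        depth = CreepCurve(TIMES, np.full_like(TIMES, 1e-7), kind="indentation")
        j = hertz_compliance(depth, proto).values
        assert j == pytest.approx(1.7778e-5, rel=1e-3)

    def test_doubling_force_halves_compliance(self):
        depth = CreepCurve(TIMES, np.full_like(TIMES, 1e-7), kind="indentation")
        j1 = hertz_compliance(depth, IndentationProtocol(force=1e-8)).values
        j2 = hertz_compliance(depth, IndentationProtocol(force=2e-8)).values
        assert np.allclose(j2, j1 / 2.0)

    def test_poisson_factor_on_depth(self):
        j = CreepCurve(TIMES, np.full_like(TIMES, 1.7778e-5), kind="compliance")
        d_incomp = hertz_indentation(j, IndentationProtocol(poisson=0.5)).values
        d_zero = hertz_indentation(j, IndentationProtocol(poisson=0.0)).values
        # the 1 - nu^2 factor rises from 0.75 to 1, scaling depth by 0.75^(2/3)
        assert np.allclose(d_incomp / d_zero, 0.75 ** (2.0 / 3.0))

    def test_indentation_inverts_hand_example(self):
        proto = IndentationProtocol(force=1e-8, probe_radius=1e-5, poisson=0.5)
        j = CreepCurve(TIMES, np.full_like(TIMES, 4.0 * np.sqrt(1e-5) * 1e-7**1.5 / (3e-8 * 0.75)),
                       kind="compliance")
        assert hertz_indentation(j, proto).values == pytest.approx(1e-7, rel=1e-9)

    def test_rejects_bad_force(self):
        with pytest.raises(RheologyError):
            IndentationProtocol(force=0.0)

    @given(st.floats(1e-9, 1e-7), st.floats(1e-6, 5e-5), st.floats(0.0, 0.49))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, force, radius, poisson):
        proto = IndentationProtocol(force=force, probe_radius=radius, poisson=poisson)
        depth = CreepCurve(TIMES, 1e-8 * (1.0 + TIMES / 10.0), kind="indentation")
        back = hertz_indentation(hertz_compliance(depth, proto), proto)
        assert np.allclose(back.values, depth.values, rtol=1e-12)


class TestDerivedMarkers:
    def test_total_modulus(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        assert derived_markers(p).e_sum == pytest.approx(456.1)

    def test_relaxation_time(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        assert derived_markers(p).tau == pytest.approx(0.5)

    def test_transition_frequency_closed_form(self):
        p = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
        assert derived_markers(p).f_t == pytest.approx(2 ** (1 / 0.65) / (2 * np.pi), rel=1e-9)
        assert derived_markers(p).f_t == pytest.approx(0.462, abs=1e-3)

    @given(params_strategy())
    @settings(max_examples=25, deadline=None)
    def test_transition_frequency_balances_branches(self, p):
        # bisection oracle: the rate where the two power-law branches cross
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if p.e1 * mid**p.alpha_l < p.e2 * mid**p.alpha_r:
                lo = mid
            else:
                hi = mid
        w_cross = np.sqrt(lo * hi)
        assert derived_markers(p).f_t * 2 * np.pi == pytest.approx(w_cross, rel=1e-4)


class TestLocalLogLogSlope:
    def test_exact_power_law_slope(self):
        curve = CreepCurve(TIMES, 3.0 * TIMES**0.5, kind="compliance")
        assert local_loglog_slope(curve) == pytest.approx(0.5, abs=1e-9)

    def test_constant_curve_slope_zero(self):
        curve = CreepCurve(TIMES, np.full_like(TIMES, 2.0), kind="compliance")
        assert np.allclose(local_loglog_slope(curve), 0.0, atol=1e-12)

    def test_healthy_curve_two_regimes(self, healthy_params_curve):
        # fast branch in (0.5, 1) at short times; slow branch near 0.2 in the
        # window between the crossover and the network-plateau onset
        _, curve = healthy_params_curve
        slopes = local_loglog_slope(curve)
        t = curve.times
        assert ((slopes[t <= 0.1] > 0.5) & (slopes[t <= 0.1] < 1.0)).all()
        slow = np.median(slopes[(t >= 1.5) & (t <= 6.0)])
        assert slow == pytest.approx(0.2, abs=0.05)

    def test_rejects_even_window(self, healthy_params_curve):
        with pytest.raises(RheologyError):
            local_loglog_slope(healthy_params_curve[1], window=4)
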