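"""Closed-form means, moment-equation variances and log-likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from gal1kinetics.models import (
    ThetaNoRepression,
    ThetaRepression,
    loglik_constant,
    loglik_timedep,
    mean_no_repression,
    mean_repression,
    var_no_repression,
    var_repression,
)

GRID = np.round(np.arange(0.0, 2.0001, 0.05), 10)


class TestMeans:
    def test_initial_condition_is_gfp0(self):
        th = ThetaNoRepression(GFP_0=3.7, r_basal=5.0, r_deg=0.8, sigma=1.0)
        assert mean_no_repression(0.0, th) == pytest.approx(3.7)

    def test_relaxation_toward_steady_state(self):
        th = ThetaNoRepression(GFP_0=0.0, r_basal=50.0, r_deg=0.5, sigma=1.0)
        assert mean_no_repression(2.0, th) == pytest.approx(63.2121, abs=1e-4)

    def test_steady_state_is_constant(self):
        th = ThetaNoRepression(GFP_0=100.0, r_basal=50.0, r_deg=0.5,
                               sigma=1.0)
        assert mean_no_repression(GRID, th) == pytest.approx(100.0)

    def test_repression_before_delay_equals_basal_form(self):
        rep = ThetaRepression(GFP_0=2.0, r_prod=3.0, r_deg=0.7, t_delay=0.9,
                              sigma=1.0)
        norep = ThetaNoRepression(GFP_0=2.0, r_basal=3.0, r_deg=0.7,
                                  sigma=1.0)
        t = GRID[GRID <= 0.9]
        np.testing.assert_allclose(mean_repression(t, rep),
                                   mean_no_repression(t, norep), rtol=1e-12)

    def test_repression_worked_values(self):
        th = ThetaRepression(GFP_0=100.0, r_prod=100.0, r_deg=0.5,
                             t_delay=0.5, sigma=1.0)
        assert mean_repression(0.5, th) == pytest.approx(122.12, abs=5e-3)
        assert mean_repression(1.5, th) == pytest.approx(74.07, abs=5e-3)
        # decay from the value at the delay
        assert mean_repression(1.5, th) == pytest.approx(
            float(mean_repression(0.5, th)) * np.exp(-0.5), rel=1e-12)

    def test_negative_time_rejected(self):
        th = ThetaNoRepression(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mean_no_repression(-0.1, th)

    def test_small_r_deg_limit_is_linear_growth(self):
        th = ThetaNoRepression(GFP_0=5.0, r_basal=3.0, r_deg=1e-12,
                               sigma=1.0)
        expected = 5.0 + 3.0 * GRID
        np.testing.assert_allclose(mean_no_repression(GRID, th), expected,
                                   rtol=1e-6)

    def test_monotone_decay_after_delay(self):
        th = ThetaRepression(GFP_0=1.0, r_prod=2.0, r_deg=0.4, t_delay=0.5,
                             sigma=1.0)
        t = GRID[GRID > 0.5]
        vals = mean_repression(t, th)
        assert np.all(np.diff(vals) < 0)


class TestVariances:
    def test_initial_variance_is_var0(self):
        th = ThetaNoRepression(5.0, 1.0, 0.5, 1.0, Var_0=7.0)
        assert var_no_repression(0.0, th) == pytest.approx(7.0)
        rep = ThetaRepression(5.0, 1.0, 0.5, 0.3, 1.0, Var_0=7.0)
        assert var_repression(0.0, rep) == pytest.approx(7.0)

    def test_stationary_poisson_limit(self):
        # GFP_0 = Var_0 = r_basal / r_deg: the process sits in its Poisson
        # stationary state, Var(t) = r_basal / r_deg for all t
        th = ThetaNoRepression(GFP_0=100.0, r_basal=50.0, r_deg=0.5,
                               sigma=1.0, Var_0=100.0)
        np.testing.assert_allclose(var_no_repression(GRID, th), 100.0,
                                   rtol=1e-10)

    def test_continuity_at_delay(self):
        th = ThetaRepression(GFP_0=80.0, r_prod=120.0, r_deg=0.6,
                             t_delay=0.7, sigma=1.0, Var_0=10.0)
        eps = 1e-9
        below = float(var_repression(0.7 - eps, th))
        above = float(var_repression(0.7 + eps, th))
        assert abs(below - above) < 1e-5
        m_below = float(mean_repression(0.7 - eps, th))
        m_above = float(mean_repression(0.7 + eps, th))
        assert abs(m_below - m_above) < 1e-5

    def test_small_r_deg_limit(self):
        th = ThetaNoRepression(GFP_0=5.0, r_basal=3.0, r_deg=1e-12,
                               sigma=1.0, Var_0=2.0)
        # d Var/dt -> r_basal + GFP_0 r_deg ~ r_basal as r_deg -> 0
        expected = 2.0 + 3.0 * GRID
        np.testing.assert_allclose(var_no_repression(GRID, th), expected,
                                   rtol=1e-5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gfp0=st.floats(0.0, 200.0), rb=st.floats(0.0, 200.0),
       rd=st.floats(0.01, 5.0), var0=st.floats(0.0, 100.0))
def test_no_repression_solutions_satisfy_their_odes(gfp0, rb, rd, var0):
    """The printed closed forms solve dGFP/dt = r_basal - r_deg GFP and the
    matching moment equation for the variance."""
    th = ThetaNoRepression(GFP_0=gfp0, r_basal=rb, r_deg=rd, sigma=1.0,
                           Var_0=var0)

    def rhs(t, y):
        gfp, var = y
        return [rb - rd * gfp,
                -2 * rd * var + rb * (2 - np.exp(-rd * t))
                + gfp0 * rd * np.exp(-rd * t)]

    sol = solve_ivp(rhs, (0, 2), [gfp0, var0], t_eval=GRID, rtol=1e-11,
                    atol=1e-12)
    np.testing.assert_allclose(mean_no_repression(GRID, th), sol.y[0],
                               rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(var_no_repression(GRID, th), sol.y[1],
                               rtol=1e-6, atol=1e-7)


def test_repression_solutions_satisfy_their_odes():
    """Piecewise closed forms match numerical integration across the delay."""
    gfp0, rp, rd, td, var0 = 100.0, 100.0, 0.5, 0.5, 5.0
    th = ThetaRepression(GFP_0=gfp0, r_prod=rp, r_deg=rd, t_delay=td,
                         sigma=1.0, Var_0=var0)

    def rhs_before(t, y):
        gfp, var = y
        return [rp - rd * gfp,
                -2 * rd * var + rp * (2 - np.exp(-rd * t))
                + gfp0 * rd * np.exp(-rd * t)]

    m_delay = float(mean_repression(td, th))

    def rhs_after(s, y):
        gfp, var = y
        return [-rd * gfp,
                -2 * rd * var + rd * m_delay * np.exp(-rd * s)]

    pre_grid = GRID[GRID <= td]
    sol1 = solve_ivp(rhs_before, (0, td), [gfp0, var0], t_eval=pre_grid,
                     rtol=1e-11, atol=1e-12)
    np.testing.assert_allclose(mean_repression(pre_grid, th), sol1.y[0],
                               rtol=1e-6)
    np.testing.assert_allclose(var_repression(pre_grid, th), sol1.y[1],
                               rtol=1e-6)

    post_grid = GRID[GRID >= td] - td
    sol2 = solve_ivp(rhs_after, (0, post_grid[-1]),
                     [m_delay, float(var_repression(td, th))],
                     t_eval=post_grid, rtol=1e-11, atol=1e-12)
    np.testing.assert_allclose(mean_repression(post_grid + td, th),
                               sol2.y[0], rtol=1e-6)
    np.testing.assert_allclose(var_repression(post_grid + td, th),
                               sol2.y[1], rtol=1e-6)


class TestLogLikelihoods:
    def test_zero_residuals_special_sigma(self):
        # sigma^2 = 1/(2 pi) makes each term log(1) = 0
        t = np.array([0.0, 0.5, 1.0])
        th = ThetaNoRepression(GFP_0=2.0, r_basal=0.0, r_deg=0.0,
                               sigma=float(np.sqrt(1 / (2 * np.pi))))
        y = mean_no_repression(t, th)
        assert loglik_constant(y, t, th) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_unit_residual(self):
        th = ThetaNoRepression(GFP_0=0.0, r_basal=0.0, r_deg=0.0, sigma=1.0)
        val = loglik_constant(np.array([1.0]), np.array([0.0]), th)
        assert val == pytest.approx(-1.418939, abs=1e-6)

    def test_additivity_of_zero_residual_point(self):
        th = ThetaNoRepression(GFP_0=5.0, r_basal=0.0, r_deg=0.0, sigma=0.7)
        t1 = np.array([0.0, 1.0])
        t2 = np.array([0.0, 1.0, 2.0])
        l1 = loglik_constant(mean_no_repression(t1, th), t1, th)
        l2 = loglik_constant(mean_no_repression(t2, th), t2, th)
        assert l2 - l1 == pytest.approx(-0.5 * np.log(2 * np.pi * 0.7 ** 2))

    def test_timedep_reduces_to_constant_when_process_variance_zero(self):
        th = ThetaRepression(GFP_0=0.0, r_prod=0.0, r_deg=0.0, t_delay=0.5,
                             sigma=0.8, Var_0=0.0)
        t = GRID[:10]
        y = np.linspace(0.1, 0.5, 10)
        assert loglik_timedep(y, t, th) == pytest.approx(
            loglik_constant(y, t, th), rel=1e-12)

    def test_timedep_two_point_hand_computed(self):
        th = ThetaNoRepression(GFP_0=10.0, r_basal=0.0, r_deg=0.5,
                               sigma=1.0, Var_0=0.0)
        t = np.array([0.0, 1.0])
        y = np.array([10.0, 7.0])
        mu1 = 10.0 * np.exp(-0.5)
        v1 = 10.0 * np.exp(-0.5) * (1 - np.exp(-0.5))
        expected = (-0.5 * (np.log(2 * np.pi * 1.0) + 0.0)
                    - 0.5 * (np.log(2 * np.pi * (1.0 + v1))
                             + (7.0 - mu1) ** 2 / (1.0 + v1)))
        assert loglik_timedep(y, t, th) == pytest.approx(expected, rel=1e-12)

    def test_sigma_zero_rejected(self):
        th = ThetaNoRepression(1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            loglik_constant(np.array([1.0]), np.array([0.0]), th)

    def test_length_mismatch_rejected(self):
        th = ThetaNoRepression(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            loglik_constant(np.array([1.0, 2.0]), np.array([0.0]), th)


def test_negative_parameters_rejected():
    with pytest.raises(ValueError):
        ThetaNoRepression(GFP_0=-1.0, r_basal=1.0, r_deg=1.0, sigma=1.0)
    with pytest.raises(ValueError):
        ThetaRepression(GFP_0=1.0, r_prod=1.0, r_deg=1.0, t_delay=-0.1,
                        sigma=1.0)
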