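"""Unit tests of the sliding-mode control laws, bounds and baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caedbs.controller import (AdaptiveBounds, ControllerGains, SurfaceParams,
                               adapt_bounds, afsmc_control, certainty_control,
                               error_boundary, ideal_control,
                               reaching_time_bound, robust_term,
                               settling_time, sliding_surface, stsmc_control,
                               time_bounds, total_control, u0_term)


SP = SurfaceParams(sigma=1.0, eta=1.5, rho=0.5,
                   k1=np.full(3, 5.0), k2=np.full(3, 5.0))


class TestSlidingSurface:
    def test_zero_history_zero_error(self):
        assert np.all(sliding_surface(np.zeros(3), np.zeros(3), 1.0, 1.5) == 0)

    def test_terminal_power(self):
        # sigma=1, eta=1.5, e=4, int_e=0: s = 4^1.5 = 8
        s = sliding_surface(np.array([4.0]), np.array([0.0]), 1.0, 1.5)
        assert s[0] == pytest.approx(8.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_odd_symmetry(self, e, ie):
        e, ie = np.array(e), np.array(ie)
        lhs = sliding_surface(-e, -ie, 0.05, 1.5)
        rhs = -sliding_surface(e, ie, 0.05, 1.5)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestIdealControl:
    def test_pure_feedforward_at_origin(self):
        f = np.array([1.0, -2.0, 0.5])
        ftau = np.array([0.1, 0.2, 0.3])
        d = np.array([0.5, 0.0, -0.5])
        xd_dot = np.array([3.0, 1.0, -1.0])
        g = np.diag([1.0, 2.0, 4.0])
        u = ideal_control(f, ftau, g, d, xd_dot, np.zeros(3), np.zeros(3), SP)
        assert np.allclose(u, np.linalg.solve(g, xd_dot - f - ftau - d))

    def test_singular_gain_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            ideal_control(np.zeros(3), np.zeros(3), np.zeros((3, 3)),
                          np.zeros(3), np.zeros(3), np.ones(3), np.ones(3), SP)


class TestCertaintyControl:
    def test_zero_gain_estimate_gives_zero_input(self):
        u = certainty_control(np.ones(3), np.ones(3), np.zeros((3, 3)),
                              np.ones(3), np.ones(3), np.ones(3), SP, eps0=0.5)
        assert np.allclose(u, 0.0)

    def test_identity_gain_halving(self):
        # G_hat = I, eps0 = 1: u_c = bracket / 2
        e, s = np.array([1.0, -2.0, 0.5]), np.array([0.2, 0.1, -0.3])
        args = (np.zeros(3), np.zeros(3), np.eye(3), np.zeros(3), e, s, SP)
        u1 = certainty_control(*args, eps0=1.0)
        u0 = certainty_control(*args, eps0=1e-12)
        assert np.allclose(u1, 0.5 * u0, rtol=1e-9)

    def test_u0_complement_identity(self):
        # for G_hat = I: u_c + u0 = bracket exactly
        e, s = np.array([1.0, -2.0, 0.5]), np.array([0.2, 0.1, -0.3])
        args = (np.array([0.3, 0.1, -0.2]), np.zeros(3), np.eye(3),
                np.array([1.0, 1.0, 1.0]), e, s, SP)
        u_c = certainty_control(*args, eps0=0.7)
        u_0 = u0_term(*args, eps0=0.7)
        full = certainty_control(*args, eps0=1e-13)
        assert np.allclose(u_c + u_0, full, rtol=1e-9)

    def test_u0_vanishes_without_regularization(self):
        u_0 = u0_term(np.ones(3), np.ones(3), np.eye(3), np.ones(3),
                      np.ones(3), np.ones(3), SP, eps0=0.0)
        assert np.all(u_0 == 0.0)


class TestRobustTerm:
    def _bounds(self, **kw):
        b = AdaptiveBounds()
        for k, v in kw.items():
            setattr(b, k, v)
        return b

    def test_zero_on_surface(self):
        b = self._bounds(eps_f=np.ones(3), d_hat=np.ones(3))
        assert np.all(robust_term(np.zeros(3), b, np.ones(3), np.ones(3)) == 0)

    def test_scalar_limit_recovers_bound_sum(self):
        # s=1, sigma0=1, Upsilon -> 0+: u_r -> total bound
        b = self._bounds(eps_f=np.array([2.0]), eps_ftau=np.array([1.0]),
                         d_hat=np.array([0.5]), eps_g=0.0,
                         upsilon=1e-12, sigma0=1.0)
        u_r = robust_term(np.array([1.0]), b, np.array([0.0]), np.array([0.0]))
        assert u_r[0] == pytest.approx(3.5, rel=1e-9)

    def test_magnitude_saturates_for_large_s(self):
        b = self._bounds(eps_f=np.array([4.0]), eps_ftau=np.array([0.0]),
                         d_hat=np.array([0.0]), upsilon=1e-9)
        mags = [abs(robust_term(np.array([m]), b,
                                np.array([0.0]), np.array([0.0]))[0])
                for m in (1.0, 10.0, 100.0)]
        assert mags == pytest.approx([4.0, 4.0, 4.0], rel=1e-6)

    def test_signs_follow_s(self):
        b = self._bounds(eps_f=np.ones(3), upsilon=0.1)
        s = np.array([0.5, -0.2, 0.0])
        u_r = robust_term(s, b, np.zeros(3), np.zeros(3))
        assert np.all(np.sign(u_r) == np.sign(s))


class TestAdaptBounds:
    def test_frozen_at_zero_error(self):
        b = AdaptiveBounds()
        ups0 = b.upsilon
        adapt_bounds(b, np.zeros(3), np.ones(3), np.ones(3), np.ones(3),
                     sigma=0.05, eta=1.5, dt=0.01)
        assert np.all(b.eps_f == 0) and np.all(b.d_hat == 0)
        assert b.upsilon == ups0

    def test_monotone_directions(self, rng):
        b = AdaptiveBounds()
        prev_ups = b.upsilon
        for _ in range(200):
            e = rng.normal(size=3)
            s = rng.normal(size=3)
            eps_before = b.eps_f.copy()
            d_before = b.d_hat.copy()
            adapt_bounds(b, e, s, rng.normal(size=3), rng.normal(size=3),
                         sigma=0.05, eta=1.5, dt=0.01)
            assert np.all(b.eps_f >= eps_before)
            assert np.all(b.d_hat >= d_before)
            assert b.upsilon <= prev_ups
            prev_ups = b.upsilon
        assert b.upsilon >= b.upsilon_min


class TestTotalControlAndBounds:
    def test_sum_and_saturation(self):
        u = total_control(np.array([1.0, -4.0, 2.0]), np.array([1.0, -2.0, 0.0]),
                          u_max=3.0)
        assert np.allclose(u, [2.0, -3.0, 2.0])

    def test_reaching_bound_zero_at_origin(self):
        assert reaching_time_bound(0.0, 1.0, 1.0, 0.5) == 0.0

    def test_settling_time_example(self):
        # sigma=1, eta=2, |x(t_r)|=1: t_s = eta/(eta-1) = 2
        assert settling_time(1.0, 2.0, 1.0) == pytest.approx(2.0)

    def test_error_boundary_shrinks_with_delta(self):
        es = [error_boundary(d, 0.05, 1.5) for d in (1.0, 0.1, 1e-6)]
        assert es[0] > es[1] > es[2]
        assert es[2] < 1e-3

    def test_bounds_decrease_with_gains(self):
        lo = time_bounds(SurfaceParams(sigma=1, eta=1.5, rho=0.5,
                                       k1=np.full(3, 2.0), k2=np.full(3, 2.0)),
                         v0=10.0, x_tr=1.0, delta=0.1)
        hi = time_bounds(SurfaceParams(sigma=1, eta=1.5, rho=0.5,
                                       k1=np.full(3, 20.0), k2=np.full(3, 20.0)),
                         v0=10.0, x_tr=1.0, delta=0.1)
        assert hi["t_reach"] < lo["t_reach"]

    def test_invalid_exponents_rejected(self):
        with pytest.raises(ValueError):
            reaching_time_bound(1.0, 1.0, 1.0, 1.2)
        with pytest.raises(ValueError):
            settling_time(1.0, 0.9, 1.0)


class TestBaselines:
    def test_afsmc_reduces_to_feedforward(self):
        u = afsmc_control(np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3),
                          np.eye(3), np.full(3, 2.0),
                          lam=1.0, k1=np.zeros(3) + 1e-12, k_sw=1.0, eps0=1e-12)
        # zero error history: u ~= G^-1(xd_dot - f_hat) + k_sw sign(0)
        assert np.allclose(u, [1.0, 1.0, 1.0], rtol=1e-6)

    def test_afsmc_switching_jump(self):
        args = dict(f_hat=np.zeros(3), ftau_hat=np.zeros(3), g_hat=np.eye(3),
                    xd_dot=np.zeros(3), lam=1.0, k1=np.ones(3), k_sw=5.0,
                    eps0=1e-12)
        up = afsmc_control(np.full(3, 1e-9), np.zeros(3), **args)
        dn = afsmc_control(np.full(3, -1e-9), np.zeros(3), **args)
        assert np.allclose(up - dn, 10.0, atol=1e-6)  # 2 k_sw jump

    def test_stsmc_idle_at_origin(self):
        u, w = stsmc_control(np.zeros(3), np.zeros(3), a=1.0, b=1.0, dt=0.01)
        assert np.all(u == 0) and np.all(w == 0)

    def test_stsmc_rejects_constant_disturbance_on_integrator(self):
        # scalar integrator s' = d - u with matched constant d: s -> 0
        dt = 1e-4
        s, w = 1.0, 0.0
        d = 0.5
        traj = []
        for _ in range(200_000):
            u, w = stsmc_control(np.array([s]), np.array([w]), a=2.0, b=2.0,
                                 dt=dt)
            w = float(w[0])
            s += dt * (d - float(u[0]))
            traj.append(abs(s))
        assert min(traj[-1000:]) < 1e-3

    def test_stsmc_continuity_as_dt_shrinks(self):
        # max per-step control jump -> 0 with dt on a fixed s trajectory
        jumps = []
        for dt in (1e-2, 1e-3, 1e-4):
            w = np.zeros(1)
            us = []
            for t in np.arange(0, 1.0, dt):
                s = np.array([np.sin(2 * np.pi * t)])
                u, w = stsmc_control(s, w, a=2.0, b=5.0, dt=dt)
                us.append(float(u[0]))
            jumps.append(np.max(np.abs(np.diff(us))))
        assert jumps[0] > jumps[1] > jumps[2]


class TestParameterValidation:
    @pytest.mark.parametrize("kw", [
        {"sigma": -1.0}, {"eta": 1.0}, {"eta": 2.0}, {"rho": 0.0},
        {"rho": 1.0}, {"k1": np.zeros(3)},
    ])
    def test_surface_ranges_enforced(self, kw):
        with pytest.raises(ValueError):
            SurfaceParams(**kw)

    def test_gain_vector_roundtrip(self):
        from caedbs import _kernels as K
        cg = ControllerGains().pack()
        assert cg.shape == (K.CG_LEN,)
        assert cg[K.CG_ETA] == 1.5
        assert cg[K.CG_UPSMIN] == 1e-6
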