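"""Unit and property tests for the plasticity primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from replaynet.plasticity import (
    AsymmetricExpWindow,
    EligibilityParams,
    GaussianWindow,
    STPParams,
    STPState,
    SymmetricExpDiffWindow,
    eligibility_step,
    normalize_weights,
    pair_spikes,
    stdp_kernel,
    stp_decay,
    stp_on_spike,
    stp_release_train,
)

GUZMAN = STPParams(U=0.37, tau_std=150.0, tau_stf=40.0)


class TestSTP:
    def test_resting_state_is_fixed_point_of_decay(self):
        s = STPState(D=np.array(1.0), F=np.array(0.37))
        out = stp_decay(s, 123.4, GUZMAN)
        assert out.D == pytest.approx(1.0)
        assert out.F == pytest.approx(0.37)

    def test_decay_closed_form_values(self):
        # direct evaluation of the exponential relaxation after one spike
        s = STPState(D=np.array(0.63), F=np.array(0.6031))
        out = stp_decay(s, 10.0, GUZMAN)
        assert out.D == pytest.approx(1 - 0.37 * np.exp(-10 / 150), rel=1e-12)
        assert out.F == pytest.approx(0.37 + 0.2331 * np.exp(-10 / 40), rel=1e-12)
        assert out.D == pytest.approx(0.65386, abs=1e-5)
        assert out.F == pytest.approx(0.55154, abs=1e-5)

    def test_decay_asymptote(self):
        s = STPState(D=np.array(0.1), F=np.array(0.99))
        out = stp_decay(s, 1e9, GUZMAN)
        assert out.D == pytest.approx(1.0)
        assert out.F == pytest.approx(GUZMAN.U)

    @pytest.mark.parametrize(
        "D,F,U,release,D_new,F_new",
        [
            (1.0, 0.6, 0.6, 0.6, 0.4, 0.84),
            (1.0, 0.37, 0.37, 0.37, 0.63, 0.37 + 0.37 * 0.63),
        ],
    )
    def test_spike_jump(self, D, F, U, release, D_new, F_new):
        params = STPParams(U=U, tau_std=150.0, tau_stf=40.0)
        rel, out = stp_on_spike(STPState(D=np.array(D), F=np.array(F)), params)
        assert rel == pytest.approx(release)
        assert out.D == pytest.approx(D_new)
        assert out.F == pytest.approx(F_new)

    def test_periodic_spiking_release_converges(self):
        # long-run iteration of the decay+jump maps has a fixed point
        state = STPState.resting(GUZMAN)
        prev = None
        for _ in range(10_000):
            state = stp_decay(state, 50.0, GUZMAN)
            rel, state = stp_on_spike(state, GUZMAN)
            if prev is not None and abs(rel - prev) < 1e-10:
                break
            prev = rel
        else:
            pytest.fail("release did not converge")
        # verify against direct fixed-point solution of the composed map
        ed, ef = np.exp(-50 / 150), np.exp(-50 / 40)
        # D* and F* just before a spike satisfy linear fixed-point equations
        # D_pre = 1 - (1 - D_pre(1-F_pre)) * ed ; F_pre = U + (F_pre + U(1-F_pre) - U) ef
        f_star = (GUZMAN.U * (1 - ef) + GUZMAN.U * ef) / (1 - ef * (1 - GUZMAN.U))
        d_star = (1 - ed) / (1 - ed * (1 - f_star))
        assert rel == pytest.approx(d_star * f_star, abs=1e-8)

    @given(
        dts=st.lists(st.floats(0.1, 200.0), min_size=1, max_size=30),
        u=st.floats(0.05, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_state_bounds_invariant(self, dts, u):
        """0 < D <= 1 and U <= F <= 1 under any decay/spike interleaving.

        Strict positivity of D requires U < 1: at U = 1 a spike releases the
        entire resource pool and D touches zero exactly.
        """
        params = STPParams(U=u, tau_std=120.0, tau_stf=60.0)
        state = STPState.resting(params)
        for dt in dts:
            state = stp_decay(state, dt, params)
            _, state = stp_on_spike(state, params)
            assert 0.0 < state.D <= 1.0
            assert params.U - 1e-12 <= state.F <= 1.0

    def test_event_based_matches_fine_euler(self):
        """Event-based STP agrees with dt = 0.001 ms Euler integration of
        the jump-free ODEs plus explicit jumps, on random trains."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            times = np.sort(rng.uniform(0, 300, size=8))
            rel_event = stp_release_train(times, GUZMAN)
            # brute-force Euler
            dt = 0.001
            D, F = 1.0, GUZMAN.U
            rel_euler = []
            t = 0.0
            for ts in times:
                n = int(round((ts - t) / dt))
                for _ in range(n):
                    D += dt * (1 - D) / GUZMAN.tau_std
                    F += dt * (GUZMAN.U - F) / GUZMAN.tau_stf
                t = ts
                rel_euler.append(D * F)
                D -= D * F
                F += GUZMAN.U * (1 - F)
            np.testing.assert_allclose(rel_event, rel_euler, rtol=1e-4)


class TestSTDPWindows:
    def test_gaussian_values(self):
        w = GaussianWindow(a=1.0, tau=70.0)
        assert w(0.0) == pytest.approx(1.0)
        assert w(70.0) == pytest.approx(np.exp(-0.5))
        assert w(-70.0) == pytest.approx(np.exp(-0.5))

    def test_asymmetric_values(self):
        w = AsymmetricExpWindow(a_plus=1.0, a_minus=0.5, tau_plus=20.0, tau_minus=40.0)
        assert w(-40.0) == pytest.approx(-0.5 * np.exp(-1.0))
        assert w(20.0) == pytest.approx(np.exp(-1.0))
        assert w(0.0) == pytest.approx(1.0)  # zero lag on the potentiation branch

    def test_symmetric_expdiff_value_and_symmetry(self):
        w = SymmetricExpDiffWindow(a_plus=1.0, a_minus=0.5, tau_plus=20.0, tau_minus=40.0)
        assert w(0.0) == pytest.approx(0.5)
        dts = np.linspace(-200, 200, 101)
        np.testing.assert_array_equal(w(dts), w(-dts))

    def test_sign_structure(self):
        asym = AsymmetricExpWindow()
        dts = np.array([-50.0, -1.0, 1.0, 50.0])
        assert np.all(np.sign(asym(dts)) == np.sign(dts))
        gauss = GaussianWindow()
        np.testing.assert_array_equal(gauss(dts), gauss(-dts))

    def test_stdp_kernel_broadcasts(self):
        w = GaussianWindow(a=2.0, tau=10.0)
        out = stdp_kernel(w, np.array([0.0, 10.0]), 0.0)
        np.testing.assert_allclose(out, [2.0, 2.0 * np.exp(-0.5)])


class TestPairing:
    def test_all_to_all_enumeration(self):
        assert pair_spikes("all_to_all", [0, 10], [5]) == [(5.0, 0.0), (5.0, 10.0)]

    def test_nearest_neighbor_definition(self):
        assert pair_spikes("nearest_neighbor", [10], [0, 5, 20, 30]) == [
            (5.0, 10.0),
            (20.0, 10.0),
        ]

    def test_empty(self):
        assert pair_spikes("nearest_neighbor", [10], []) == []
        assert pair_spikes("all_to_all", [], [1.0]) == []


class TestEligibility:
    PARAMS = EligibilityParams(eta=2.0, tau_w=500.0)

    def test_zero_drive_zero_trace_is_fixed(self):
        w, d = eligibility_step(np.array(3.0), np.array(0.0), 0.0, 1.0, self.PARAMS)
        assert w == 3.0 and d == 0.0

    def test_constant_drive_steady_state(self):
        w, d = 0.0, 0.0
        g = 0.3
        for _ in range(50_000):
            w, d = eligibility_step(w, d, g, 1.0, self.PARAMS)
        assert d == pytest.approx(self.PARAMS.eta * g, rel=1e-3)

    def test_impulse_response_matches_matrix_exponential(self):
        """Total weight change from a drive impulse of area G equals eta*G,
        verified against the exact solution of the 2x2 linear system."""
        eta, tau_w, dt = self.PARAMS.eta, self.PARAMS.tau_w, 0.5
        G = 1.7
        # impulse: delta jumps by eta*G/tau_w, then free evolution
        w, d = 0.0, eta * G / tau_w
        for _ in range(int(20 * tau_w / dt)):
            w, d = eligibility_step(w, d, 0.0, dt, self.PARAMS)
        assert w == pytest.approx(eta * G, rel=1e-3)
        # cross-check one free-evolution segment against expm
        A = np.array([[0.0, 1.0], [0.0, -1.0 / tau_w]])
        x0 = np.array([0.0, eta * G / tau_w])
        xT = expm(A * 5000.0) @ x0
        w2, d2 = 0.0, eta * G / tau_w
        for _ in range(int(5000 / dt)):
            w2, d2 = eligibility_step(w2, d2, 0.0, dt, self.PARAMS)
        assert w2 == pytest.approx(xT[0], rel=1e-3)
        assert d2 == pytest.approx(xT[1], rel=1e-2)


class TestNormalization:
    def test_rescale_halves_doubled_row(self):
        w = np.array([[0.0, 2.0, 2.0], [1.0, 0.0, 1.0], [0.5, 0.5, 0.0]])
        ref = np.array([2.0, 2.0, 1.0])
        out = normalize_weights(w, ref, "rescale_to_initial")
        np.testing.assert_allclose(out.sum(axis=1), ref)
        np.testing.assert_allclose(out[0], [0.0, 1.0, 1.0])

    def test_rescale_is_idempotent(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (5, 5))
        ref = np.full(5, 1.3)
        once = normalize_weights(w, ref, "rescale_to_initial")
        twice = normalize_weights(once, ref, "rescale_to_initial")
        np.testing.assert_allclose(once, twice)

    def test_rescale_leaves_zero_rows(self):
        w = np.zeros((2, 2))
        out = normalize_weights(w, np.ones(2), "rescale_to_initial")
        np.testing.assert_array_equal(out, w)

    @pytest.mark.parametrize("total,factor", [(0.5, 1.0), (1.25, 0.8)])
    def test_cap_mode(self, total, factor):
        w = np.array([[0.0, total / 2, total / 2]])
        out = normalize_weights(w, 1.0, "cap_at_one")
        np.testing.assert_allclose(out, w * factor)

    def test_cap_never_increases(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 0.5, (6, 6))
        out = normalize_weights(w, 1.0, "cap_at_one")
        assert np.all(out <= w + 1e-15)
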