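"""Tests for the offline spike-train generators and bias evaluator."""

import numpy as np
import pytest
from scipy import stats

from replaynet import bias_eval as be
from replaynet.plasticity import GaussianWindow, STPParams, pair_spikes, stp_release_train


class TestSequenceTrains:
    def test_single_spike_deterministic_lag_grid(self):
        p = be.SequenceTrainParams(n_spikes=1, mean_isi=20.0, lag=10.0)
        trains = be.gen_sequence_trains(p, 0)
        for n, t in enumerate(trains):
            assert t.shape == (1,)
            assert t[0] == pytest.approx(n * 10.0)
        # neuron #11 (1-based), i.e. index 10, starts at 100 ms
        assert trains[10][0] == pytest.approx(100.0)

    def test_refractory_and_truncated_exponential_mean(self):
        p = be.SequenceTrainParams(n_spikes=2, mean_isi=20.0, lag=5.0)
        rng = np.random.default_rng(42)
        isis = []
        for _ in range(5000):
            trains = be._gen_sequence_batch(1, 2, 20.0, 5.0, rng)[0]
            isis.extend(np.diff(trains, axis=-1).ravel())
        isis = np.asarray(isis)
        assert isis.min() >= 1.0
        # E[ISI | ISI >= 1] = 1 + tau for an exponential by memorylessness
        assert isis.mean() == pytest.approx(21.0, rel=0.02)

    def test_spike_counts(self):
        p = be.SequenceTrainParams(n_spikes=5, mean_isi=10.0, lag=7.0)
        trains = be.gen_sequence_trains(p, 3)
        assert len(trains) == 21
        assert all(t.shape == (5,) and np.all(np.diff(t) >= 1.0) for t in trains)


class TestThetaTrains:
    def test_center_neuron_peaks_mid_track(self):
        p = be.ThetaTrainParams(alpha=0.15, beta=0.5)
        rng = np.random.default_rng(0)
        counts = np.zeros(1000)
        for _ in range(200):
            trains = be.gen_theta_trains(p, rng)
            b = trains[40].astype(int)
            counts[np.clip(b, 0, 999)] += 1
        # expected peak of neuron #41 (mu = 0.5) near t = 500 ms
        sm = np.convolve(counts, np.ones(101) / 101, mode="same")
        assert abs(int(np.argmax(sm)) - 500) < 100

    def test_flat_phase_limit_matches_place_field_rate(self):
        # beta -> 0: von Mises factor tends to 1/(2pi); expected spike count
        # of the center neuron approaches alpha * integral(PF) / (2pi)
        p = be.ThetaTrainParams(alpha=0.1, beta=1e-9)
        rng = np.random.default_rng(1)
        n_spk = np.mean([len(be.gen_theta_trains(p, rng)[40]) for _ in range(300)])
        prob = be._theta_prob_batch(1, p, np.random.default_rng(2))[0, 40]
        assert n_spk == pytest.approx(prob.sum(), rel=0.1)

    def test_phase_concentration_reduces_circular_variance(self):
        rng = np.random.default_rng(5)
        cvs = []
        for beta in (0.1, 1.0, 10.0):
            p = be.ThetaTrainParams(alpha=0.15, beta=beta)
            cos_sum = sin_sum = n = 0.0
            for _ in range(100):
                c = rng.uniform(0, 2 * np.pi)
                geometry = be._theta_geometry(p)
                prob = be._theta_prob_batch(1, p, np.random.default_rng(rng.integers(2**31)))[0]
                spikes = np.random.default_rng(rng.integers(2**31)).random(prob.shape) < prob
                # spike phases of neuron 41 relative to its preferred phase
                t_sec = (np.flatnonzero(spikes[40]) + 0.5) / 1000.0
                mu = 0.5
                phase = 2 * np.pi * 8 * t_sec - np.pi * (mu - t_sec)
                cos_sum += np.cos(phase).sum()
                sin_sum += np.sin(phase).sum()
                n += phase.size
            r = np.hypot(cos_sum, sin_sum) / n
            cvs.append(1.0 - r)
        assert cvs[0] > cvs[1] > cvs[2]


class TestWeightChanges:
    def test_worked_example_two_center_spikes(self):
        # center spikes [0, 10]; postsynaptic neuron spikes [5];
        # releases 0.37 and 0.36063; Gaussian kernel at |dt| = 5
        trains = [np.array([], float)] * 21
        trains[10] = np.array([0.0, 10.0])
        trains[9] = np.array([5.0])
        d = be.compute_weight_changes(
            trains, GaussianWindow(1.0, 70.0), "all_to_all", be.REPLAY_STP, 10
        )
        expected = (0.37 + 0.36063) * np.exp(-0.5 * (5 / 70) ** 2)
        assert d[9] == pytest.approx(expected, abs=1e-4)
        assert d[10] == 0.0
        assert np.all(d[:9] == 0) and np.all(d[11:] == 0)

    def test_empty_postsynaptic_train_gives_zero(self):
        trains = [np.array([], float)] * 21
        trains[10] = np.array([0.0, 10.0])
        d = be.compute_weight_changes(
            trains, GaussianWindow(), "all_to_all", be.REPLAY_STP, 10
        )
        assert np.all(d == 0)

    @pytest.mark.parametrize("scheme", ["all_to_all", "nearest_neighbor"])
    def test_matches_pair_enumeration_oracle(self, scheme):
        """Vectorized evaluator equals a brute-force oracle that enumerates
        spike pairs explicitly and integrates STP by fine Euler steps."""
        rng = np.random.default_rng(11)
        window = GaussianWindow(1.0, 70.0)
        for _ in range(10):
            p = be.SequenceTrainParams(
                n_spikes=int(rng.integers(2, 6)),
                mean_isi=float(rng.uniform(5, 40)),
                lag=float(rng.uniform(5, 40)),
            )
            trains = be.gen_sequence_trains(p, rng)
            d = be.compute_weight_changes(trains, window, scheme, be.REPLAY_STP, 10)
            # oracle: Euler-integrated STP releases + explicit pair lists
            tc = trains[10]
            dt = 0.001
            D, F, t = 1.0, be.REPLAY_STP.U, 0.0
            rel = {}
            for ts in tc:
                for _ in range(int(round((ts - t) / dt))):
                    D += dt * (1 - D) / be.REPLAY_STP.tau_std
                    F += dt * (be.REPLAY_STP.U - F) / be.REPLAY_STP.tau_stf
                t = ts
                rel[ts] = D * F
                D, F = D - D * F, F + be.REPLAY_STP.U * (1 - F)
            expected = np.zeros(21)
            for i, ti in enumerate(trains):
                if i == 10:
                    continue
                for t_post, t_pre in pair_spikes(scheme, tc, ti):
                    expected[i] += window(t_post - t_pre) * rel[t_pre]
            np.testing.assert_allclose(d, expected, rtol=1e-3)

    def test_kernel_amplitude_linearity(self):
        rng = np.random.default_rng(3)
        p = be.SequenceTrainParams(n_spikes=4, mean_isi=12.0, lag=9.0)
        trains = be.gen_sequence_trains(p, rng)
        d1 = be.compute_weight_changes(trains, GaussianWindow(1.0, 70.0), "all_to_all", be.REPLAY_STP, 10)
        d2 = be.compute_weight_changes(trains, GaussianWindow(2.0, 70.0), "all_to_all", be.REPLAY_STP, 10)
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)
        assert be.compute_bias(d2, 10) == pytest.approx(2 * be.compute_bias(d1, 10))


class TestBias:
    def test_symmetric_vector_is_zero(self):
        d = np.exp(-np.abs(np.arange(21) - 10.0))
        assert be.compute_bias(d, 10) == pytest.approx(0.0)

    def test_single_entry(self):
        d = np.zeros(21)
        d[0] = 2.0
        assert be.compute_bias(d, 10) == 2.0

    def test_index_reflection_negates_bias(self):
        """Reflecting neuron indices about the center negates the bias
        exactly, for any window and gating."""
        rng = np.random.default_rng(8)
        p = be.SequenceTrainParams(n_spikes=4, mean_isi=15.0, lag=10.0)
        trains = be.gen_sequence_trains(p, rng)
        w = GaussianWindow(1.0, 70.0)
        b = be.compute_bias(
            be.compute_weight_changes(trains, w, "all_to_all", be.REPLAY_STP, 10), 10
        )
        b_ref = be.compute_bias(
            be.compute_weight_changes(trains[::-1], w, "all_to_all", be.REPLAY_STP, 10), 10
        )
        assert b_ref == pytest.approx(-b, rel=1e-12)

    def test_time_reversal_preserves_changes_without_gating(self):
        """With the STP gating removed and a symmetric window, time reversal
        leaves every weight change invariant (so reversal plus reflection
        negates the bias exactly); the gated evaluator breaks this symmetry,
        which is the mechanism under study."""
        rng = np.random.default_rng(9)
        p = be.SequenceTrainParams(n_spikes=4, mean_isi=15.0, lag=10.0)
        trains = be.gen_sequence_trains(p, rng)
        T = max(t.max() for t in trains)
        rev = [np.sort(T - t) for t in trains]
        w = GaussianWindow(1.0, 70.0)
        d = be.compute_weight_changes(trains, w, "all_to_all", None, 10)
        d_rev = be.compute_weight_changes(rev, w, "all_to_all", None, 10)
        np.testing.assert_allclose(d_rev, d, rtol=1e-12)
        b_revref = be.compute_bias(
            be.compute_weight_changes(rev[::-1], w, "all_to_all", None, 10), 10
        )
        assert b_revref == pytest.approx(-be.compute_bias(d, 10), rel=1e-10)


class TestEvaluateSetting:
    def test_reverse_bias_in_burst_regime(self):
        """Bursting sequences (5 spikes, short ISI) give overwhelmingly
        positive reverse-direction biases with the fitted STP constants."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = be.SequenceTrainParams(
                n_spikes=5,
                mean_isi=float(rng.uniform(5, 18)),
                lag=float(rng.uniform(5, 18)),
            )
            res = be.evaluate_setting(
                p, GaussianWindow(1.0, 70.0), seed=int(rng.integers(2**31))
            )
            assert res.mean_bias > 0
            assert res.p_pos > 0.5
            assert res.wilcoxon_p < 0.01 or res.binomial_p < 0.01

    def test_asymmetric_all_to_all_never_positive(self):
        """The asymmetric CA1 window with all-to-all pairing produces no
        significant positive bias."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = be.SequenceTrainParams(
                n_spikes=5,
                mean_isi=float(rng.uniform(5, 20)),
                lag=float(rng.uniform(5, 20)),
            )
            stp = STPParams(
                U=float(rng.uniform(0.1, 0.6)),
                tau_std=float(rng.uniform(50, 500)),
                tau_stf=float(rng.uniform(10, 300)),
            )
            res = be.evaluate_setting(
                p, be.GUZMAN_ASYMMETRIC_WINDOW, "all_to_all", stp, seed=int(rng.integers(2**31))
            )
            assert not (res.mean_bias > 0 and res.wilcoxon_p < 0.01)

    def test_mean_bias_near_zero_without_gating_symmetric_window(self):
        """Ungated symmetric-window biases have mean ~ 0 over realizations."""
        rng = np.random.default_rng(4)
        biases = []
        for _ in range(2000):
            trains = be._gen_sequence_batch(1, 3, 15.0, 12.0, rng)[0]
            d = be.compute_weight_changes(list(trains), GaussianWindow(1.0, 70.0), "all_to_all", None, 10)
            biases.append(be.compute_bias(d, 10))
        biases = np.asarray(biases)
        sem = biases.std(ddof=1) / np.sqrt(biases.size)
        assert abs(biases.mean()) < 3 * sem


class TestTenCellSummation:
    def test_summed_biases_scale_with_cell_count(self):
        """Summing the biases of ten independent center-cell trains
        amplifies the mean bias roughly tenfold, the mechanism by which
        overlapping place cells make run-regime biases significant."""
        tp = be.ThetaTrainParams(alpha=0.12, beta=1.0)
        w = GaussianWindow(1.0, 70.0)
        b1, _ = be._theta_bias_batch(150, tp, w, be.REPLAY_STP, np.random.default_rng(1))
        b10, _ = be._theta_bias_batch(
            150, tp, w, be.REPLAY_STP, np.random.default_rng(2), n_center_cells=10
        )
        assert b1.mean() > 0
        ratio = b10.mean() / b1.mean()
        assert 5 < ratio < 20


class TestSweep:
    def test_pearson_matches_two_pass_formula(self):
        sw = be.run_sweep("fig3", n_settings=30, n_realizations=20, seed=0, n_spikes=[3])
        df = sw.settings
        row = sw.correlations.query("parameter == 'mean_isi' and statistic == 'mean_bias'")
        x, y = df["mean_isi"].to_numpy(), df["mean_bias"].to_numpy()
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert row["r"].iloc[0] == pytest.approx(r_manual, abs=1e-12)

    def test_sweep_table_shape_and_determinism(self):
        a = be.run_sweep("fig4", n_settings=10, n_realizations=10, seed=5)
        b = be.run_sweep("fig4", n_settings=10, n_realizations=10, seed=5)
        assert a.settings.equals(b.settings)
        assert set(["U", "tau_std", "tau_stf", "mean_bias", "p_pos"]).issubset(a.settings.columns)
        assert np.all(np.abs(a.correlations["r"]) <= 1.0)
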