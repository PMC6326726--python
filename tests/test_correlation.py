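"""Spike-density / whisker-angle trial-by-trial correlation matrices."""

import numpy as np
import pytest

from whiskpc.behavior import TrialEpochs, epoch_trials
from whiskpc.correlation import (diagonal_with_ci, max_corr_shift, pool_cells,
                                 spike_density, trial_correlation_matrix)


def epochs_from_matrix(data, window=(-100.0, 300.0)):
    return TrialEpochs(data=data, window=window)


class TestSpikeDensity:
    def test_single_spike_integral_is_one(self):
        sdf = spike_density([np.array([50.0])] * 3, window=(-100.0, 300.0))
        integral = sdf.data.sum(axis=1) / 1e3  # spikes/s on a 1 ms grid
        assert np.allclose(integral, 1.0, rtol=1e-6)
        assert sdf.data[0].argmax() == 150  # bump centered on the spike

    def test_empty_trial_is_zero_row(self):
        sdf = spike_density([np.empty(0), np.array([10.0])])
        assert (sdf.data[0] == 0).all()

    def test_poisson_trials_mean_matches_rate(self):
        rng = np.random.default_rng(0)
        lam = 65.0
        trials = [
            np.sort(rng.uniform(-100, 300, rng.poisson(lam * 0.4)))
            for _ in range(500)
        ]
        sdf = spike_density(trials)
        mean_rate = sdf.data.mean()
        assert mean_rate == pytest.approx(lam, rel=0.05)

    def test_baseline_alignment_zeroes_baseline_mean(self):
        rng = np.random.default_rng(1)
        trials = [np.sort(rng.uniform(-200, 300, 30)) for _ in range(20)]
        sdf = spike_density(trials, window=(-200.0, 300.0),
                            baseline_window=(-200.0, 0.0))
        t = sdf.times
        base = sdf.data[:, (t >= -200) & (t < 0)].mean(axis=1)
        assert np.allclose(base, 0.0, atol=1e-9)
        assert sdf.aligned


class TestCorrelationMatrix:
    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (40, 400))
        sdf_like = spike_density(
            [np.sort(rng.uniform(-100, 300, 20)) for _ in range(40)])
        # whisker bin j constructed as affine function of spike bin i=5
        t = sdf_like.times
        bin5 = sdf_like.data[:, (t >= -50) & (t < -40)].mean(axis=1)
        wh = np.tile(x, 1)[:, :400]
        # whisker samples covering 200..210 ms sit 300 ms after window start
        wh[:, 300:310] = (3.0 * bin5 + 2.0)[:, None]
        m = trial_correlation_matrix(sdf_like, epochs_from_matrix(wh))
        assert m.R[5, 30] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_cell_is_nan_not_zero(self):
        rng = np.random.default_rng(3)
        sdf = spike_density(
            [np.sort(rng.uniform(-100, 300, 20)) for _ in range(20)])
        wh = rng.normal(0, 1, (20, 400))
        wh[:, 0:10] = 7.0  # constant whisker bin 0
        m = trial_correlation_matrix(sdf, epochs_from_matrix(wh))
        assert np.isnan(m.R[:, 0]).all()
        # NaN cells are excluded from the max search
        r, c = m.max_cell
        assert not np.isnan(m.R[r, c])

    def test_trial_order_reversal_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(4)
        trials = [np.sort(rng.uniform(-100, 300, 25)) for _ in range(30)]
        wh = rng.normal(0, 1, (30, 400))
        m1 = trial_correlation_matrix(spike_density(trials),
                                      epochs_from_matrix(wh))
        m2 = trial_correlation_matrix(spike_density(trials[::-1]),
                                      epochs_from_matrix(wh[::-1]))
        assert np.allclose(np.nan_to_num(m1.R), np.nan_to_num(m2.R))

    def test_planted_lag_recovered_at_matrix_maximum(self, coupled_session):
        protocol, train, trace = coupled_session
        from tests.conftest import relative_ss_ms

        onsets = protocol.onsets("pre")
        sdf = spike_density(relative_ss_ms(train, onsets),
                            window=(-200.0, 300.0),
                            baseline_window=(-200.0, 0.0))
        ep = epoch_trials(trace, onsets, window=(-200.0, 300.0))
        m = trial_correlation_matrix(sdf, ep)
        assert abs(m.lag_ms - 20.0) <= 10.0

    def test_too_few_trials_rejected(self):
        sdf = spike_density([np.array([1.0])] * 5)
        with pytest.raises(ValueError):
            trial_correlation_matrix(
                sdf, epochs_from_matrix(np.zeros((5, 400))))


class TestDiagonalWithCi:
    def test_null_data_exceeds_band_at_nominal_rate(self):
        rng = np.random.default_rng(5)
        exceed = []
        for s in range(30):
            trials = [np.sort(rng.uniform(-100, 300, 25))
                      for _ in range(60)]
            wh = rng.normal(0, 1, (60, 400))
            m = diagonal_with_ci(spike_density(trials),
                                 epochs_from_matrix(wh),
                                 n_perm=300, seed=s)
            diag = m.diagonal
            exceed.append(np.mean((diag < m.ci_low) | (diag > m.ci_high)))
        # 99% band: ~1% exceedance on independent data
        assert 0.001 < np.mean(exceed) < 0.035

    def test_planted_coupling_breaks_out_of_band(self, coupled_session):
        protocol, train, trace = coupled_session
        from tests.conftest import relative_ss_ms

        onsets = protocol.onsets("pre")
        sdf = spike_density(relative_ss_ms(train, onsets),
                            window=(-200.0, 300.0),
                            baseline_window=(-200.0, 0.0))
        ep = epoch_trials(trace, onsets, window=(-200.0, 300.0))
        m = diagonal_with_ci(sdf, ep, n_perm=300, seed=0)
        diag = m.diagonal
        assert ((diag > m.ci_high) | (diag < m.ci_low)).any()

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(-100, 300, 25)) for _ in range(20)]
        with pytest.warns(UserWarning, match="n_perm"):
            diagonal_with_ci(spike_density(trials),
                             epochs_from_matrix(rng.normal(0, 1, (20, 400))),
                             n_perm=50, seed=1)


class TestPoolCells:
    def test_single_cell_identical_to_own_matrix(self):
        rng = np.random.default_rng(7)
        trials = [np.sort(rng.uniform(-100, 300, 25)) for _ in range(30)]
        wh = rng.normal(0, 1, (30, 400))
        sdf = spike_density(trials)
        ep = epochs_from_matrix(wh)
        own = trial_correlation_matrix(sdf, ep)
        pooled = pool_cells([(sdf, ep)])
        assert np.allclose(np.nan_to_num(own.R), np.nan_to_num(pooled.R))

    def test_duplicated_cell_changes_nothing(self):
        rng = np.random.default_rng(8)
        trials = [np.sort(rng.uniform(-100, 300, 25)) for _ in range(30)]
        wh = rng.normal(0, 1, (30, 400))
        sdf = spike_density(trials)
        ep = epochs_from_matrix(wh)
        one = pool_cells([(sdf, ep)])
        two = pool_cells([(sdf, ep), (sdf, ep)])
        assert np.allclose(np.nan_to_num(one.R), np.nan_to_num(two.R),
                           atol=1e-9)

    def test_opposite_sign_coupling_cancels_in_pool(self):
        rng = np.random.default_rng(9)
        trials = [np.sort(rng.uniform(-100, 300, 25)) for _ in range(50)]
        sdf = spike_density(trials)
        t = sdf.times
        drive = sdf.data[:, (t >= 0) & (t < 10)].mean(axis=1)
        wh_pos = rng.normal(0, 0.1, (50, 400)) + drive[:, None]
        wh_neg = rng.normal(0, 0.1, (50, 400)) - drive[:, None]
        pooled = pool_cells([
            (sdf, epochs_from_matrix(wh_pos)),
            (sdf, epochs_from_matrix(wh_neg)),
        ])
        single = pool_cells([(sdf, epochs_from_matrix(wh_pos))])
        i = 10  # spike bin containing 0..10 ms
        assert abs(pooled.R[i]).max() < 0.5 * abs(single.R[i]).max()


class TestMaxCorrShift:
    def test_identical_matrices_zero_shift(self, coupled_session):
        protocol, train, trace = coupled_session
        from tests.conftest import relative_ss_ms

        onsets = protocol.onsets("pre")
        sdf = spike_density(relative_ss_ms(train, onsets),
                            window=(-200.0, 300.0),
                            baseline_window=(-200.0, 0.0))
        ep = epoch_trials(trace, onsets, window=(-200.0, 300.0))
        m = trial_correlation_matrix(sdf, ep)
        assert max_corr_shift(m, m) == (0.0, 0.0, 0.0)

    def test_planted_lag_shift_recovered(self):
        import whiskpc as w
        from tests.conftest import relative_ss_ms

        protocol = w.gen_protocol(100, 0, 100)
        train = w.gen_purkinje_unit(protocol, w.UnitParams(seed=31))
        trace = w.gen_whisker_session(
            protocol, train,
            w.WhiskerParams(seed=32, coupling_gain=0.03, coupling_lag=0.0,
                            post_coupling_lag=20.0, cs_trial_bonus=0.0))

        def matrix(phase):
            onsets = protocol.onsets(phase)
            sdf = spike_density(relative_ss_ms(train, onsets),
                                window=(-200.0, 300.0),
                                baseline_window=(-200.0, 0.0))
            ep = epoch_trials(trace, onsets, window=(-200.0, 300.0))
            return trial_correlation_matrix(sdf, ep)

        _, _, d_lag = max_corr_shift(matrix("pre"), matrix("post"))
        assert abs(d_lag - 20.0) <= 10.0

    def test_sign_convention_positive_lag_means_spikes_lead(self):
        # construct matrices with known maxima directly
        from whiskpc.correlation import CorrelationMatrix

        centers = -95.0 + 10.0 * np.arange(40)
        R_pre = np.zeros((40, 40))
        R_pre[10, 10] = 1.0
        R_post = np.zeros((40, 40))
        R_post[10, 12] = 1.0  # whisker bin later than spike bin: spikes lead
        pre = CorrelationMatrix(R=R_pre, bin_centers=centers, bin_width=10.0,
                                n_trials=50)
        post = CorrelationMatrix(R=R_post, bin_centers=centers,
                                 bin_width=10.0, n_trials=50)
        assert pre.lag_ms == 0.0
        assert post.lag_ms == 20.0
        d_row, d_col, d_lag = max_corr_shift(pre, post)
        assert (d_row, d_col, d_lag) == (0.0, 20.0, 20.0)
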