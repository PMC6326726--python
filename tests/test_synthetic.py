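"""Generator correctness: protocols, spike trains, whisker traces,
population event matrices, and planted-parameter recovery against
independent oracles."""

import numpy as np
import pytest

import whiskpc as w
from whiskpc.synthetic import ss_rate_profile


class TestProtocol:
    def test_study_protocol_spacing_and_counts(self):
        p = w.gen_protocol(100, 80, 100)
        assert p.onset_times.size == 280
        pre = p.onsets("pre")
        ind = p.onsets("induction")
        assert np.allclose(np.diff(pre), 2.0)
        assert np.allclose(np.diff(ind), 0.25)
        # induction block is contiguous
        labels = p.phase_labels
        first, last = np.flatnonzero(labels == "induction")[[0, -1]]
        assert (labels[first:last + 1] == "induction").all()

    def test_no_induction_gives_pre_and_post_only(self):
        p = w.gen_protocol(10, 0, 10)
        assert not (p.phase_labels == "induction").any()
        assert p.onset_times.size == 20

    def test_deterministic_given_arguments(self):
        a = w.gen_protocol(30, 10, 30, seed=1)
        b = w.gen_protocol(30, 10, 30, seed=1)
        assert np.array_equal(a.onset_times, b.onset_times)
        assert np.array_equal(a.phase_labels, b.phase_labels)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            w.gen_protocol(-1, 0, 0)


class TestPurkinjeUnit:
    def test_same_seed_identical_output(self, small_protocol):
        a = w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=3))
        b = w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=3))
        assert np.array_equal(a.ss_times, b.ss_times)
        assert np.array_equal(a.cs_times, b.cs_times)

    def test_no_cs_sources_gives_empty_cs_list(self, small_protocol):
        t = w.gen_purkinje_unit(
            small_protocol,
            w.UnitParams(seed=4, cs_response_prob=0.0, cs_baseline_rate=0.0))
        assert t.cs_times.size == 0

    def test_cs_pause_enforced(self, small_protocol):
        t = w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=5))
        idx = np.searchsorted(t.ss_times, t.cs_times, side="right")
        ok = idx < t.ss_times.size
        gaps = t.ss_times[idx[ok]] - t.cs_times[ok]
        assert (gaps >= 0.010 - 1e-9).all()

    def test_refractory_period_enforced(self, small_protocol):
        t = w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=6))
        assert np.diff(t.ss_times).min() >= 0.003 - 1e-9

    def test_planted_gain_recovered_within_ten_percent(self):
        # oracle: Monte-Carlo average of the planted intensity function,
        # corrected for the measured effect of refractoriness and pauses by
        # comparing response-window vs baseline rates (ratio-of-rates)
        protocol = w.gen_protocol(200, 0, 0)
        params = w.UnitParams(seed=7, ss_response=((0.0, 60.0, 1.5),),
                              cs_response_prob=0.0, cs_baseline_rate=0.0)
        train = w.gen_purkinje_unit(protocol, params)
        onsets = protocol.onset_times
        resp, base = 0, 0
        for o in onsets:
            resp += np.count_nonzero((train.ss_times >= o)
                                     & (train.ss_times < o + 0.06))
            base += np.count_nonzero((train.ss_times >= o - 0.5)
                                     & (train.ss_times < o - 0.2))
        resp_rate = resp / (0.06 * onsets.size)
        base_rate = base / (0.3 * onsets.size)
        assert resp_rate / base_rate == pytest.approx(1.5, rel=0.10)

    def test_rate_profile_marks_post_trials_with_plasticity(self):
        protocol = w.gen_protocol(2, 2, 2, rates=(0.5, 4.0, 0.5))
        params = w.UnitParams(ss_response=((0.0, 50.0, 2.0),),
                              plasticity_gain=1.5)
        pre_t = protocol.onsets("pre")[0] + 0.01
        post_t = protocol.onsets("post")[0] + 0.01
        rate = ss_rate_profile(np.array([pre_t, post_t]), protocol, params)
        assert rate[0] == pytest.approx(65.0 * 2.0)
        assert rate[1] == pytest.approx(65.0 * 3.0)

    def test_plasticity_gain_one_plants_no_pre_post_change(self):
        protocol = w.gen_protocol(150, 0, 150)
        params = w.UnitParams(seed=8, plasticity_gain=1.0)
        train = w.gen_purkinje_unit(protocol, params)

        def mean_count(onsets):
            return np.mean([
                np.count_nonzero((train.ss_times >= o)
                                 & (train.ss_times < o + 0.06))
                for o in onsets
            ])

        pre = mean_count(protocol.onsets("pre"))
        post = mean_count(protocol.onsets("post"))
        # identical distributions: difference within 4 binomial-ish se
        se = np.sqrt(2 * pre / 150)
        assert abs(post - pre) < 4 * se


class TestWhiskerSession:
    def test_noise_free_uncoupled_trials_identical(self, small_protocol):
        train = w.gen_purkinje_unit(small_protocol, w.UnitParams(seed=9))
        params = w.WhiskerParams(noise_sd=0.0, coupling_gain=0.0,
                                 cs_trial_bonus=0.0, seed=1)
        trace = w.gen_whisker_session(small_protocol, train, params)
        from whiskpc.behavior import epoch_trials

        ep = epoch_trials(trace, small_protocol.onset_times, baseline=None)
        assert np.allclose(ep.data, ep.data[0][None, :])
        assert ep.n_trials == small_protocol.onset_times.size

    def test_cs_bonus_is_exact_planted_difference(self, small_protocol):
        train = w.gen_purkinje_unit(
            small_protocol, w.UnitParams(seed=10, cs_response_prob=0.5))
        params = w.WhiskerParams(noise_sd=0.0, coupling_gain=0.0,
                                 cs_trial_bonus=2.0, seed=1)
        trace = w.gen_whisker_session(small_protocol, train, params)
        from whiskpc.behavior import epoch_trials

        ep = epoch_trials(trace, small_protocol.onset_times, baseline=None)
        has_cs = np.array([
            np.any((train.cs_times >= o) & (train.cs_times < o + 0.1))
            for o in small_protocol.onset_times
        ])
        t = ep.times
        at_peak = np.argmin(np.abs(t - params.protraction_peak_time))
        diff = ep.data[has_cs].mean(axis=0) - ep.data[~has_cs].mean(axis=0)
        assert diff[at_peak] == pytest.approx(2.0, abs=1e-9)

    def test_post_gain_recovered_from_protraction_ratio(self):
        protocol = w.gen_protocol(100, 0, 100)
        train = w.gen_purkinje_unit(protocol, w.UnitParams(seed=11))
        # generator-level oracle: without sensor noise the per-trial maxima
        # are exact, so the ratio recovers the planted gain directly
        params = w.WhiskerParams(seed=12, post_gain=1.18, coupling_gain=0.0,
                                 cs_trial_bonus=0.0, noise_sd=0.0)
        trace = w.gen_whisker_session(protocol, train, params)
        from whiskpc.behavior import epoch_trials, trial_kinematics

        ep = epoch_trials(trace, protocol.onset_times,
                          phase_labels=protocol.phase_labels)
        kin = trial_kinematics(ep)
        pre = kin["max_protraction"][ep.phase_labels == "pre"].mean()
        post = kin["max_protraction"][ep.phase_labels == "post"].mean()
        assert post / pre == pytest.approx(1.18, abs=0.005)

    def test_mismatched_duration_rejected(self, small_protocol):
        short = w.SpikeTrain("u", np.array([1.0]), np.empty(0), 10.0)
        with pytest.raises(ValueError, match="cover"):
            w.gen_whisker_session(small_protocol, short, w.WhiskerParams())


class TestPopulationEvents:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            w.PopulationParams(coherent_fraction=1.5)

    def test_rho_zero_pairs_uncorrelated(self):
        # independence must hold conditionally on the stimulus: test pure
        # baseline frames (no stimulus) and the stimulus frames separately
        params = w.PopulationParams(n_dendrites=5, n_frames=100_000,
                                    coherent_fraction=0.0, seed=13)
        stim = np.arange(0, 100_000, 25)
        ev = w.gen_population_events(params, stim)
        E = ev.events.astype(float)
        baseline_cols = np.setdiff1d(np.arange(100_000), stim)
        for cols in (baseline_cols, stim):
            rs = []
            for i in range(5):
                for j in range(i + 1, 5):
                    rs.append(np.corrcoef(E[i, cols], E[j, cols])[0, 1])
            assert np.abs(np.mean(rs)) < 0.02

    def test_full_coherence_full_probability_fires_everyone(self):
        params = w.PopulationParams(n_dendrites=4, n_frames=200,
                                    baseline_event_prob=0.0,
                                    evoked_event_prob=1.0,
                                    coherent_fraction=1.0, seed=14)
        stim = np.arange(10, 200, 20)
        ev = w.gen_population_events(params, stim)
        assert (ev.events[:, stim] == 1).all()
        assert ev.events.sum() == 4 * stim.size

    def test_all_dendrite_coincidence_matches_closed_form(self):
        # closed form from the generative rule, on stimulus frames:
        # shared branch (prob rho): all fire iff the shared evoked draw
        # succeeds or every dendrite fires a baseline event; independent
        # branch: every dendrite fires (evoked OR baseline) independently
        q, b, rho, n = 0.4, 0.04, 0.3, 6
        per = b + (1 - b) * q  # per-dendrite event prob on a stimulus frame
        p_shared = q + (1 - q) * b ** n
        expected = rho * p_shared + (1 - rho) * per ** n
        params = w.PopulationParams(n_dendrites=n, n_frames=400_000,
                                    baseline_event_prob=b,
                                    evoked_event_prob=q,
                                    coherent_fraction=rho, seed=15)
        stim = np.arange(0, 400_000, 4)
        ev = w.gen_population_events(params, stim)
        counts = ev.events[:, stim].sum(axis=0)
        observed = np.mean(counts == n)
        se = np.sqrt(expected * (1 - expected) / stim.size)
        assert abs(observed - expected) < 4 * se

    def test_deterministic_given_seed(self):
        params = w.PopulationParams(n_dendrites=3, n_frames=500,
                                    coherent_fraction=0.2, seed=16)
        stim = np.arange(0, 500, 10)
        a = w.gen_population_events(params, stim)
        b = w.gen_population_events(params, stim)
        assert np.array_equal(a.events, b.events)

    def test_stimulus_frames_bounds_checked(self):
        params = w.PopulationParams(n_frames=100, seed=1)
        with pytest.raises(ValueError):
            w.gen_population_events(params, np.array([150]))


def test_sample_unit_population_class_mixture():
    units = w.sample_unit_population(400, seed=17)
    probs = np.array([u.cs_response_prob for u in units])
    assert 0.20 < np.mean(probs > 0.5) < 0.48  # strong responders ~34%
    assert np.mean(probs < 0.05) < 0.25  # non-responders are a minority
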