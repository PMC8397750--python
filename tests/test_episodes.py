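"""Episode detection (PSTH peaks, FWHM, merging) and gain-stability statistics."""

import numpy as np
import pytest

from ringdrift import episodes as ep
from ringdrift import synthetic
from ringdrift._utils import fit_gaussian


def gaussian_bump(center, sd, height, n=200):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - center) / sd) ** 2)


class TestBinarize:
    def test_threshold_at_three_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, size=(1, 1000, 2))
        sigma = x.std()
        x[0, 5, 0] = 4 * sigma
        x[0, 9, 0] = 2 * sigma
        out = ep.binarize_spikes(x, threshold_sd=3.0)
        # recompute with the post-insertion SD, as the routine sees it
        sd = x.std(axis=(1, 2))[0]
        assert out[0, 5, 0] == (x[0, 5, 0] > 3 * sd)
        assert out[0, 9, 0] == 0

    def test_all_zero_stays_zero(self):
        out = ep.binarize_spikes(np.zeros((2, 10, 3)))
        assert out.sum() == 0

    def test_zero_threshold_is_positivity_indicator(self):
        x = np.array([[[-1.0], [0.0], [2.0]]])
        out = ep.binarize_spikes(x, threshold_sd=0.0)
        np.testing.assert_array_equal(out[0, :, 0], [0, 0, 1])


class TestPsth:
    def test_sum_across_trials(self):
        spikes = np.zeros((1, 3, 2), dtype=int)
        spikes[0, :, 0] = [1, 0, 0]
        spikes[0, :, 1] = [0, 0, 1]
        np.testing.assert_array_equal(ep.compute_psth(spikes, 0), [1, 0, 1])

    def test_subset_additivity(self):
        rng = np.random.default_rng(1)
        spikes = rng.poisson(0.5, size=(1, 50, 10))
        full = ep.compute_psth(spikes, 0)
        parts = ep.compute_psth(spikes, 0, np.arange(4)) + ep.compute_psth(
            spikes, 0, np.arange(4, 10)
        )
        np.testing.assert_array_equal(full, parts)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ep.compute_psth(np.zeros((1, 5, 2)), 0, np.array([], dtype=int))

    def test_smoothing_preserves_mass_and_constants(self):
        const = np.full(100, 4.0)
        np.testing.assert_allclose(ep.smooth_psth(const), const)
        impulse = np.zeros(100)
        impulse[50] = 7.0
        sm = ep.smooth_psth(impulse, bandwidth_s=0.2, dt=0.1)
        assert sm.sum() == pytest.approx(7.0, rel=1e-6)
        assert sm.argmax() == 50

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            ep.smooth_psth(np.ones(10), bandwidth_s=0.0)


class TestDetect:
    def test_flat_psth_no_episodes(self):
        assert ep.detect_episodes(np.full(100, 5.0)) == []

    def test_gaussian_fwhm_duration(self):
        # FWHM of a Gaussian of SD 3 bins is 2.355*3 ~ 7 bins
        x = gaussian_bump(100, 3.0, 10.0)
        eps = ep.detect_episodes(x, prominence=3.0, dt=0.1)
        assert len(eps) == 1
        e = eps[0]
        assert e.peak_bin == 100
        fwhm_bins = e.end_bin - e.start_bin
        assert abs(fwhm_bins - 2.355 * 3) <= 1.6  # floor/ceil adds <=1 bin
        assert e.duration_s == pytest.approx(fwhm_bins * 0.1)

    def test_overlapping_fwhm_windows_merge_into_one(self):
        # two bumps close enough that their half-max windows overlap: the
        # merged episode spans the start of the first to the end of the last
        x = gaussian_bump(95, 4.0, 10.0) + gaussian_bump(105, 4.0, 10.0)
        merged = ep.detect_episodes(x, prominence=1.0, dt=0.1)
        assert len(merged) == 1
        assert merged[0].start_bin < 95 < 105 < merged[0].end_bin
        # well-separated bumps stay distinct
        y = gaussian_bump(60, 3.0, 10.0) + gaussian_bump(140, 3.0, 10.0)
        assert len(ep.detect_episodes(y, prominence=1.0)) == 2

    def test_low_prominence_peaks_ignored(self):
        x = gaussian_bump(100, 3.0, 2.0)  # prominence 2 < threshold 3
        assert ep.detect_episodes(x, prominence=3.0) == []

    def test_planted_episode_recovery_from_spikes(self, small_dataset,
                                                  small_params):
        dff, spikes, gt = small_dataset
        detected = ep.detect_all_episodes(spikes, dt=small_params.dt)
        rec = ep.match_to_planted(
            detected,
            np.array([e.start_bin for e in gt.episodes]),
            np.array([e.end_bin for e in gt.episodes]),
            np.array([e.neuron for e in gt.episodes]),
        )
        assert rec.mean() >= 0.9


class TestRates:
    def test_rate_arithmetic(self):
        spikes = np.zeros((1, 20, 2), dtype=int)
        spikes[0, 5, 0] = 1  # 1 spike in a 0.5 s episode -> 2 Hz
        e = ep.Episode(neuron=0, start_bin=3, end_bin=8, peak_bin=5, dt=0.1)
        table = ep.episode_rates(spikes, [e], np.array([0, 0]), dt=0.1)
        assert table.rates[0, 0] == pytest.approx(2.0)
        assert table.rates[0, 1] == 0.0

    def test_rates_match_loop_oracle(self):
        rng = np.random.default_rng(2)
        spikes = rng.poisson(0.4, size=(3, 40, 12))
        weeks = np.repeat([0, 1, 2], 4)
        eps = [
            ep.Episode(neuron=0, start_bin=5, end_bin=12, peak_bin=8),
            ep.Episode(neuron=1, start_bin=20, end_bin=23, peak_bin=21),
            ep.Episode(neuron=2, start_bin=30, end_bin=40, peak_bin=35),
        ]
        table = ep.episode_rates(spikes, eps, weeks, dt=0.1)
        for i, e in enumerate(eps):
            for k in range(12):
                manual = sum(
                    spikes[e.neuron, t, k] for t in range(e.start_bin, e.end_bin)
                ) / ((e.end_bin - e.start_bin) * 0.1)
                assert table.rates[i, k] == manual
        # week means recompute
        np.testing.assert_allclose(
            table.week_means[:, 0], table.rates[:, :4].mean(axis=1)
        )

    def test_invalid_episode_geometry_rejected(self):
        with pytest.raises(ValueError):
            ep.Episode(neuron=0, start_bin=5, end_bin=5, peak_bin=5)
        with pytest.raises(ValueError):
            ep.Episode(neuron=0, start_bin=5, end_bin=8, peak_bin=9)


def _table_from_week_means(week_means, neurons, n_trials_per_week=4):
    """Build a rate table directly from per-week means (no trial noise)."""
    week_means = np.asarray(week_means, dtype=float)
    n_ep, n_weeks = week_means.shape
    weeks = np.repeat(np.arange(n_weeks), n_trials_per_week)
    rates = np.repeat(week_means, n_trials_per_week, axis=1)
    eps = [
        ep.Episode(neuron=int(n), start_bin=10 * i, end_bin=10 * i + 5,
                   peak_bin=10 * i + 2)
        for i, n in enumerate(neurons)
    ]
    return ep.EpisodeRateTable(
        episodes=eps, rates=rates, week_means=week_means,
        week_labels=weeks, weeks=np.arange(n_weeks), dt=0.1,
    )


class TestStability:
    def test_permuted_rates_give_zero_across_week_cc(self):
        rng = np.random.default_rng(3)
        n_ep = 200
        base = rng.random(n_ep) * 10
        # week 2 = permutation of week 1 across episodes -> expected CC ~ 0
        wm = np.stack([base, base[rng.permutation(n_ep)]], axis=1)
        table = _table_from_week_means(wm, np.arange(n_ep))
        _, across = ep.episode_rate_stability(table)
        assert abs(across) < 0.1

    def test_stable_rates_within_equals_across(self):
        p = synthetic.SyntheticParams(
            n_neurons=40, n_weeks=3, trials_per_week=30, n_gain_clusters=1,
            gain_cluster_profiles=np.ones((1, 3)), seed=4,
        )
        dff, spikes, gt = synthetic.generate_dataset(p)
        detected = ep.detect_all_episodes(spikes, dt=p.dt)
        table = ep.episode_rates(spikes, detected, p.week_labels, dt=p.dt)
        within, across = ep.episode_rate_stability(table)
        assert across == pytest.approx(within, abs=0.1)


class TestPairSimilarity:
    def test_identical_and_opposite_trajectories(self):
        wm = np.array([
            [1.0, 2.0, 3.0, 4.0],   # neuron 0, episode a
            [2.0, 4.0, 6.0, 8.0],   # neuron 0, episode b: same shape -> CC 1
            [1.0, 2.0, 1.0, 2.0],   # neuron 1, episode a
            [2.0, 1.0, 2.0, 1.0],   # neuron 1, episode b: opposite -> CC -1
        ])
        table = _table_from_week_means(wm, [0, 0, 1, 1])
        sim = ep.episode_pair_similarity(table)
        assert sim[0] == pytest.approx(1.0)
        assert sim[1] == pytest.approx(-1.0)

    def test_single_episode_neurons_excluded(self):
        wm = np.array([[1.0, 2.0], [3.0, 1.0], [1.0, 5.0]])
        table = _table_from_week_means(wm, [0, 1, 1])
        sim = ep.episode_pair_similarity(table)
        assert list(sim.index) == [1]

    def test_independent_trajectories_center_at_zero(self):
        rng = np.random.default_rng(5)
        n_neurons = 2000
        wm = rng.random((2 * n_neurons, 6))
        table = _table_from_week_means(
            wm, np.repeat(np.arange(n_neurons), 2))
        sim = ep.episode_pair_similarity(table)
        assert abs(sim.mean()) < 0.02


class TestControls:
    def test_poisson_control_high_rates_approach_one(self):
        # counts >> 1: the shared weekly trajectory dominates Poisson noise
        rng = np.random.default_rng(6)
        wm = np.stack([rng.uniform(200, 400, 6) for _ in range(40)])
        table = _table_from_week_means(wm, np.repeat(np.arange(20), 2))
        sim, (mu, _) = ep.poisson_control(table, seed=0)
        assert mu > 0.9

    def test_poisson_control_flat_trajectory_centers_at_zero(self):
        wm = np.full((400, 6), 3.0)
        table = _table_from_week_means(wm, np.repeat(np.arange(200), 2))
        sim, (mu, _) = ep.poisson_control(table, seed=1)
        assert abs(mu) < 0.05

    def test_week_shuffle_centers_at_zero_and_two_week_case(self):
        rng = np.random.default_rng(7)
        wm = rng.random((1000, 6)) * 5
        table = _table_from_week_means(wm, np.repeat(np.arange(500), 2))
        sim, (mu, sd) = ep.week_shuffle_control(table, seed=2)
        assert abs(mu) < 0.05
        # with two weeks every defined CC is exactly +/-1
        wm2 = rng.random((400, 2)) * 5
        table2 = _table_from_week_means(wm2, np.repeat(np.arange(200), 2))
        sim2, (mu2, _) = ep.week_shuffle_control(table2, seed=3)
        assert set(np.round(sim2.to_numpy(), 9)) <= {-1.0, 1.0}
        assert abs(mu2) < 0.2

    def test_controls_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        wm = rng.random((20, 4))
        table = _table_from_week_means(wm, np.repeat(np.arange(10), 2))
        a1, f1 = ep.poisson_control(table, seed=5)
        a2, f2 = ep.poisson_control(table, seed=5)
        assert a1.equals(a2) and f1 == f2
        b1, g1 = ep.week_shuffle_control(table, seed=5)
        b2, g2 = ep.week_shuffle_control(table, seed=5)
        assert b1.equals(b2) and g1 == g2

    def test_gaussian_fit_matches_mle_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.3, 0.2, 500)
        mu, sd = fit_gaussian(x)
        assert mu == pytest.approx(x.mean(), abs=1e-12)
        assert sd == pytest.approx(np.sqrt(((x - x.mean()) ** 2).mean()),
                                   abs=1e-12)


class TestPsthConsistency:
    def test_across_vs_within_week_durations_similar_on_stable_data(self):
        # episode windows from the all-week PSTH vs per-week PSTHs should
        # have similar durations when timing is stable
        p = synthetic.SyntheticParams(
            n_neurons=30, n_weeks=3, trials_per_week=10, n_gain_clusters=1,
            gain_cluster_profiles=np.ones((1, 3)), seed=12,
        )
        dff, spikes, gt = synthetic.generate_dataset(p)
        all_eps = ep.detect_all_episodes(spikes, dt=p.dt)
        all_durs = np.array([e.duration_s for e in all_eps])
        week_durs = []
        for w in range(3):
            trials = np.flatnonzero(p.week_labels == w)
            for e in ep.detect_all_episodes(spikes, trial_subset=trials,
                                            dt=p.dt):
                week_durs.append(e.duration_s)
        diff_bins = abs(np.median(all_durs) - np.median(week_durs)) / p.dt
        assert diff_bins <= 2.0
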