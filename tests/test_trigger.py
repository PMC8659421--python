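"""Spike-triggered ensemble, STA, SVD separation and temporal collapse."""

import numpy as np
import pytest

import stnmflab as sl
from stnmflab.circuits import SpikeTrain
from stnmflab.stimulus import StimulusMovie
from stnmflab.trigger import (
    EmptyEnsembleError,
    build_ensemble,
    collapse_temporal,
    compute_sta,
    quadratic_lag_profile,
    svd_separate,
)


def _movie(n=50, grid=(2, 2), seed=0):
    rng = np.random.default_rng(seed)
    frames = (rng.integers(0, 2, (n, *grid)) - 0.5).astype(np.float32)
    return StimulusMovie(frames, 10.0)


class TestBuildEnsemble:
    def test_single_spike_segment_is_preceding_frames(self):
        movie = _movie(30)
        train = SpikeTrain("c", np.array([205.0]), duration=300.0)  # frame 20
        ens = build_ensemble(movie, train, n_lags=3)
        np.testing.assert_array_equal(ens.segments[0], movie.frames[[20, 19, 18]])

    def test_early_spike_dropped_and_counted(self):
        movie = _movie(30)
        train = SpikeTrain("c", np.array([15.0, 205.0]), duration=300.0)  # frames 1, 20
        ens = build_ensemble(movie, train, n_lags=3)
        assert ens.n_spikes == 1 and ens.n_dropped == 1

    def test_first_dimension_is_spike_count_minus_drops(self):
        movie = _movie(40)
        times = np.array([5.0, 25.0, 155.0, 255.0, 355.0])
        ens = build_ensemble(movie, SpikeTrain("c", times, 400.0), n_lags=3)
        # only the frame-0 spike lacks 3 frames of history
        assert ens.segments.shape[0] == 5 - ens.n_dropped == 4

    def test_empty_train_raises(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble(_movie(), SpikeTrain("c", np.array([]), 100.0), n_lags=3)

    def test_time_shift_shifts_segments_consistently(self):
        movie = _movie(60)
        base = np.array([205.0, 305.0, 405.0])
        e1 = build_ensemble(movie, SpikeTrain("c", base, 600.0), n_lags=4)
        e2 = build_ensemble(movie, SpikeTrain("c", base + 100.0, 600.0), n_lags=4)
        # +10 frames: segment i of e2 equals segment of frames shifted by 10
        np.testing.assert_array_equal(
            e2.segments[0], movie.frames[[30, 29, 28, 27]]
        )
        np.testing.assert_array_equal(e1.segments[0], movie.frames[[20, 19, 18, 17]])


class TestSTA:
    def test_single_spike_sta_is_segment(self):
        movie = _movie(30)
        ens = build_ensemble(movie, SpikeTrain("c", np.array([205.0]), 300.0), n_lags=3)
        np.testing.assert_allclose(compute_sta(ens), ens.segments[0])

    def test_lnp_sta_recovers_true_filter(self):
        spec = sl.preset_network("fig1")
        cell = spec.cells["rgc1"]
        movie = sl.generate_white_noise(30_000, (8, 8), seed=1)
        train = sl.lnp_spikes(cell, movie, seed=2)
        ens = build_ensemble(movie, train, n_lags=15)
        assert ens.n_spikes >= 5000
        sta = compute_sta(ens)
        k_true = cell.filter.full()
        cos = np.dot(sta.ravel(), k_true.ravel()) / (
            np.linalg.norm(sta) * np.linalg.norm(k_true)
        )
        assert cos >= 0.9

    def test_stimulus_independent_train_gives_null_sta(self):
        movie = _movie(5000, (2, 2), seed=3)
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(200, 49_999, 2000))
        ens = build_ensemble(movie, SpikeTrain("c", times, 50_000.0), n_lags=3)
        sta = compute_sta(ens)
        assert np.max(np.abs(sta)) < 4 * 0.5 / np.sqrt(ens.n_spikes)


class TestSVDSeparate:
    def test_exact_rank1_recovery(self):
        temporal = np.array([-0.2, -1.0, 0.4, 0.3])
        spatial = np.array([[0.0, 1.0], [2.0, 0.5]])
        sta = temporal[:, None, None] * spatial[None]
        t, s, info = svd_separate(sta)
        cos_t = np.dot(t, temporal) / np.linalg.norm(temporal)
        assert cos_t == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.outer(t, s.ravel()), sta.reshape(4, -1), atol=1e-10)
        assert info["separability"] == pytest.approx(1.0)

    def test_rank1_plus_noise_high_separability(self):
        rng = np.random.default_rng(0)
        temporal = np.array([-1.0, -0.5, 0.3, 0.2])
        spatial = rng.uniform(0.5, 1.5, (3, 3))
        sta = temporal[:, None, None] * spatial[None] + 0.02 * rng.standard_normal((4, 3, 3))
        _, _, info = svd_separate(sta)
        assert info["separability"] > 0.9

    def test_dominant_lobe_sign_convention(self):
        sta = np.ones((3, 2, 2)) * np.array([0.2, 1.0, 0.1])[:, None, None]
        t, s, _ = svd_separate(sta)
        assert t[np.argmax(np.abs(t))] < 0

    def test_zero_sta_flagged_degenerate(self):
        t, s, info = svd_separate(np.zeros((5, 2, 2)))
        assert info["degenerate"]

    def test_noise_level_sta_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        n = 10_000
        sta = rng.normal(0, 0.5 / np.sqrt(n), (15, 8, 8))
        _, _, info = svd_separate(sta, noise_scale=0.5 / np.sqrt(n))
        assert info["degenerate"]


class TestCollapse:
    def test_delta_weights_select_spike_frame(self):
        movie = _movie(30)
        train = SpikeTrain("c", np.array([205.0, 251.0]), 300.0)
        ens = build_ensemble(movie, train, n_lags=3)
        w = np.array([1.0, 0.0, 0.0])
        eff = collapse_temporal(ens, w)
        np.testing.assert_allclose(eff.S[0], movie.frames[20].ravel())
        np.testing.assert_allclose(eff.S[1], movie.frames[25].ravel())

    def test_zero_weights_give_zero_images(self):
        movie = _movie(30)
        ens = build_ensemble(movie, SpikeTrain("c", np.array([205.0]), 300.0), n_lags=3)
        assert np.all(collapse_temporal(ens, np.zeros(3)).S == 0)

    def test_toy_hand_computed_sum(self):
        # 2 spikes, 2 lags, 1x2 pixels; brute-force weighted sum oracle
        frames = np.array(
            [[[0.5, -0.5]], [[-0.5, -0.5]], [[0.5, 0.5]], [[-0.5, 0.5]]], dtype=np.float32
        )
        movie = StimulusMovie(frames, 10.0)
        train = SpikeTrain("c", np.array([15.0, 35.0]), 40.0)  # frames 1, 3
        ens = build_ensemble(movie, train, n_lags=2)
        w = np.array([2.0, -1.0])
        eff = collapse_temporal(ens, w)
        expected = np.array(
            [
                w[0] * frames[1, 0] + w[1] * frames[0, 0],
                w[0] * frames[3, 0] + w[1] * frames[2, 0],
            ]
        )
        np.testing.assert_allclose(eff.S, expected)

    def test_collapse_is_linear_in_weights(self):
        movie = _movie(40, (3, 3), seed=5)
        train = SpikeTrain("c", np.sort(np.array([105.0, 215.0, 334.0])), 400.0)
        ens = build_ensemble(movie, train, n_lags=4)
        rng = np.random.default_rng(6)
        w1, w2 = rng.standard_normal(4), rng.standard_normal(4)
        lhs = collapse_temporal(ens, 2.0 * w1 - 3.0 * w2).S
        rhs = 2.0 * collapse_temporal(ens, w1).S - 3.0 * collapse_temporal(ens, w2).S
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_sta_consistency_with_collapsed_mean(self):
        # sum_tau w(tau)*STA(tau) == column mean of S
        movie = _movie(60, (2, 3), seed=7)
        times = np.sort(np.random.default_rng(8).uniform(150, 599, 20))
        ens = build_ensemble(movie, SpikeTrain("c", times, 600.0), n_lags=5)
        w = np.random.default_rng(9).standard_normal(5)
        lhs = np.tensordot(w, compute_sta(ens), axes=([0], [0])).ravel()
        rhs = collapse_temporal(ens, w).S.mean(axis=0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_length_mismatch_rejected(self):
        movie = _movie(30)
        ens = build_ensemble(movie, SpikeTrain("c", np.array([205.0]), 300.0), n_lags=3)
        with pytest.raises(ValueError):
            collapse_temporal(ens, np.ones(4))


class TestQuadraticProfile:
    def test_recovers_filter_shape_for_polarity_balanced_spikes(self):
        # spikes triggered by +-filter events: STA cancels, the quadratic
        # profile must still localize the filter's temporal support
        kt = sl.biphasic_temporal_filter(10)
        rng = np.random.default_rng(0)
        movie = _movie(20_000, (4, 4), seed=1)
        spatial = np.zeros((4, 4))
        spatial[1:3, 1:3] = 1.0
        proj = np.tensordot(movie.frames, spatial, axes=([1, 2], [0, 1]))
        g = np.convolve(proj, kt, mode="full")[9:20_000]
        # fire on both strong positive and strong negative projections
        hot = np.flatnonzero(np.abs(g) > 2.0 * g.std()) + 9
        times = hot * 10.0 + 5.0
        ens = build_ensemble(movie, SpikeTrain("c", times, 200_000.0), n_lags=10)
        sta = compute_sta(ens)
        assert np.max(np.abs(sta)) < 5 * 0.5 / np.sqrt(ens.n_spikes)  # cancelled
        prof = quadratic_lag_profile(ens)
        cos = abs(np.dot(prof, kt))
        assert cos > 0.8
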