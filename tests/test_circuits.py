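"""LNP/LIF cells, synapses and network simulation."""

import numpy as np
import pytest

import stnmflab as sl
from stnmflab.circuits import (
    LIFParams,
    LNPCell,
    NetworkSpec,
    SpatioTemporalFilter,
    SynapseSpec,
    alpha_current,
    lnp_generator_signal,
    lnp_spikes,
    simulate_lif,
    simulate_network,
)
from stnmflab.stimulus import StimulusMovie


def _cell(spatial, temporal, gain=1.0, polarity="OFF"):
    return LNPCell("c", SpatioTemporalFilter(spatial, temporal, polarity=polarity), gain=gain)


class TestGeneratorSignal:
    def test_zero_movie_gives_zero_generator(self):
        movie = StimulusMovie(np.zeros((20, 2, 2)), 10.0)
        cell = _cell(np.ones((2, 2)), np.array([-1.0, 0.5]))
        g = lnp_generator_signal(cell, movie)
        assert np.isnan(g[0]) and np.allclose(g[1:], 0.0)

    def test_impulse_kernel_reproduces_pixel_trace(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(-0.5, 0.5, (30, 2, 2)).astype(np.float32)
        movie = StimulusMovie(frames, 10.0)
        spatial = np.zeros((2, 2))
        spatial[1, 0] = 1.0
        cell = _cell(spatial, np.array([-1.0]))
        g = lnp_generator_signal(cell, movie)
        np.testing.assert_allclose(g, -frames[:, 1, 0], rtol=1e-6)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(-0.5, 0.5, (3, 2, 2)).astype(np.float32)
        movie = StimulusMovie(frames, 10.0)
        spatial = np.array([[1.0, 0.5], [0.25, 2.0]])
        temporal = np.array([-1.0, -0.3])
        cell = _cell(spatial, temporal)
        g = lnp_generator_signal(cell, movie)
        # brute-force double sum at t = 2: sum_tau sum_px spatial*temporal(tau)*s(t-tau)
        expected = sum(
            temporal[tau] * np.sum(spatial * frames[2 - tau]) for tau in range(2)
        )
        assert np.isnan(g[0])
        np.testing.assert_allclose(g[2], expected, rtol=1e-6)

    def test_grid_mismatch_raises(self):
        movie = StimulusMovie(np.zeros((5, 3, 3)), 10.0)
        cell = _cell(np.ones((2, 2)), np.array([-1.0]))
        with pytest.raises(ValueError, match="grid"):
            lnp_generator_signal(cell, movie)


class TestLNPSpikes:
    def test_nonpositive_generator_gives_empty_train(self):
        # an OFF cell under an all-dark... all-bright stimulus never fires
        movie = StimulusMovie(np.full((50, 2, 2), 0.5, dtype=np.float32), 10.0)
        cell = _cell(np.ones((2, 2)), np.array([-1.0]))
        train = lnp_spikes(cell, movie, seed=0)
        assert train.n_spikes == 0

    def test_constant_rate_matches_poisson_mean(self):
        # all-dark stimulus + OFF cell: generator = +1 per frame, rate = gain
        movie = StimulusMovie(np.full((10_000, 1, 1), -0.5, dtype=np.float32), 10.0)
        cell = _cell(np.ones((1, 1)) * 2.0, np.array([-1.0]), gain=0.4)
        lam = 0.4  # 2.0 * 1.0 * 0.5 * gain
        train = lnp_spikes(cell, movie, seed=1)
        mean_count = train.n_spikes / 10_000
        assert abs(mean_count - lam) < 3 * np.sqrt(lam / 10_000)

    def test_fano_factor_near_one(self):
        movie = StimulusMovie(np.full((10_000, 1, 1), -0.5, dtype=np.float32), 10.0)
        cell = _cell(np.ones((1, 1)) * 2.0, np.array([-1.0]), gain=0.4)
        train = lnp_spikes(cell, movie, seed=2)
        counts = np.bincount((train.times / 10.0).astype(int), minlength=10_000)
        fano = counts.var() / counts.mean()
        assert 0.8 < fano < 1.2

    def test_seed_determinism(self):
        movie = StimulusMovie(np.full((100, 1, 1), -0.5, dtype=np.float32), 10.0)
        cell = _cell(np.ones((1, 1)), np.array([-1.0]), gain=0.5)
        a = lnp_spikes(cell, movie, seed=5)
        b = lnp_spikes(cell, movie, seed=5)
        np.testing.assert_array_equal(a.times, b.times)


class TestAlphaCurrent:
    def test_onset_equals_amplitude(self):
        assert alpha_current(5.0, 5.0, A=1.0, tau0=10.0) == pytest.approx(1.0)

    def test_one_time_constant_decay(self):
        assert alpha_current(15.0, 5.0, A=1.0, tau0=10.0) == pytest.approx(np.exp(-1))

    def test_causality(self):
        assert alpha_current(4.999, 5.0) == 0.0


class TestLIF:
    def test_rest_is_fixed_point(self):
        p = LIFParams(noise_sd=0.0)
        train, V = simulate_lif(p, np.zeros(500), dt=1.0)
        assert train.n_spikes == 0
        assert np.allclose(V, p.V_rest)

    def test_subthreshold_steady_state(self):
        p = LIFParams(V_thresh=5.0, noise_sd=0.0)
        train, V = simulate_lif(p, np.full(2000, 2.0), dt=0.5)
        assert train.n_spikes == 0
        assert V[-1] == pytest.approx(2.0, abs=1e-3)  # V_rest + R*I

    @pytest.mark.parametrize("current", [1.5, 2.0, 4.0])
    def test_isi_matches_closed_form(self, current):
        p = LIFParams(V_thresh=1.0, V_rest=0.0, V_reset=0.0, noise_sd=0.0, refractory=0.0)
        dt = 0.5
        train, _ = simulate_lif(p, np.full(20_000, current), dt=dt)
        isi = np.diff(train.times)
        expected = p.tau_m * np.log(current / (current - 1.0))
        assert abs(isi.mean() - expected) <= 2 * dt

    def test_nonfinite_current_reports_step(self):
        I = np.zeros(10)
        I[7] = np.inf
        with pytest.raises(FloatingPointError, match="step 7"):
            simulate_lif(LIFParams(), I)


class TestNetwork:
    def test_zero_weights_silence_downstream(self):
        spec = sl.preset_network("fig1")
        for syn in spec.synapses:
            syn.weight = 0.0
        spec.cells["lgn"].noise_sd = 0.0
        movie = sl.generate_white_noise(500, (8, 8), seed=0)
        trains = simulate_network(spec, movie, seed=1)
        assert trains["lgn"].n_spikes == 0

    def test_single_strong_input_causality(self):
        # every LIF spike must follow an afferent spike within 3*tau0
        spec = sl.preset_network("fig1")
        movie = sl.generate_white_noise(3000, (8, 8), seed=2)
        trains = simulate_network(spec, movie, seed=3)
        pre = np.sort(np.concatenate([trains[c].times for c in spec.lnp_ids]))
        for t in trains["lgn"].times:
            i = np.searchsorted(pre, t)
            assert i > 0 and t - pre[i - 1] <= 30.0

    def test_fig1_preset_runs_end_to_end(self):
        spec = sl.preset_network("fig1")
        assert len(spec.lnp_ids) == 4 and spec.lif_ids == ["lgn"]
        movie = sl.generate_white_noise(3000, (8, 8), seed=4)
        trains = simulate_network(spec, movie, seed=5)
        assert trains["lgn"].n_spikes > 0

    def test_bit_reproducible_under_seed(self):
        spec = sl.preset_network("fig3")
        movie = sl.generate_white_noise(2000, (8, 8), seed=6)
        a = simulate_network(spec, movie, seed=7)
        b = simulate_network(spec, movie, seed=7)
        for cid in a:
            np.testing.assert_array_equal(a[cid].times, b[cid].times)

    def test_polarity_sign_symmetry(self):
        # flipping all polarities and negating the stimulus preserves
        # layer-1 spike trains exactly (same seeds, mirrored cascade)
        spec = sl.preset_network("fig5")
        movie = sl.generate_white_noise(2000, (8, 8), seed=8)
        flipped = StimulusMovie(-movie.frames, movie.frame_duration)
        counts = {}
        for tag, mov in (("orig", movie), ("flip", flipped)):
            spec2 = sl.preset_network("fig5")
            if tag == "flip":
                for cid in spec2.lnp_ids:
                    f = spec2.cells[cid].filter
                    spec2.cells[cid].filter = SpatioTemporalFilter(
                        -f.spatial, f.temporal, polarity="ON" if f.polarity == "OFF" else "OFF"
                    )
            counts[tag] = {
                cid: lnp_spikes(spec2.cells[cid], mov, seed=11).times for cid in spec2.lnp_ids
            }
        for cid in counts["orig"]:
            np.testing.assert_array_equal(counts["orig"][cid], counts["flip"][cid])

    def test_cyclic_feedforward_rejected(self):
        kt = sl.biphasic_temporal_filter(3)
        cell = LNPCell("a", SpatioTemporalFilter(np.ones((2, 2)), kt))
        with pytest.raises(ValueError, match="cycle"):
            NetworkSpec(
                layers=[["a"], ["b", "c"]],
                cells={"a": cell, "b": LIFParams(id="b"), "c": LIFParams(id="c")},
                synapses=[
                    SynapseSpec("a", "b"),
                    SynapseSpec("b", "c"),
                    SynapseSpec("c", "b"),
                ],
            )


class TestPresets:
    def test_fig3_topology(self):
        spec = sl.preset_network("fig3")
        assert [len(layer) for layer in spec.layers] == [6, 2, 1]
        lgn1_in = {s.pre_id for s in spec.synapses if s.post_id == "lgn1"}
        lgn2_in = {s.pre_id for s in spec.synapses if s.post_id == "lgn2"}
        assert lgn1_in == {"rgc1", "rgc2", "rgc3", "rgc4"}
        assert lgn2_in == {"rgc3", "rgc4", "rgc5", "rgc6"}

    def test_s5_recurrent_edge(self):
        spec = sl.preset_network("s5")
        rec = [s for s in spec.synapses if s.kind == "recurrent"]
        assert len(rec) == 1
        assert (rec[0].pre_id, rec[0].post_id, rec[0].weight) == ("v1", "lgn2", 0.1)

    def test_s6_feedback_edge(self):
        spec = sl.preset_network("s6")
        fb = [s for s in spec.synapses if s.kind == "feedback"]
        assert len(fb) == 1
        assert (fb[0].pre_id, fb[0].post_id, fb[0].weight) == ("v1", "lgn1", 0.1)

    def test_fig7_polarity_paired_cells(self):
        spec = sl.preset_network("fig7")
        assert len(spec.lnp_ids) == 8
        for i in range(4):
            a = spec.cells[f"rgc{i + 1}"].filter
            b = spec.cells[f"rgc{i + 5}"].filter
            np.testing.assert_array_equal(a.spatial, -b.spatial)
            assert a.polarity != b.polarity

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="fig1"):
            sl.preset_network("fig99")

    def test_spike_train_io_round_trip(self, tmp_path):
        spec = sl.preset_network("fig1")
        movie = sl.generate_white_noise(500, (8, 8), seed=9)
        trains = simulate_network(spec, movie, seed=10)
        path = str(tmp_path / "spikes.txt")
        sl.save_spike_trains(trains, path)
        back = sl.load_spike_trains(path)
        assert set(back) == set(trains)
        for cid in trains:
            np.testing.assert_allclose(back[cid].times, trains[cid].times)
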