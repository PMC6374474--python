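"""Generator correctness: geometry, determinism, truth/render consistency."""

import numpy as np
import pandas as pd
import pytest

import calwave as cw
from calwave.synthetic import wave_activation_time


class TestMakeTissue:
    def test_single_cell_fills_disk(self):
        t = cw.make_tissue(cw.TissueSpec(image_size_px=(64, 64), n_cells=1, seed=0))
        assert t.n_cells == 1
        assert set(np.unique(t.labels)) == {0, 1}
        # the labelled region is the centred disk
        yy, xx = np.mgrid[0:64, 0:64]
        disk = np.hypot(yy - 31.5, xx - 31.5) <= 30
        assert np.array_equal(t.labels > 0, disk)

    def test_requested_cell_count(self):
        t = cw.make_tissue(cw.TissueSpec(image_size_px=(512, 512), n_cells=100, seed=1))
        assert t.n_cells == 100
        assert np.array_equal(t.cell_ids, np.arange(1, 101))

    def test_deterministic_for_fixed_seed(self):
        spec = cw.TissueSpec(image_size_px=(128, 128), n_cells=50, seed=3)
        a = cw.make_tissue(spec)
        b = cw.make_tissue(spec)
        assert np.array_equal(a.labels, b.labels)

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError, match="do not fit"):
            cw.make_tissue(cw.TissueSpec(image_size_px=(32, 32), n_cells=500))

    def test_cells_partition_foreground(self, small_tissue):
        # no overlaps by construction; every foreground pixel has one label
        assert small_tissue.labels[small_tissue.foreground].min() >= 1
        assert small_tissue.labels[~small_tissue.foreground].max() == 0


class TestSimulateOscillations:
    def test_pulses_appear_at_programmed_times(self, small_tissue):
        p = cw.OscillationParams(duration_s=5000.0)
        centers = np.array([900.0, 2400.0, 4100.0])
        movie, truth = cw.simulate_oscillations(small_tissue, p, pulse_centers=centers)
        trace = cw.extract_global_trace(movie, small_tissue)
        for c in centers:
            i = np.argmin(np.abs(trace.times_s - c))
            lo, hi = max(0, i - 10), i + 11
            assert abs(trace.times_s[lo:hi][np.argmax(trace.values[lo:hi])] - c) <= p.frame_interval_s
        assert truth.events["onset_s"].tolist() == centers.tolist()

    def test_zero_amplitude_gives_constant_baseline(self, small_tissue):
        p = cw.OscillationParams(peak_fold_change=0.0, duration_s=600.0)
        movie, _ = cw.simulate_oscillations(small_tissue, p, pulse_centers=[300.0])
        fg = small_tissue.foreground
        assert np.allclose(movie.data[:, fg], p.baseline_level)

    def test_pulse_count_matches_expected_rate(self, small_tissue):
        p = cw.OscillationParams(duration_s=7200.0)
        _, truth = cw.simulate_oscillations(small_tissue, p, seed=5)
        expected = p.duration_s / p.mean_interpeak_s
        assert abs(len(truth.events) - expected) <= 3  # ~3 sigma of the count

    def test_too_short_movie_warns_with_empty_truth(self, small_tissue):
        p = cw.OscillationParams(duration_s=1500.0, frame_interval_s=5.0)
        with pytest.warns(UserWarning, match="too short"):
            movie, truth = cw.simulate_oscillations(
                small_tissue, p, pulse_centers=np.array([])
            )
        assert truth.events.empty
        assert movie.n_frames >= 2

    def test_pulses_scale_all_tissue_pixels_proportionally(self, small_tissue):
        p = cw.OscillationParams(duration_s=3000.0)
        movie, _ = cw.simulate_oscillations(small_tissue, p, pulse_centers=[1500.0])
        fg = small_tissue.foreground
        frame = movie.data[:, fg]
        # every tissue pixel carries the same time profile
        assert np.allclose(frame, frame[:, [0]])


class TestSimulateSpikes:
    def test_zero_rate_constant_movie(self, small_tissue):
        p = cw.SpikeParams(rate_per_cell_per_s=0.0)
        movie, truth = cw.simulate_spikes(small_tissue, p, 60.0, 1.0, seed=1)
        assert truth.events.empty
        assert np.allclose(movie.data, movie.data[0])

    def test_scheduled_event_confined_to_its_cell(self, small_tissue):
        p = cw.SpikeParams()
        movie, truth = cw.simulate_spikes(
            small_tissue, p, 30.0, 1.0, scheduled=[(5, 10.0, 3.0)]
        )
        base = movie.data[0]
        elevated = movie.data > base + 1e-6
        times = movie.times_s
        inside = (times >= 10.0) & (times < 13.0)
        cell5 = small_tissue.labels == 5
        assert elevated[inside][:, cell5].all()
        assert not elevated[:, ~cell5].any()
        assert not elevated[~inside].any()

    def test_duration_mixture_recovered_in_truth(self, small_tissue):
        p = cw.SpikeParams()
        _, truth = cw.simulate_spikes(
            small_tissue, p, 4000.0, 1.0, seed=9, n_events=2000
        )
        d = truth.events["duration_s"].to_numpy()
        fractions = [
            np.mean((d >= lo) & (d < hi))
            for lo, hi in ((1, 5), (5, 10), (10, np.inf))
        ]
        for frac, w in zip(fractions, (0.70, 0.17, 0.13)):
            ci = 1.96 * np.sqrt(w * (1 - w) / len(d))
            assert abs(frac - w) <= ci + 0.01

    def test_events_never_overlap_within_a_cell(self, small_tissue):
        _, truth = cw.simulate_spikes(
            small_tissue, cw.SpikeParams(), 2000.0, 1.0, seed=4, n_events=600
        )
        for _, grp in truth.events.groupby("cell_id"):
            g = grp.sort_values("onset_s")
            ends = (g["onset_s"] + g["duration_s"]).to_numpy()[:-1]
            starts = g["onset_s"].to_numpy()[1:]
            assert (starts > ends).all()


class TestSimulateWave:
    def test_activation_times_follow_piecewise_law(self, crescent_study):
        # independent oracle: recompute distance -> time from first principles
        tissue = crescent_study["tissue"]
        p = crescent_study["params"]
        truth = crescent_study["truth"].events
        cents = tissue.centroids_um()
        oy, ox = p.origin_px[0] * 0.5, p.origin_px[1] * 0.5
        d = np.array([np.hypot(*(np.array(cents[c]) - (oy, ox))) for c in truth["cell_id"]])
        t_total = 2 * d.max() / (p.v_fast_um_s + p.v_slow_um_s)
        t_sw = t_total / 2
        r_sw = p.v_fast_um_s * t_sw
        expected = np.where(
            d <= r_sw, d / p.v_fast_um_s, t_sw + (d - r_sw) / p.v_slow_um_s
        ) + p.stim_time_s
        assert np.allclose(truth["onset_s"].to_numpy(), expected, atol=1e-9)

    def test_constant_speed_activation_linear_in_distance(self, small_tissue):
        p = cw.WaveParams(
            origin_px=(48, 48), v_fast_um_s=1.0, v_slow_um_s=1.0,
            crescent_onset_s=None, crescent_duration_s=None, decay_time_s=60.0,
        )
        _, truth = cw.simulate_wave(small_tissue, p, 80.0, 1.0)
        cents = small_tissue.centroids_um()
        d = np.array([np.hypot(*(np.array(cents[c]) - (24.0, 24.0)))
                      for c in truth.events["cell_id"]])
        assert np.allclose(truth.events["onset_s"], p.stim_time_s + d / 1.0)

    def test_known_distance_and_speed(self):
        p = cw.WaveParams(v_fast_um_s=2.0, v_slow_um_s=2.0)
        t = wave_activation_time(p, np.array([20.0]), 100.0)
        assert t[0] == pytest.approx(10.0)

    def test_origin_outside_tissue_raises(self, small_tissue):
        p = cw.WaveParams(origin_px=(0, 0))
        with pytest.raises(ValueError, match="origin"):
            cw.simulate_wave(small_tissue, p, 50.0, 1.0)


class TestAddNoise:
    def test_zero_sd_identity(self, small_tissue):
        movie, _ = cw.simulate_spikes(small_tissue, cw.SpikeParams(), 30.0, 1.0, seed=1)
        out = cw.add_noise(movie, 0.0, seed=2)
        assert np.array_equal(out.data, movie.data)

    def test_same_seed_same_noise(self, small_tissue):
        movie, _ = cw.simulate_spikes(small_tissue, cw.SpikeParams(), 30.0, 1.0, seed=1)
        a = cw.add_noise(movie, 25.0, seed=5)
        b = cw.add_noise(movie, 25.0, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_residual_sd_matches_request(self):
        flat = cw.Movie(np.full((4, 256, 256), 1000.0), 1.0, 0.5)
        noisy = cw.add_noise(flat, 40.0, seed=1)
        resid = noisy.data - 1000.0
        assert abs(resid.std() - 40.0) / 40.0 < 0.05

    def test_truth_events_recoverable_after_rendering(self, small_tissue):
        # noise off: thresholding the rendered movie recovers each spike's
        # exact frame support
        movie, truth = cw.simulate_spikes(
            small_tissue, cw.SpikeParams(), 120.0, 1.0, seed=11, n_events=10
        )
        lab = small_tissue.labels
        dt = movie.frame_interval_s
        n_frames = movie.n_frames
        for cid, grp in truth.events.groupby("cell_id"):
            cell = lab == cid
            elevated = np.flatnonzero(
                (movie.data[:, cell] > 1000.0 + 1e-3).any(axis=1)
            )
            expected = sorted(
                k
                for _, ev in grp.iterrows()
                for k in range(n_frames)
                if min(ev.onset_s + ev.duration_s, (k + 1) * dt) - max(ev.onset_s, k * dt)
                > 1e-9
            )
            assert elevated.tolist() == expected


def test_ground_truth_roundtrip(tmp_path, small_tissue):
    _, truth = cw.simulate_spikes(
        small_tissue, cw.SpikeParams(), 60.0, 1.0, seed=2, n_events=5
    )
    truth.to_csv(tmp_path / "truth.csv")
    truth.params_json(tmp_path / "params.json")
    back = pd.read_csv(tmp_path / "truth.csv")
    assert len(back) == 5
    assert list(back.columns) == ["kind", "cell_id", "onset_s", "duration_s", "amplitude"]
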