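"""Kymograph extraction, segmentation, classification and summaries."""

import numpy as np
import pytest

from axonquant import kymo, simulate
from axonquant.kymo import AxonPath, Track


def make_track(positions, dt=0.2, start_frame=0):
    positions = np.asarray(positions, dtype=float)
    return Track(0, np.arange(start_frame, start_frame + len(positions)), positions, dt)


class TestExtractKymograph:
    def test_all_zero_movie(self):
        movie = np.zeros((5, 9, 50), dtype=np.float32)
        path = AxonPath([[0, 4], [49, 4]], width=3)
        ky = kymo.extract_kymograph(movie, path, 0.1, 0.2)
        assert ky.data.shape[0] == 5
        assert np.all(ky.data == 0)

    def test_static_bright_pixel_gives_constant_column(self):
        movie = np.zeros((6, 9, 50), dtype=np.float32)
        movie[:, 4, 20] = 100.0
        path = AxonPath([[0, 4], [49, 4]], width=3)
        ky = kymo.extract_kymograph(movie, path, 0.1, 0.2)
        assert (ky.data.argmax(axis=1) == 20).all()

    def test_moving_vesicle_line_slope(self):
        cfg = simulate.TransportSimConfig(
            n_vesicles=1, noise_model="none", fraction_static=0.0,
            speed_antero=(1.0, 0.0), state_switch_rates={}, initial_state="antero", seed=3,
        )
        movie, truth = simulate.simulate_axonal_movie(cfg)
        path = AxonPath([[0, cfg.image_half_height], [999, cfg.image_half_height]])
        ky = kymo.extract_kymograph(movie, path, cfg.pixel_size, cfg.frame_interval)
        peak_bins = ky.data.argmax(axis=1).astype(float)
        truth_px = truth.positions.sort_values("frame")["position_um"].to_numpy() / cfg.pixel_size
        assert np.max(np.abs(peak_bins - truth_px)) <= 1.0

    def test_path_outside_image_rejected(self):
        movie = np.zeros((2, 9, 50), dtype=np.float32)
        with pytest.raises(ValueError, match="bounds"):
            kymo.extract_kymograph(movie, AxonPath([[0, 4], [80, 4]]), 0.1, 0.2)


class TestDetectAndLink:
    def test_empty_movie_no_tracks(self):
        movie = np.full((20, 9, 50), 10.0, dtype=np.float32)
        path = AxonPath([[0, 4], [49, 4]])
        assert kymo.detect_and_link(movie, path, 0.1, 0.2) == []

    def test_single_vesicle_subpixel_accuracy(self):
        cfg = simulate.TransportSimConfig(
            n_vesicles=1, fraction_static=0.0, speed_antero=(1.0, 0.0),
            state_switch_rates={}, amplitude=200.0, initial_state="antero", seed=5,
        )
        movie, truth = simulate.simulate_axonal_movie(cfg)
        path = AxonPath([[0, cfg.image_half_height], [999, cfg.image_half_height]])
        tracks = kymo.detect_and_link(movie, path, cfg.pixel_size, cfg.frame_interval)
        assert len(tracks) == 1
        tr = tracks[0]
        truth_pos = (
            truth.positions.set_index("frame").loc[tr.frames, "position_um"].to_numpy()
        )
        # per-frame position error below one pixel (0.1 um); the centroid
        # window clips at the image border, so judge the interior only
        interior = (truth_pos > 1.0) & (truth_pos < 99.0)
        assert np.max(np.abs(tr.positions_um - truth_pos)[interior]) < 0.1

    def test_two_separated_vesicles_no_identity_swap(self):
        cfg = simulate.TransportSimConfig(
            n_vesicles=2, fraction_static=0.0, speed_antero=(0.5, 0.0),
            speed_retro=(0.5, 0.0), state_switch_rates={}, amplitude=200.0,
            noise_model="none", seed=1,
        )
        movie, truth = simulate.simulate_axonal_movie(cfg)
        P = truth.positions.pivot(index="frame", columns="vesicle", values="position_um")
        assert np.min(np.abs(P[0] - P[1])) > 2.0  # the pair never comes close
        path = AxonPath([[0, cfg.image_half_height], [999, cfg.image_half_height]])
        tracks = kymo.detect_and_link(movie, path, cfg.pixel_size, cfg.frame_interval)
        assert len(tracks) == 2
        for tr in tracks:
            err = [
                np.mean(np.abs(P[v].to_numpy()[tr.frames] - tr.positions_um)) for v in (0, 1)
            ]
            assert min(err) < 0.1  # each track follows exactly one vesicle


class TestSegmentTrack:
    def test_antero_pause_antero_hand_computed(self):
        pos = np.concatenate([
            0.2 * np.arange(10),            # frames 0..9 moving +1.0 um/s
            np.full(10, 1.8),               # frames 10..19 paused
            1.8 + 0.2 * np.arange(1, 11),   # frames 20..29 moving +1.0 um/s
        ])
        tr = kymo.segment_track(make_track(pos))
        dirs = [s.direction for s in tr.segments]
        assert dirs == ["anterograde", "pause", "anterograde"]
        antero = [s for s in tr.segments if s.direction == "anterograde"]
        assert antero[0].mean_speed_um_s == pytest.approx(1.0, abs=1e-9)
        assert antero[1].mean_speed_um_s == pytest.approx(1.0, abs=1e-9)

    def test_uniform_retrograde(self):
        tr = kymo.segment_track(make_track(20.0 - 0.1 * np.arange(30)))
        assert [s.direction for s in tr.segments] == ["retrograde"]
        assert tr.segments[0].mean_speed_um_s == pytest.approx(0.5, abs=1e-9)
        assert tr.segments[0].displacement_um < 0

    def test_zero_displacement_single_pause(self):
        tr = kymo.segment_track(make_track(np.full(30, 5.0)))
        assert [s.direction for s in tr.segments] == ["pause"]

    def test_too_short_track_flagged(self):
        tr = kymo.segment_track(make_track([1.0]))
        assert tr.too_short and tr.segments == []

    def test_pause_segments_respect_speed_invariant(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(0, 0.005, 100))  # localization jitter only
        tr = kymo.segment_track(make_track(pos))
        for seg in tr.segments:
            if seg.direction == "pause":
                assert seg.mean_speed_um_s < 0.1


class TestClassifyVesicle:
    def test_no_movement_is_static(self):
        tr = kymo.segment_track(make_track(np.full(50, 3.0)))
        assert kymo.classify_vesicle(tr) == "static"

    def test_dominant_direction_wins(self):
        # net +12 um with a brief 1 um retrograde excursion
        pos = np.concatenate([
            0.24 * np.arange(50),           # +11.76 um anterograde
            12.0 - 0.2 * np.arange(1, 6),   # -1 um retrograde
            np.full(10, 11.0) + 0.24 * np.arange(10),
        ])
        tr = kymo.segment_track(make_track(pos))
        assert kymo.classify_vesicle(tr) == "anterograde"

    def test_exact_tie_broken_to_later_direction(self):
        # +2 um, then -2 um: equal cumulative displacement, retro occurs later
        pos = np.concatenate([0.2 * np.arange(11), 2.0 - 0.2 * np.arange(1, 11)])
        tr = kymo.segment_track(make_track(pos))
        assert kymo.classify_vesicle(tr) == "retrograde"

    def test_unsegmented_track_rejected(self):
        with pytest.raises(ValueError, match="segmented"):
            kymo.classify_vesicle(make_track(np.zeros(10)))


class TestSummarizeAxon:
    @staticmethod
    def _tracks(n_antero, n_retro, n_static):
        tracks = []
        for _ in range(n_antero):
            tracks.append(make_track(0.2 * np.arange(40)))
        for _ in range(n_retro):
            tracks.append(make_track(20 - 0.2 * np.arange(40)))
        for _ in range(n_static):
            tracks.append(make_track(np.full(40, 7.0)))
        return tracks

    def test_hand_counted_net_flux(self):
        summ = kymo.summarize_axon(self._tracks(3, 1, 2), 100.0, 60.0)
        assert (summ.n_anterograde, summ.n_retrograde, summ.n_static) == (3, 1, 2)
        assert summ.net_flux_per_100um_min == pytest.approx(2.0)

    def test_symmetric_traffic_zero_flux_and_directionality(self):
        summ = kymo.summarize_axon(self._tracks(2, 2, 0), 100.0, 60.0)
        assert summ.net_flux_per_100um_min == 0.0
        assert summ.directionality == pytest.approx(0.0, abs=1e-12)

    def test_no_movement_directionality_missing(self):
        summ = kymo.summarize_axon(self._tracks(0, 0, 3), 100.0, 60.0)
        assert summ.directionality is None

    def test_flux_and_flow_antisymmetric_under_reflection(self):
        # mirror x -> L - x swaps antero and retro and flips signed metrics
        cfg = simulate.TransportSimConfig(n_vesicles=12, seed=9)
        _, truth = simulate.simulate_axonal_movie(cfg)
        tracks = kymo.tracks_from_truth(truth.positions, cfg.frame_interval)
        mirrored = [
            Track(t.vesicle_id, t.frames, cfg.axon_length - t.positions_um, t.frame_interval)
            for t in tracks
        ]
        s1 = kymo.summarize_axon(tracks, duration_s=cfg.duration)
        s2 = kymo.summarize_axon(mirrored, duration_s=cfg.duration)
        assert s2.net_flux_per_100um_min == pytest.approx(-s1.net_flux_per_100um_min)
        assert s2.linear_flow_um_per_vesicle_min == pytest.approx(
            -s1.linear_flow_um_per_vesicle_min
        )
        assert (s2.n_anterograde, s2.n_retrograde) == (s1.n_retrograde, s1.n_anterograde)
        assert s2.n_static == s1.n_static

    def test_truth_fed_tracks_reproduce_truth_exactly(self):
        cfg = simulate.TransportSimConfig(n_vesicles=15, seed=6)
        _, truth = simulate.simulate_axonal_movie(cfg)
        tracks = kymo.tracks_from_truth(truth.positions, cfg.frame_interval)
        summ = kymo.summarize_axon(tracks, duration_s=cfg.duration)
        classes = truth.vesicles["class"].value_counts()
        assert summ.n_anterograde == classes.get("anterograde", 0)
        assert summ.n_retrograde == classes.get("retrograde", 0)
        assert summ.n_static == classes.get("static", 0)
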