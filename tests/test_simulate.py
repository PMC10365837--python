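"""Generator contracts: rendering, truth completeness, determinism."""

import numpy as np
import pandas as pd
import pytest

from axonquant import em, simulate
from axonquant.simulate import TransportSimConfig


class TestTransportSim:
    def test_frame_count_from_interval_and_duration(self):
        cfg = TransportSimConfig(n_vesicles=1, frame_interval=0.2, duration=60.0)
        movie, _ = simulate.simulate_axonal_movie(cfg)
        assert movie.shape[0] == 300

    def test_non_integer_frame_count_rejected(self):
        with pytest.raises(ValueError, match="integer frame count"):
            TransportSimConfig(frame_interval=0.2, duration=60.1)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TransportSimConfig(speed_antero=(-1.0, 0.1))

    def test_zero_vesicles_pure_background(self):
        cfg = TransportSimConfig(n_vesicles=0, noise_model="none", background=100.0)
        movie, truth = simulate.simulate_axonal_movie(cfg)
        assert np.allclose(movie, 100.0)
        assert truth.positions.empty and truth.vesicles.empty

    def test_pure_anterograde_closed_form_kinematics(self):
        cfg = TransportSimConfig(
            n_vesicles=1, noise_model="none", fraction_static=0.0,
            speed_antero=(1.0, 0.0), state_switch_rates={}, initial_state="antero", seed=3,
        )
        _, truth = simulate.simulate_axonal_movie(cfg)
        pos = truth.positions.sort_values("frame")["position_um"].to_numpy()
        steps = np.diff(pos)
        interior = (pos[:-1] > 1) & (pos[:-1] < 99)  # away from the reflecting edges
        assert np.allclose(steps[interior], 0.2, atol=1e-9)

    def test_seed_determinism_bit_identical(self):
        a = simulate.simulate_axonal_movie(TransportSimConfig(n_vesicles=5, seed=11))
        b = simulate.simulate_axonal_movie(TransportSimConfig(n_vesicles=5, seed=11))
        assert np.array_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1].positions, b[1].positions)

    def test_kinematic_consistency_of_truth(self):
        # integrating truth velocities over frames reproduces truth positions
        cfg = TransportSimConfig(n_vesicles=10, seed=4)
        _, truth = simulate.simulate_axonal_movie(cfg)
        for _, grp in truth.positions.groupby("vesicle"):
            grp = grp.sort_values("frame")
            pos = grp["position_um"].to_numpy()
            vel = grp["velocity_um_s"].to_numpy()[:-1]
            integrated = pos[0] + np.cumsum(vel * cfg.frame_interval)
            assert np.max(np.abs(integrated - pos[1:])) < 1e-9

    def test_truth_completeness_one_entry_per_vesicle(self):
        cfg = TransportSimConfig(n_vesicles=7, seed=2)
        _, truth = simulate.simulate_axonal_movie(cfg)
        assert sorted(truth.vesicles["vesicle"]) == list(range(7))
        assert truth.positions.groupby("vesicle").size().eq(cfg.n_frames).all()


class TestPhluorinSim:
    def test_zero_post_rate_gives_no_post_events(self):
        _, _, truth = simulate.simulate_phluorin_movie(
            n_fields=1, rois_per_field=3, post_rate=0.0, seed=0
        )
        assert truth.events.query("epoch == 'post'").empty

    def test_poisson_event_count_mean(self):
        # 2 events/min over 1 min and 10 ROIs -> 20 expected truth events
        counts = [
            len(simulate.simulate_phluorin_movie(
                n_fields=1, rois_per_field=10, pre_rate=2.0, post_rate=0.0, seed=s
            )[2].events)
            for s in range(30)
        ]
        mean = np.mean(counts)
        assert abs(mean - 20) < 3 * np.sqrt(20 / 30)

    def test_rendered_amplitude_matches_truth(self):
        fields, rois, truth = simulate.simulate_phluorin_movie(
            n_fields=1, rois_per_field=2, pre_rate=3.0, post_rate=0.0,
            event_amplitude=50.0, baseline=100.0, noise_sd=0.0, seed=1,
        )
        movie = fields[0]["pre"]
        ev = truth.events.iloc[0]
        r = rois[rois.roi == ev.roi].iloc[0]
        trace = movie[:, int(r.y), int(r.x)]
        assert trace[ev.onset_frame] - 100.0 == pytest.approx(50.0, abs=1e-3)

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError, match="decay_tau"):
            simulate.simulate_phluorin_movie(decay_tau=-1.0)


class TestEMSim:
    def test_one_hot_zone_mix_distances(self):
        geom, _ = simulate.simulate_em_synapse(
            n_vesicles=10, zone_mix=(1.0, 0.0, 0.0, 0.0), seed=1
        )
        d = em.zone_distances(geom)
        assert (d < 40.0).all()

    def test_zone3_only_distances_in_band(self):
        geom, _ = simulate.simulate_em_synapse(
            n_vesicles=8, zone_mix=(0.0, 0.0, 1.0, 0.0), seed=2
        )
        d = em.zone_distances(geom)
        assert ((d >= 80.0) & (d < 120.0)).all()

    def test_zero_vesicles(self):
        geom, truth = simulate.simulate_em_synapse(n_vesicles=0, seed=0)
        assert geom.centroids.shape == (0, 2)
        assert truth.zones.empty

    def test_hard_core_no_interpenetration(self):
        geom, _ = simulate.simulate_em_synapse(n_vesicles=25, vesicle_radius=20.0, seed=3)
        from scipy.spatial.distance import pdist

        assert pdist(geom.centroids).min() >= 40.0

    def test_bad_zone_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.simulate_em_synapse(zone_mix=(0.5, 0.2, 0.1, 0.1))


class TestPunctaSim:
    def test_full_colocalization_duplicates_centers(self):
        _, _, truth = simulate.simulate_two_channel_puncta(
            n_puncta=40, coloc_fraction=1.0, jitter_px=0.0, seed=0
        )
        a = truth.puncta.query("channel == 'A'").sort_values("pair_id")
        b = truth.puncta.query("channel == 'B'").sort_values("pair_id")
        assert (a["pair_id"] >= 0).all()
        assert np.allclose(a[["y", "x"]].to_numpy(), b[["y", "x"]].to_numpy())

    def test_half_colocalization_truth_counts(self):
        _, _, truth = simulate.simulate_two_channel_puncta(
            n_puncta=100, coloc_fraction=0.5, seed=1
        )
        assert truth.puncta.query("channel == 'A' and colocalized").shape[0] == 50

    def test_overcrowding_warns(self):
        with pytest.warns(UserWarning, match="overlap"):
            simulate.simulate_two_channel_puncta(n_puncta=400, field_size=64, seed=0)


class TestEPSCSim:
    def test_noise_free_equal_peaks_at_unit_ppr(self):
        sweeps, _ = simulate.simulate_epsc_pair(
            isi=250.0, a1=100.0, ppr_true=1.0, noise_sd=0.0, n_sweeps=1
        )
        y = sweeps[0].current_pA
        t = sweeps[0].time_ms
        p1 = np.abs(y[(t >= 50) & (t < 200)]).max()
        p2 = np.abs(y[t >= 300]).max()
        assert p1 == pytest.approx(100.0, rel=1e-9)
        assert p2 == pytest.approx(100.0, rel=1e-6)

    def test_second_peak_scales_with_ppr(self):
        sweeps, _ = simulate.simulate_epsc_pair(
            isi=250.0, a1=100.0, ppr_true=1.5, noise_sd=0.0, n_sweeps=1
        )
        y, t = sweeps[0].current_pA, sweeps[0].time_ms
        assert np.abs(y[t >= 300]).max() == pytest.approx(150.0, rel=1e-6)

    def test_sweep_count_contract(self):
        sweeps, truth = simulate.simulate_epsc_pair(n_sweeps=20, seed=1)
        assert len(sweeps) == 20 and len(truth.sweeps) == 20

    def test_short_isi_flagged_as_overlapping(self):
        sweeps, truth = simulate.simulate_epsc_pair(isi=5.0, n_sweeps=1)
        assert sweeps[0].overlap_flag and truth.sweeps["overlap"].all()
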