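"""EM morphometry: areas, densities, zone partition and assignment."""

import numpy as np
import pytest

from axonquant import em, simulate
from axonquant.em import SynapseGeometry


def square_geometry(side=1000.0, centroids=(), az_edge=True):
    outline = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    az = np.array([[0.0, 0.0], [side, 0.0]])
    return SynapseGeometry(outline, az, np.asarray(centroids, dtype=float).reshape(-1, 2))


class TestTerminalArea:
    @pytest.mark.parametrize(
        "vertices,expected",
        [
            ([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], 1.0),  # 1 um square
            ([[0, 0], [1000, 0], [0, 2000]], 1.0),  # right triangle legs 1000, 2000
        ],
    )
    def test_closed_form_areas(self, vertices, expected):
        assert em.terminal_area(np.array(vertices, dtype=float)) == pytest.approx(expected)

    def test_orientation_invariance(self):
        v = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        assert em.terminal_area(v) == em.terminal_area(v[::-1])

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1000, 1000], [1000, 0], [0, 1000]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            em.terminal_area(bowtie)


class TestDensities:
    def test_vesicle_density_arithmetic(self):
        assert em.vesicle_density(10, 1.0) == 10.0
        assert em.vesicle_density(0, 2.0) == 0.0
        assert em.vesicle_density(10, 2.0) == em.vesicle_density(10, 1.0) / 2

    def test_synapse_density_per_100um2(self):
        assert em.synapse_density(5, 250.0) == pytest.approx(2.0)
        assert em.synapse_density(0, 100.0) == 0.0
        assert em.synapse_density(10, 500.0) == em.synapse_density(5, 250.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            em.vesicle_density(1, 0.0)
        with pytest.raises(ValueError):
            em.synapse_density(1, 0.0)


class TestPartitionZones:
    def test_rectangle_full_edge_zone_areas(self):
        # terminal much deeper than the bands: each clipped band is
        # approximately edge length x 40 nm (caps add a small rounded margin)
        geom = square_geometry()
        part = em.partition_zones(geom)
        for k, area in enumerate(part.areas_um2):
            expected = 1000.0 * 40.0 / 1e6
            assert area >= expected
            assert area == pytest.approx(expected, rel=0.06)

    def test_band_boundaries_at_40_80_120(self):
        geom = square_geometry()
        part = em.partition_zones(geom, band_width_nm=40.0, n_bands=3)
        from shapely.geometry import Point

        for k, (d_in, d_out) in enumerate([(20, 50), (60, 90), (100, 130)]):
            assert part.polygons[k].covers(Point(500.0, d_in))
            assert not part.polygons[k].covers(Point(500.0, d_out))

    def test_shallow_terminal_clips_distal_zone(self):
        outline = np.array([[0, 0], [1000, 0], [1000, 100], [0, 100]], dtype=float)
        geom = SynapseGeometry(outline, [[0, 0], [1000, 0]], np.empty((0, 2)))
        part = em.partition_zones(geom)
        assert part.areas_um2[2] < part.areas_um2[0]
        assert part.areas_um2[2] >= 0.0

    def test_degenerate_active_zone_rejected(self):
        geom = square_geometry()
        geom.active_zone = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            em.partition_zones(geom)


class TestAssignVesicles:
    def test_half_open_band_membership(self):
        geom = square_geometry(
            centroids=[[500, 0], [500, 100], [500, 150], [500, 40]]
        )
        part = em.partition_zones(geom)
        res = em.assign_vesicles(geom, part)
        # distance 0 -> zone 1; 100 -> zone 3; 150 -> beyond; 40 -> zone 2
        assert list(res["labels"]) == [0, 2, -1, 1]
        assert list(res["zone_counts"]) == [1, 1, 1]
        assert res["n_beyond"] == 1

    def test_centroid_outside_terminal_excluded(self):
        geom = square_geometry(centroids=[[500, 50], [500, -50]])
        res = em.assign_vesicles(geom, em.partition_zones(geom))
        assert res["n_excluded"] == 1
        assert res["zone_counts"].sum() == 1

    def test_conservation_of_counts(self):
        geom, _ = simulate.simulate_em_synapse(n_vesicles=25, seed=4)
        res = em.assign_vesicles(geom, em.partition_zones(geom))
        total = res["zone_counts"].sum() + res["n_beyond"] + res["n_excluded"]
        assert total == geom.centroids.shape[0]

    def test_rigid_motion_invariance(self):
        geom, _ = simulate.simulate_em_synapse(n_vesicles=20, seed=5)
        res0 = em.assign_vesicles(geom, em.partition_zones(geom))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -456.0])
        moved = SynapseGeometry(
            geom.terminal @ R.T + shift,
            geom.active_zone @ R.T + shift,
            geom.centroids @ R.T + shift,
            geom.vesicle_radius,
        )
        res1 = em.assign_vesicles(moved, em.partition_zones(moved))
        assert np.array_equal(res0["labels"], res1["labels"])


class TestGeometryOracle:
    def test_recovered_zone_counts_equal_truth(self):
        geom, truth = simulate.simulate_em_synapse(
            n_vesicles=30, zone_mix=(0.4, 0.3, 0.2, 0.1), seed=6
        )
        res = em.assign_vesicles(geom, em.partition_zones(geom))
        for k in range(3):
            assert res["zone_counts"][k] == (truth.zones["zone"] == k).sum()
        assert res["n_beyond"] == (truth.zones["zone"] == -1).sum()

    def test_blob_helper_finds_rendered_vesicles(self):
        # synthetic micrograph: dark-field gaussian blobs at known centers
        rng = np.random.default_rng(0)
        centers = np.array([[20.0, 20.0], [40.0, 60.0], [70.0, 30.0]])
        yy, xx = np.mgrid[:96, :96]
        img = np.zeros((96, 96))
        for cy, cx in centers:
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
        found = em.detect_vesicle_blobs(img, vesicle_radius_px=2.8)
        assert len(found) == 3
        for c in centers:
            assert np.min(np.linalg.norm(found - c, axis=1)) < 1.5

    def test_monte_carlo_area_agreement(self):
        # scaled-down check; the full 1e6-sample comparison runs in acceptance
        geom, _ = simulate.simulate_em_synapse(seed=7)
        part = em.partition_zones(geom)
        mc = em.monte_carlo_zone_areas(
            geom, n_samples=200_000, rng=np.random.default_rng(1)
        )
        assert np.all(np.abs(mc / part.areas_um2 - 1) < 0.03)
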