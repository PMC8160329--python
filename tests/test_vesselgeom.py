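"""Movie diameter tracking and 3-D vascular morphometry."""

import numpy as np
import pytest
from scipy import ndimage

from oxyflow import synth, vesselgeom
from oxyflow.vesselgeom import Volume


def _cylinder_truth(shape=(80, 80, 80), voxel=1.0, radius=2.5):
    ext = shape[0] * voxel
    mid = ext / 2
    return synth.NetworkTruth(
        volume_shape=shape, voxel_size=voxel,
        segments=[((0.0, mid, mid), (ext, mid, mid), radius)],
        target_density=None)


class TestFrameDiameter:
    def test_constant_tube(self):
        t = synth.MovieTruth(n_frames=8, diameter_timecourse=5.0,
                             noise_sd=0.01, seed=3)
        movie, _, _ = synth.make_movie(t)
        d = vesselgeom.frame_diameter_trace(movie)
        assert np.all(np.isfinite(d.values))
        assert np.allclose(d.values, 5.0, atol=0.2)

    def test_step_recovered_at_correct_frame(self):
        steps = np.concatenate([np.full(10, 5.0), np.full(10, 6.0)])
        t = synth.MovieTruth(n_frames=20, diameter_timecourse=steps,
                             noise_sd=0.01, seed=4)
        movie, _, _ = synth.make_movie(t)
        d = vesselgeom.frame_diameter_trace(movie)
        assert np.allclose(d.values[:10], 5.0, atol=0.25)
        assert np.allclose(d.values[10:], 6.0, atol=0.25)

    def test_rotation_invariance(self):
        ext = 128 * 0.4
        diag = synth.MovieTruth(
            n_frames=4, diameter_timecourse=5.0, noise_sd=0.0, seed=5,
            vessel_path=np.array([[0.0, 0.0], [ext, ext]]),
            roi_centres=((10.0, 40.0),))
        straight = synth.MovieTruth(n_frames=4, diameter_timecourse=5.0,
                                    noise_sd=0.0, seed=5)
        d_diag = vesselgeom.frame_diameter_trace(synth.make_movie(diag)[0])
        d_str = vesselgeom.frame_diameter_trace(synth.make_movie(straight)[0])
        assert np.nanmean(d_diag.values) == pytest.approx(
            np.nanmean(d_str.values), rel=0.05)

    def test_gain_invariance(self):
        t = synth.MovieTruth(n_frames=3, diameter_timecourse=5.0, seed=6)
        movie, _, _ = synth.make_movie(t)
        scaled = vesselgeom.Movie(
            channels={k: 4.0 * v for k, v in movie.channels.items()},
            frame_rate=movie.frame_rate, px=movie.px)
        d0 = vesselgeom.frame_diameter_trace(movie)
        d1 = vesselgeom.frame_diameter_trace(scaled)
        assert np.allclose(d0.values, d1.values, rtol=1e-6)


class TestSkeleton:
    def test_cylinder_radii(self):
        vol, _ = synth.make_volume(_cylinder_truth())
        sk = vesselgeom.skeletonize_volume(vol)
        # distance-map radius is exact to about half a voxel (diagonal slack)
        assert np.all(np.abs(sk.radii - 2.5) <= 0.75)

    def test_straight_tube_length_matches_endpoints(self):
        vol, _ = synth.make_volume(_cylinder_truth())
        sk = vesselgeom.skeletonize_volume(vol)
        pts = sk.points * sk.voxel_size
        span = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        length = vesselgeom._skeleton_length_um(sk)
        assert abs(length - span) <= np.sqrt(3) * sk.voxel_size

    def test_crossing_tubes_have_branch_point(self):
        t = synth.NetworkTruth(
            volume_shape=(60, 60, 60), voxel_size=1.0,
            segments=[((0.0, 30.0, 30.0), (60.0, 30.0, 30.0), 2.5),
                      ((30.0, 0.0, 30.0), (30.0, 60.0, 30.0), 2.5)],
            target_density=None)
        vol, _ = synth.make_volume(t)
        sk = vesselgeom.skeletonize_volume(vol)
        assert sk.branch_points.size > 0

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            vesselgeom.skeletonize_volume(Volume(data=np.zeros((20, 20, 20)),
                                                 voxel_size=1.0))


class TestDensity:
    def test_single_tube_density(self):
        vol, stats = synth.make_volume(_cylinder_truth(shape=(100, 100, 100)))
        sk = vesselgeom.skeletonize_volume(vol)
        dens = vesselgeom.capillary_density(sk, units="um/um3")
        assert dens == pytest.approx(1e-4, rel=0.06)

    def test_recovery_across_seeds(self, small_network):
        vol, stats = small_network
        sk = vesselgeom.skeletonize_volume(vol)
        dens = vesselgeom.capillary_density(sk)
        assert dens == pytest.approx(stats["density_m_per_mm3"], rel=0.05)

    def test_monotone_in_segments(self):
        base = [((0.0, 20.0, 20.0), (60.0, 20.0, 20.0), 2.5)]
        more = base + [((0.0, 40.0, 40.0), (60.0, 40.0, 40.0), 2.5)]
        d = []
        for segs in (base, more):
            t = synth.NetworkTruth(volume_shape=(60, 60, 60), voxel_size=1.0,
                                   segments=segs, target_density=None)
            vol, _ = synth.make_volume(t)
            sk = vesselgeom.skeletonize_volume(vol)
            d.append(vesselgeom.capillary_density(sk))
        assert d[1] > d[0]

    def test_zero_volume_raises(self, small_network):
        sk = vesselgeom.skeletonize_volume(small_network[0])
        with pytest.raises(ValueError):
            vesselgeom.capillary_density(sk, volume_um3=0.0)


class TestDepthProfile:
    def test_uniform_network_flat(self, small_network):
        sk = vesselgeom.skeletonize_volume(small_network[0])
        prof = vesselgeom.diameter_depth_profile(sk, bin_um=40.0)
        means = prof["mean_diameter"].dropna()
        assert means.std() < 0.15 * means.mean()

    def test_deep_large_vessel_peaks_at_depth(self):
        t = synth.NetworkTruth(
            volume_shape=(80, 80, 80), voxel_size=1.0,
            segments=[((10.0, 40.0, 0.0), (10.0, 40.0, 80.0), 2.0),
                      ((60.0, 40.0, 0.0), (60.0, 40.0, 80.0), 6.0)],
            target_density=None)
        vol, _ = synth.make_volume(t)
        sk = vesselgeom.skeletonize_volume(vol)
        prof = vesselgeom.diameter_depth_profile(sk, bin_um=20.0)
        means = prof["mean_diameter"].to_numpy()
        assert np.nanargmax(means) == 3  # 60-80 μm bin
        assert means[3] > means[0] + 4.0

    def test_bins_partition_points(self, small_network):
        sk = vesselgeom.skeletonize_volume(small_network[0])
        prof = vesselgeom.diameter_depth_profile(sk, bin_um=10.0)
        assert prof["n"].sum() == sk.points.shape[0]

    def test_empty_bin_is_nan(self):
        t = synth.NetworkTruth(
            volume_shape=(80, 80, 80), voxel_size=1.0,
            segments=[((70.0, 40.0, 0.0), (70.0, 40.0, 80.0), 3.0)],
            target_density=None)
        vol, _ = synth.make_volume(t)
        sk = vesselgeom.skeletonize_volume(vol)
        prof = vesselgeom.diameter_depth_profile(sk, bin_um=10.0)
        assert np.isnan(prof["mean_diameter"].iloc[0])
        assert prof["n"].iloc[0] == 0


class TestDistanceDistribution:
    def test_analytic_cylinder_field(self):
        vol, _ = synth.make_volume(_cylinder_truth(shape=(60, 60, 60)))
        mask = vesselgeom._binarize_volume(vol)
        edt = ndimage.distance_transform_edt(~mask, sampling=1.0)
        yy, xx = np.mgrid[0:60, 0:60]
        analytic = np.maximum(np.hypot(yy - 30.0, xx - 30.0) - 2.5, 0.0)
        err = np.abs(edt[30] - analytic)
        assert err.max() <= 1.0  # voxel-centre convention

    def test_zero_on_foreground(self, small_network):
        vol, _ = small_network
        mask = vesselgeom._binarize_volume(vol)
        edt = ndimage.distance_transform_edt(~mask, sampling=vol.voxel_size)
        assert np.all(edt[mask] == 0)

    def test_centiles_non_decreasing(self, small_network):
        dd = vesselgeom.tissue_distance_distribution(
            small_network[0], substack_um=80.0, n_substacks=3, seed=2)
        vals = [dd.centiles[r] for r in sorted(dd.centiles)]
        assert np.all(np.diff(vals) >= 0)

    def test_denser_network_smaller_95th(self):
        c95 = {}
        for dens in (0.45, 1.8):
            vals = []
            for seed in range(3):
                t = synth.NetworkTruth(volume_shape=(80, 80, 80), voxel_size=2.0,
                                       target_density=dens, seed=seed)
                vol, _ = synth.make_volume(t)
                dd = vesselgeom.tissue_distance_distribution(
                    vol, substack_um=60.0, n_substacks=2, seed=seed)
                vals.append(dd.centiles[95])
            c95[dens] = np.mean(vals)
        assert c95[1.8] < c95[0.45]

    def test_all_vessel_volume_distances_zero(self):
        vol = Volume(data=np.ones((40, 40, 40)), voxel_size=2.0)
        dd = vesselgeom.tissue_distance_distribution(vol, substack_um=30.0,
                                                     n_substacks=2, seed=0)
        assert all(v == 0.0 for v in dd.centiles.values())

    def test_substack_too_large_raises(self, small_network):
        with pytest.raises(ValueError):
            vesselgeom.tissue_distance_distribution(
                small_network[0], substack_um=500.0, n_substacks=1, seed=0)

    def test_cannot_place_raises(self, small_network):
        with pytest.raises(ValueError):
            vesselgeom.tissue_distance_distribution(
                small_network[0], substack_um=150.0, n_substacks=4, seed=0)
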