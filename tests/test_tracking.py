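"""Enhancement, watershed segmentation, sphericity, drift, linking, statistics."""

import numpy as np
import pytest

from cardioquant.pipeline4d import track_movie
from cardioquant.synthetic import MovieSimConfig, generate_movie, simulate_tracks
from cardioquant.synthetic.movie import tracks_from_truth
from cardioquant.tracking import (
    CellObservation,
    HeartSummary,
    Movie4D,
    Track,
    apply_drift_correction,
    compare_groups,
    compute_sphericity,
    enhance_particles,
    estimate_drift,
    filter_by_volume,
    fit_msd_slope,
    link_tracks,
    mean_msd_curve,
    measure_frame,
    segment_cells,
    summarize_heart,
    track_msd,
    track_speed,
)


def ball_mask(radius, pad=4, spacing=(1.0, 1.0, 1.0)):
    sp = np.asarray(spacing)
    n = (np.ceil(radius / sp).astype(int)) + pad
    zz, yy, xx = np.mgrid[-n[0] : n[0] + 1, -n[1] : n[1] + 1, -n[2] : n[2] + 1]
    return (zz * sp[0]) ** 2 + (yy * sp[1]) ** 2 + (xx * sp[2]) ** 2 <= radius**2


def obs(t, z, y, x, vol=500.0, area=300.0, psi=0.8, label=1):
    return CellObservation(t, (z, y, x), vol, area, psi, label)


class TestSphericity:
    def test_ball_close_to_one(self):
        res = compute_sphericity(ball_mask(8.0), (1, 1, 1))
        assert res.sphericity == pytest.approx(1.0, abs=0.05)
        assert not res.degenerate

    def test_cube_matches_closed_form(self):
        m = np.zeros((20, 20, 20), bool)
        m[2:18, 2:18, 2:18] = True
        res = compute_sphericity(m, (1, 1, 1))
        assert res.sphericity == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.05)
        assert res.volume_um3 == 16**3

    def test_elongation_strictly_lowers_sphericity(self):
        zz, yy, xx = np.mgrid[-20:21, -8:9, -8:9]
        ell = (zz / 18) ** 2 + (yy / 6) ** 2 + (xx / 6) ** 2 <= 1
        psi_ell = compute_sphericity(ell, (1, 1, 1)).sphericity
        psi_ball = compute_sphericity(ball_mask(8.0), (1, 1, 1)).sphericity
        assert psi_ell < psi_ball

    def test_anisotropic_voxels_handled(self):
        res = compute_sphericity(ball_mask(8.0, spacing=(2, 1, 1)), (2, 1, 1))
        assert res.sphericity == pytest.approx(1.0, abs=0.06)

    def test_sphericity_never_exceeds_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = rng.random((9, 9, 9)) > 0.6
            if m.sum() == 0:
                continue
            res = compute_sphericity(m, (1, 1, 1))
            assert res.sphericity <= 1.02

    def test_single_voxel_flagged_degenerate(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        res = compute_sphericity(m, (1, 1, 1))
        assert res.degenerate
        assert 0 < res.sphericity <= 1.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_sphericity(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestEnhancement:
    def _movie(self, data, voxel=(1, 1, 1)):
        return Movie4D(data[None], voxel, 2.0)

    def test_constant_frame_maps_to_zero(self):
        out = enhance_particles(self._movie(np.full((16, 16, 16), 7.0)), 4.0)
        assert np.abs(out.intensity).max() < 1e-4

    def test_response_peaks_at_spot_center(self):
        from scipy import ndimage as ndi

        img = np.zeros((24, 24, 24))
        img[12, 13, 10] = 1.0
        img = ndi.gaussian_filter(img, 2.0)
        out = enhance_particles(self._movie(img), 4.0)
        assert np.unravel_index(np.argmax(out.intensity[0]), img.shape) == (12, 13, 10)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        img = rng.random((12, 12, 12))
        e1 = enhance_particles(self._movie(img), 4.0).intensity
        e3 = enhance_particles(self._movie(3.0 * img), 4.0).intensity
        assert np.allclose(3.0 * e1, e3, atol=1e-4)

    def test_subvoxel_radius_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="clamping"):
            enhance_particles(self._movie(np.zeros((8, 8, 8)), voxel=(4, 4, 4)), 1.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            enhance_particles(self._movie(np.zeros((8, 8, 8))), 0.0)


class TestSegmentation:
    def _sphere_frame(self, centers, radius=5.0, shape=(32, 48, 48)):
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        img = np.zeros(shape)
        for c in centers:
            img += (
                (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2
            ).astype(float)
        return np.clip(img, 0, 1)

    def test_two_separated_spheres_two_labels(self):
        frame = self._sphere_frame([(16, 14, 14), (16, 34, 34)])
        movie = Movie4D(frame[None] * 100, (1, 1, 1), 2.0)
        labels = segment_cells(enhance_particles(movie, 5.0), reference=movie)[0]
        ids = np.unique(labels)[1:]
        assert len(ids) == 2
        for c in [(16, 14, 14), (16, 34, 34)]:
            lab = labels[c]
            assert lab > 0
            com = np.array(
                [(labels == lab).nonzero()[i].mean() for i in range(3)]
            )
            assert np.abs(com - np.array(c)).max() <= 1.0

    def test_overlapping_spheres_still_split(self):
        # centers 8 px apart at radius 5: ~20% overlap; the watershed must
        # split the touching pair at the waist of the distance map
        frame = self._sphere_frame([(16, 20, 20), (16, 20, 28)])
        movie = Movie4D(frame[None] * 100, (1, 1, 1), 2.0)
        labels = segment_cells(movie)[0]
        ids = np.unique(labels)[1:]
        assert len(ids) == 2
        sizes = [int((labels == i).sum()) for i in ids]
        assert min(sizes) / max(sizes) > 0.8  # split near the midplane

    def test_blank_frame_yields_no_labels(self):
        movie = Movie4D(np.zeros((1, 16, 16, 16)), (1, 1, 1), 2.0)
        labels = segment_cells(movie)[0]
        assert labels.max() == 0


class TestVolumeFilter:
    def test_debris_removed_cells_kept(self, small_movie):
        cfg, (movie, truth, debris) = small_movie
        enhanced = enhance_particles(movie, 5.0)
        segs = segment_cells(enhanced, reference=movie)
        kept = filter_by_volume(segs, cfg.volume_filter_um3, movie.voxel_size_um)
        voxvol = movie.voxel_volume_um3
        for labels in kept:
            sizes = np.bincount(labels.ravel())[1:]
            sizes = sizes[sizes > 0]
            assert len(sizes) == cfg.n_cells
            assert (sizes * voxvol >= cfg.volume_filter_um3).all()

    def test_zero_threshold_is_identity(self, small_movie):
        _, (movie, _, _) = small_movie
        segs = segment_cells(enhance_particles(movie, 5.0), reference=movie)
        out = filter_by_volume(segs, 0.0, movie.voxel_size_um)
        assert all(np.array_equal(a, b) for a, b in zip(segs, out))

    def test_infinite_threshold_empties_everything(self, small_movie):
        _, (movie, _, _) = small_movie
        segs = segment_cells(enhance_particles(movie, 5.0), reference=movie)
        out = filter_by_volume(segs, np.inf, movie.voxel_size_um)
        assert all(labels.max() == 0 for labels in out)


class TestDrift:
    def test_constant_shift_recovered_exactly_for_static_cells(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(10, 90, (20, 3))
        shift = np.array([1.0, -2.0, 0.5])
        frames = [base + t * shift for t in range(8)]
        drift = estimate_drift(frames)
        inc = np.diff(drift, axis=0)
        assert np.abs(inc - shift).max() < 0.1

    def test_no_drift_estimates_near_zero(self):
        cfg = MovieSimConfig(
            n_cells=50, frames=20, diffusion_um2_per_min=0.5,
            shape_vox=(64, 128, 128), seed=3,
        )
        truth, _ = simulate_tracks(cfg)
        frames = [
            g[["z_um", "y_um", "x_um"]].to_numpy() for _, g in truth.groupby("t")
        ]
        drift = estimate_drift(frames)
        step_sd = np.sqrt(2 * 0.5 * 2.0)
        assert np.abs(np.diff(drift, axis=0)).max() < step_sd

    def test_empty_frames_carry_drift_forward(self):
        frames = [np.ones((3, 3)), np.empty((0, 3)), np.ones((3, 3)) + 5]
        drift = estimate_drift(frames)
        assert np.array_equal(drift[1], drift[0])

    def test_correction_restores_undrifted_statistics(self):
        base = dict(
            n_cells=100, frames=60, diffusion_um2_per_min=1.0,
            shape_vox=(128, 256, 256), seed=4,
        )
        t_plain, _ = simulate_tracks(MovieSimConfig(**base))
        t_drift, _ = simulate_tracks(
            MovieSimConfig(**base, drift_um_per_frame=(0.5, -1.0, 1.5))
        )
        frames = [
            g[["z_um", "y_um", "x_um"]].to_numpy() for _, g in t_drift.groupby("t")
        ]
        drift = estimate_drift(frames)
        tracks_plain = tracks_from_truth(t_plain)
        tracks_corr = tracks_from_truth(t_drift)
        for tr in tracks_corr:
            tr.centroids_um = tr.centroids_um - drift[tr.t]
        s0 = np.mean([track_speed(tr, 2.0) for tr in tracks_plain])
        s1 = np.mean([track_speed(tr, 2.0) for tr in tracks_corr])
        m0 = fit_msd_slope(mean_msd_curve(tracks_plain, 5), 2.0)
        m1 = fit_msd_slope(mean_msd_curve(tracks_corr, 5), 2.0)
        assert abs(s1 - s0) / s0 < 0.05
        assert abs(m1 - m0) / m0 < 0.05


class TestLinking:
    def test_single_cell_full_length_track(self):
        frames = [[obs(t, 10.0, 10.0 + 0.1 * t, 10.0)] for t in range(90)]
        tracks = link_tracks(frames, gate_um=5.0)
        assert len(tracks) == 1 and len(tracks[0]) == 90

    def test_four_frame_cell_excluded(self):
        frames = [[obs(t, 5, 5, 5)] for t in range(4)] + [[] for _ in range(6)]
        assert link_tracks(frames, gate_um=5.0) == []

    def test_five_frame_cell_kept(self):
        frames = [[obs(t, 5, 5, 5)] for t in range(5)] + [[] for _ in range(5)]
        tracks = link_tracks(frames, gate_um=5.0)
        assert len(tracks) == 1 and len(tracks[0]) == 5

    def test_bridges_single_excluded_timepoint(self):
        frames = [[obs(t, 5, 5, 5)] if t != 4 else [] for t in range(10)]
        tracks = link_tracks(frames, gate_um=3.0, excluded_timepoints={4})
        assert len(tracks) == 1
        assert list(tracks[0].t) == [0, 1, 2, 3, 5, 6, 7, 8, 9]

    def test_unbridged_gap_splits_track(self):
        frames = [[obs(t, 5, 5, 5)] if t != 6 else [] for t in range(13)]
        tracks = link_tracks(frames, gate_um=3.0, min_length=5)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [6, 6]

    def test_identity_preservation_against_truth(self):
        cfg = MovieSimConfig(
            n_cells=50, frames=30, diffusion_um2_per_min=1.0,
            shape_vox=(96, 192, 192), seed=5,
        )
        truth, _ = simulate_tracks(cfg)
        frames = []
        for t, g in truth.groupby("t"):
            frames.append(
                [
                    obs(int(t), r.z_um, r.y_um, r.x_um, label=int(r.cell_id))
                    for r in g.itertuples()
                ]
            )
        tracks = link_tracks(frames, gate_um=15.0)
        assert len(tracks) == 50
        correct = total = 0
        for tr in tracks:
            ids = tr.labels
            total += len(ids) - 1
            correct += int((ids[1:] == ids[:-1]).sum())
        assert correct / total >= 0.95

    def test_no_observation_in_two_tracks_and_monotone_time(self):
        rng = np.random.default_rng(6)
        frames = [
            [
                obs(t, *rng.uniform(0, 100, 3), label=t * 100 + i)
                for i in range(8)
            ]
            for t in range(12)
        ]
        tracks = link_tracks(frames, gate_um=30.0, min_length=2)
        seen = set()
        for tr in tracks:
            assert (np.diff(tr.t) > 0).all()
            for t_, lab in zip(tr.t, tr.labels):
                key = (int(t_), int(lab))
                assert key not in seen
                seen.add(key)


class TestTrackStats:
    def _track(self, positions, ts=None):
        pos = np.asarray(positions, float)
        ts = np.arange(len(pos)) if ts is None else np.asarray(ts)
        n = len(pos)
        return Track(0, ts, pos, np.full(n, 500.0), np.full(n, 300.0), np.full(n, 0.8))

    def test_static_cell_zero_speed_zero_msd(self):
        tr = self._track([[5, 5, 5]] * 10)
        assert track_speed(tr, 2.0) == 0.0
        assert all(v == 0.0 for v in track_msd(tr, 5).values())

    def test_straight_line_speed(self):
        tr = self._track([[0, 0, i * 1.0] for i in range(10)])
        assert track_speed(tr, 2.0) == pytest.approx(0.5)

    def test_bridged_gap_uses_actual_elapsed_time(self):
        # 2 µm step over a bridged 2-frame jump = 2 µm / 4 min
        tr = self._track([[0, 0, 0], [0, 0, 1], [0, 0, 3]], ts=[0, 1, 3])
        assert track_speed(tr, 2.0) == pytest.approx((0.5 + 0.5) / 2)

    def test_ballistic_msd_exact(self):
        v = 0.7  # µm/min at 2-min frames
        tr = self._track([[0, 0, v * 2.0 * i] for i in range(12)])
        msd = track_msd(tr, 5)
        for tau in range(1, 6):
            assert msd[tau] == pytest.approx((v * tau * 2.0) ** 2)

    def test_msd_omits_unreachable_lags(self):
        tr = self._track([[0, 0, i] for i in range(4)])
        msd = track_msd(tr, 10)
        assert set(msd) == {1, 2, 3}

    def test_brownian_ensemble_slope_is_6d(self):
        cfg = MovieSimConfig(
            n_cells=200, frames=90, diffusion_um2_per_min=1.0,
            shape_vox=(128, 256, 256), seed=7,
        )
        truth, _ = simulate_tracks(cfg)
        slope = fit_msd_slope(mean_msd_curve(tracks_from_truth(truth), 5), 2.0)
        assert slope == pytest.approx(6.0, rel=0.10)


class TestGroupComparison:
    def _summaries(self, speeds_by_group):
        out = []
        for g, speeds in speeds_by_group.items():
            for i, s in enumerate(speeds):
                out.append(
                    HeartSummary(f"{g}{i}", g, 10, 10, s, 50.0, 0.7)
                )
        return out

    def test_identical_groups_not_significant(self):
        s = self._summaries({"old": [1, 2, 3, 4, 5, 6], "young": [1, 2, 3, 4, 5, 6]})
        res = compare_groups(s, "speed", "wilcoxon")
        assert res.pvalue > 0.9

    def test_label_swap_flips_t_statistic(self):
        s1 = self._summaries({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 7.0]})
        s2 = self._summaries({"b": [1.0, 2.0, 3.0], "a": [4.0, 5.0, 7.0]})
        r1 = compare_groups(s1, "speed", "welch_t")
        r2 = compare_groups(s2, "speed", "welch_t")
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_too_few_hearts_rejected(self):
        s = self._summaries({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(s, "speed")

    def test_unknown_metric_and_test_rejected(self):
        s = self._summaries({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(s, "velocity")
        with pytest.raises(ValueError):
            compare_groups(s, "speed", test="anova")


class TestEndToEnd:
    def test_pipeline_recovers_cells_and_lengths(self, small_movie):
        cfg, (movie, truth, _) = small_movie
        res = track_movie(
            movie, cell_radius_um=5.0, min_volume_um3=cfg.volume_filter_um3
        )
        assert len(res.tracks) == cfg.n_cells
        assert all(len(tr) == cfg.frames for tr in res.tracks)
        # centroids close to truth at t=0 (matched by nearest neighbor)
        t0 = truth[truth.t == 0][["z_um", "y_um", "x_um"]].to_numpy()
        for tr in res.tracks:
            d = np.linalg.norm(t0 - tr.centroids_um[0], axis=1).min()
            assert d < 3.0

    def test_rendered_old_young_pattern(self):
        """Full rendered pipeline reproduces the qualitative aging pattern:
        old cells (higher D, rounder) show higher sphericity, speed and MSD
        than young."""
        summaries = {}
        for group, d, psi in (("old", 2.0, 0.92), ("young", 0.5, 0.65)):
            cfg = MovieSimConfig(
                n_cells=5, n_debris=5, frames=10, diffusion_um2_per_min=d,
                target_sphericity_mean=psi, target_sphericity_sd=0.03,
                noise_model={"gaussian_sd": 0.0, "poisson_scaling": 0.0},
                seed=99,
            )
            movie, _, _ = generate_movie(cfg)
            res = track_movie(movie, 5.0, cfg.volume_filter_um3)
            summaries[group] = summarize_heart(
                res.tracks, group, group, cfg.frame_interval_min, ref_lag=3
            )
        old, young = summaries["old"], summaries["young"]
        assert old.mean_sphericity > young.mean_sphericity
        assert old.mean_track_speed_um_per_min > young.mean_track_speed_um_per_min
        assert old.mean_msd_at_ref_lag_um2 > young.mean_msd_at_ref_lag_um2

    def test_summarize_heart_means(self, small_movie):
        cfg, (movie, truth, _) = small_movie
        res = track_movie(movie, 5.0, cfg.volume_filter_um3)
        summary = summarize_heart(
            res.tracks, "h1", "young", cfg.frame_interval_min, ref_lag=3
        )
        assert summary.n_tracks == cfg.n_cells
        assert summary.n_cells_t0 == cfg.n_cells
        truth_psi = truth.groupby("cell_id")["sphericity"].first().mean()
        assert summary.mean_sphericity == pytest.approx(truth_psi, abs=0.08)
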