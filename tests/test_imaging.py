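"""Segmentation-derived constriction metrics and the synthetic movie."""

import numpy as np
import pytest

from agf.imaging import (SegmentedMovie, constriction_flags, detect_time_zero,
                         generate_synthetic_movie, identify_active_cells,
                         minor_axis_length, nu_avg_profile,
                         pixel_neighbor_graph, reference_minor_axis,
                         second_moment_matrix, track_cells)


def _block(x0, y0, w, h):
    xs, ys = np.meshgrid(np.arange(x0, x0 + w), np.arange(y0, y0 + h))
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestSecondMoment:
    def test_solid_3x3_block(self):
        M = second_moment_matrix(_block(0, 0, 3, 3))
        np.testing.assert_allclose(M, np.diag([6.0, 6.0]))

    def test_single_row(self):
        M = second_moment_matrix(_block(0, 0, 5, 1))
        np.testing.assert_allclose(M, np.diag([10.0, 0.0]))

    def test_rotation_invariance_of_eigenvalues(self):
        pts = _block(0, 0, 7, 3)
        rotated = np.column_stack([-pts[:, 1], pts[:, 0]])
        e1 = np.linalg.eigvalsh(second_moment_matrix(pts))
        e2 = np.linalg.eigvalsh(second_moment_matrix(rotated))
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_degenerate_pixel_set_rejected(self):
        with pytest.raises(ValueError):
            second_moment_matrix([(0, 0), (1, 1)])


class TestMinorAxis:
    def test_3x3_block_value(self):
        M = second_moment_matrix(_block(0, 0, 3, 3))
        assert minor_axis_length(M, 9) == pytest.approx(4 * np.sqrt(6 / 9))

    def test_rasterized_disk_recovers_diameter(self):
        R = 40
        ys, xs = np.mgrid[-R - 2:R + 3, -R - 2:R + 3]
        mask = xs ** 2 + ys ** 2 <= R ** 2
        pts = np.column_stack([xs[mask], ys[mask]])
        M = second_moment_matrix(pts)
        lam = minor_axis_length(M, pts.shape[0])
        assert lam == pytest.approx(2 * R, rel=0.03)

    def test_collinear_pixels_warn_and_return_zero(self):
        M = second_moment_matrix(_block(0, 0, 5, 1))
        with pytest.warns(UserWarning):
            assert minor_axis_length(M, 5) == 0.0

    def test_matches_skimage_on_rasterized_ellipse(self):
        """Independent oracle: scikit-image's equivalent-ellipse axes."""
        from skimage.measure import regionprops

        a, b = 30, 14
        ys, xs = np.mgrid[-40:41, -40:41]
        mask = (xs / a) ** 2 + (ys / b) ** 2 <= 1.0
        label = mask.astype(np.int32)
        prop = regionprops(label)[0]
        pts = np.column_stack([xs[mask] + 40, ys[mask] + 40])
        M = second_moment_matrix(pts)
        lam = minor_axis_length(M, pts.shape[0])
        assert lam == pytest.approx(prop.axis_minor_length, rel=1e-6)
        assert lam == pytest.approx(2 * b, rel=0.03)


@pytest.fixture(scope="module")
def random_movie():
    return generate_synthetic_movie(n_cols=14, n_rows=10, n_frames=30,
                                    schedule="random", n_constrict=18,
                                    onset_frame=22, seed=3)


class TestReferenceMinorAxis:
    def test_constant_preonset_mean_is_exact(self, random_movie):
        track = track_cells(random_movie)
        lref = reference_minor_axis(track, window=20, onset_frame=22)
        truth = random_movie.ground_truth["lambda_ref"]
        for cell, lam in lref.dropna().items():
            assert lam == pytest.approx(truth[cell], rel=1e-6)

    def test_insufficient_preonset_frames_flagged(self, random_movie):
        track = track_cells(random_movie)
        short = track[track["frame"] >= 12]   # only 10 pre-onset frames left
        lref = reference_minor_axis(short, window=20, onset_frame=22)
        assert lref.isna().all()

    def test_invalid_window_rejected(self, random_movie):
        with pytest.raises(ValueError):
            reference_minor_axis(track_cells(random_movie), window=0)


class TestConstrictionFlags:
    def test_threshold_boundary_inclusive(self):
        import pandas as pd
        track = pd.DataFrame({"frame": [0, 1, 2], "cell": [1, 1, 1],
                              "minor": [10.0, 6.5, 6.4],
                              "area": 50, "cx": 0.0, "cy": 0.0,
                              "major": 10.0})
        lref = pd.Series({1: 10.0})
        out = constriction_flags(track, lref, r_c=0.65)
        assert list(out["constricted"]) == [False, True, True]

    def test_threshold_monotonicity(self, random_movie):
        """The constricted set at a stricter cutoff is a subset of the set
        at a weaker cutoff, frame by frame."""
        track = track_cells(random_movie)
        lref = reference_minor_axis(track, window=20, onset_frame=22)
        strict = constriction_flags(track, lref, r_c=0.6)
        weak = constriction_flags(track, lref, r_c=0.9)
        assert not (strict["constricted"] & ~weak["constricted"]).any()


class TestTimeZero:
    def test_no_constrictions_not_found(self):
        movie = generate_synthetic_movie(n_cols=8, n_rows=6, n_frames=12,
                                         schedule="none", seed=1)
        frame, cell = detect_time_zero(movie, ref_window=5)
        assert frame is None and cell is None

    def test_persistent_constriction_detected_at_onset(self):
        movie = generate_synthetic_movie(n_cols=8, n_rows=6, n_frames=16,
                                         schedule="chain", n_constrict=1,
                                         onset_frame=7, seed=2)
        frame, cell = detect_time_zero(movie, ref_window=5, persistence=3)
        assert frame is not None
        assert abs(frame - 7) <= 1
        assert cell in movie.ground_truth["constriction_frame"]

    def test_persistence_gate_rejects_flicker(self):
        base = generate_synthetic_movie(n_cols=8, n_rows=6, n_frames=16,
                                        schedule="chain", n_constrict=1,
                                        onset_frame=7, seed=2)
        frames = list(base.frames)
        frames[8] = frames[0].copy()   # cell recovers at frame 8
        frames[10] = frames[0].copy()
        frames[11] = frames[0].copy()
        frames[12] = frames[0].copy()
        frames[13] = frames[0].copy()
        frames[14] = frames[0].copy()
        frames[15] = frames[0].copy()
        movie = SegmentedMovie(frames=frames)
        frame, _ = detect_time_zero(movie, ref_window=5, persistence=3)
        assert frame is None


class TestPixelNeighborGraph:
    def test_blocks_across_membrane_are_adjacent(self):
        frame = np.zeros((10, 11), dtype=int)
        frame[2:8, 1:5] = 1
        frame[2:8, 6:10] = 2    # one empty column between them
        assert (1, 2) in pixel_neighbor_graph(frame)

    def test_distant_blocks_not_adjacent(self):
        frame = np.zeros((10, 12), dtype=int)
        frame[2:8, 1:4] = 1
        frame[2:8, 7:11] = 2    # three empty columns
        assert pixel_neighbor_graph(frame) == set()

    def test_recovers_generator_ground_truth(self, random_movie):
        found = pixel_neighbor_graph(random_movie.frames[0])
        truth = random_movie.ground_truth["adjacency"]
        recall = len(found & truth) / len(truth)
        assert recall >= 0.99
        # extra edges come only from corner-touching diagonal cells (a
        # genuine property of the Chebyshev-2 criterion); they stay rare
        assert len(found - truth) <= 0.10 * len(truth)


class TestActiveCellsAndRoundTrip:
    def test_designed_active_subset_recovered(self, random_movie):
        active = identify_active_cells(random_movie, r_active=0.85,
                                       window=20, onset_frame=22)
        scheduled = set(random_movie.ground_truth["constriction_frame"])
        assert active == scheduled

    def test_constriction_times_within_one_frame(self, random_movie):
        track = track_cells(random_movie)
        lref = reference_minor_axis(track, window=20, onset_frame=22)
        flagged = constriction_flags(track, lref, r_c=0.65)
        first = flagged[flagged["constricted"]].groupby("cell")["frame"].min()
        truth = random_movie.ground_truth["constriction_frame"]
        assert set(first.index) == set(truth)
        for cell, t_meas in first.items():
            assert abs(int(t_meas) - truth[cell]) <= 1

    def test_determinism(self):
        a = generate_synthetic_movie(seed=9)
        b = generate_synthetic_movie(seed=9)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_overbooked_schedule_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_movie(n_cols=4, n_rows=4, n_constrict=100)


class TestNuAvgProfile:
    def test_single_bin_is_overall_fraction(self, random_movie):
        prof = nu_avg_profile(random_movie, frames=[29], n_bins=1, r_c=0.65,
                              window=20, onset_frame=22)
        track = track_cells(random_movie)
        lref = reference_minor_axis(track, window=20, onset_frame=22)
        flagged = constriction_flags(track, lref, r_c=0.65)
        last = flagged[flagged["frame"] == 29]
        assert prof["nu_avg"].iloc[0] == pytest.approx(
            last["constricted"].mean())

    def test_disrupted_band_is_depressed(self):
        movie = generate_synthetic_movie(n_cols=18, n_rows=10, n_frames=30,
                                         schedule="band-disrupted",
                                         n_constrict=30, onset_frame=22,
                                         band_cols=(7, 11), seed=6)
        prof = nu_avg_profile(movie, frames=[29], n_bins=6, r_c=0.65,
                              window=20, onset_frame=22)
        center = prof["nu_avg"].iloc[2:4].mean()
        flanks = prof["nu_avg"].iloc[[0, 1, 4, 5]].mean()
        assert center < flanks

    def test_absolute_threshold_requires_pixel_size(self, random_movie):
        movie = SegmentedMovie(frames=random_movie.frames, pixel_size=None)
        with pytest.raises(ValueError):
            nu_avg_profile(movie, frames=[0], minor_threshold_um=1.3)

    def test_cluster_of_chain_schedule_is_single_multiplet(self):
        """A chain schedule must yield one dominant multiplet on the
        pixel-adjacency graph."""
        from agf.clusters import cluster_report, identify_clusters

        movie = generate_synthetic_movie(n_cols=12, n_rows=8, n_frames=26,
                                         schedule="chain", n_constrict=8,
                                         onset_frame=20, seed=4)
        track = track_cells(movie)
        lref = reference_minor_axis(track, window=18, onset_frame=20)
        flagged = constriction_flags(track, lref, r_c=0.65)
        last = flagged[flagged["frame"] == movie.n_frames - 1]
        constricted = set(last[last["constricted"]]["cell"].astype(int))
        pairs = list(pixel_neighbor_graph(movie.frames[-1]))
        clusters = identify_clusters(constricted, pairs)
        rpt = cluster_report(clusters, len(movie.cell_ids))
        assert rpt.eta_m > 0.8
        assert max(len(c) for c in clusters) >= 6
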