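"""Circularity, segmentation, tracking, and local stretch estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valvemech import cells as ck
from valvemech import synthetic as syn
from valvemech.errors import (
    InsufficientDataError,
    InvalidPolygonError,
    InvalidSeedError,
    UnstablePairError,
)


def regular_polygon(n, radius=100.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


class TestCircularity:
    def test_square_is_pi_over_four(self):
        square = np.array([[0, 0], [7, 0], [7, 7], [0, 7]], dtype=float)
        assert ck.circularity(square) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_fine_regular_polygon_approaches_circle(self):
        assert ck.circularity(regular_polygon(360)) >= 0.9999

    def test_sliver_rectangle_closed_form(self):
        rect = np.array([[0, 0], [100, 0], [100, 1], [0, 1]], dtype=float)
        expected = 4 * np.pi * 100 / 202**2
        assert ck.circularity(rect) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0308, abs=1e-4)

    def test_rejects_degenerate_and_self_intersecting(self):
        with pytest.raises(InvalidPolygonError):
            ck.circularity(np.array([[0, 0], [1, 1]]))
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(InvalidPolygonError):
            ck.circularity(bowtie)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        scale=st.floats(0.01, 100.0),
        angle=st.floats(0.0, 2 * math.pi),
        n=st.integers(3, 12),
        seed=st.integers(0, 10_000),
    )
    def test_similarity_invariance(self, scale, angle, n, seed):
        # CI is invariant under rotation + uniform scaling + translation
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(0.5, 1.5, n)
        poly = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        rot = np.array([[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]])
        moved = scale * poly @ rot.T + np.array([3.7, -11.2])
        assert ck.circularity(moved) == pytest.approx(ck.circularity(poly), rel=1e-9)

    def test_isoperimetric_bound_on_random_convex_polygons(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 40)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            if len(np.unique(angles)) < 3:
                continue
            r = rng.uniform(1.0, 50.0)
            poly = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
            assert ck.circularity(poly) <= 1.0 + 1e-9


class TestSegmentation:
    def test_counts_disjoint_generated_cells(self):
        spec = syn.CellFieldSpec(n_cells=20, base_ci=0.85, ci_slope=0.0, noise_sd=0.0, seed=7)
        binary = (syn.gen_cell_masks(spec, 1.0) > 0).astype(float)
        outlines = ck.segment_cells(binary)
        assert len(outlines) == 20

    def test_blank_raster_yields_empty_result(self):
        assert ck.segment_cells(np.zeros((64, 64))) == []

    def test_overlapping_ellipses_merge_into_one_component(self):
        from skimage.draw import ellipse

        img = np.zeros((128, 128))
        rr, cc = ellipse(60, 50, 15, 25, shape=img.shape)
        img[rr, cc] = 1.0
        rr, cc = ellipse(60, 70, 15, 25, shape=img.shape)
        img[rr, cc] = 1.0
        assert len(ck.segment_cells(img)) == 1


class TestMatching:
    def test_identical_frames_identity_matching(self):
        spec = syn.CellFieldSpec(n_cells=10, seed=1)
        frame = ck.outlines_from_labels(syn.gen_cell_masks(spec, 1.0))
        chains = ck.match_cells([frame, frame])
        assert len(chains) == 10
        assert all(a.cell_id == b.cell_id for a, b in chains)

    def test_ground_truth_labels_recovered_across_stretch(self, stretch_levels):
        spec = syn.CellFieldSpec(n_cells=30, ci_slope=-0.2, seed=5)
        frames = [
            ck.outlines_from_labels(syn.gen_cell_masks(spec, lam), frame=t)
            for t, lam in enumerate(stretch_levels)
        ]
        chains = ck.match_cells(frames)
        correct = sum(1 for chain in chains if len({c.cell_id for c in chain}) == 1)
        assert correct / spec.n_cells >= 0.95

    def test_zero_gating_radius_matches_nothing(self):
        spec = syn.CellFieldSpec(n_cells=5, seed=1)
        frame = ck.outlines_from_labels(syn.gen_cell_masks(spec, 1.0))
        assert ck.match_cells([frame, frame], gating_radius=0.0) == []


class TestCiTrajectory:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        lam = np.arange(1.0, 1.61, 0.1)
        chains = []
        for cid in range(3):
            chain = []
            for t, l in enumerate(lam):
                ci_target = 0.9 - 0.3 * (l - 1.0)
                q = syn._aspect_from_ci(ci_target)
                a = 30.0
                tpts = np.linspace(0, 2 * np.pi, 720, endpoint=False)
                verts = np.column_stack([a * np.cos(tpts), a * q * np.sin(tpts)])
                chain.append(ck.CellOutline(cell_id=cid, frame=t, vertices=verts + 100 * cid))
            chains.append(chain)
        traj = ck.ci_trajectory(chains, lam)
        # analytic ellipses discretized at 720 vertices: slope exact to ~1e-4
        assert traj.slope == pytest.approx(-0.3, abs=1e-3)
        assert traj.r_squared > 0.9999

    def test_constant_ci_gives_zero_slope(self):
        lam = np.array([1.0, 1.2, 1.4])
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        chain = [ck.CellOutline(0, t, square) for t in range(3)]
        traj = ck.ci_trajectory([chain], lam)
        assert traj.slope == pytest.approx(0.0, abs=1e-14)

    def test_generator_slope_recovered(self, stretch_levels):
        spec = syn.CellFieldSpec(n_cells=50, base_ci=0.9, ci_slope=-0.25, noise_sd=0.01, seed=3)
        frames = [
            ck.outlines_from_labels(syn.gen_cell_masks(spec, lam), frame=t)
            for t, lam in enumerate(stretch_levels)
        ]
        traj = ck.ci_trajectory(ck.match_cells(frames), stretch_levels)
        assert traj.slope == pytest.approx(-0.25, abs=0.04)

    def test_too_few_frames_raises(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        with pytest.raises(InsufficientDataError):
            ck.ci_trajectory([[ck.CellOutline(0, 0, square)]], [1.0])


def _blob_frame(points, size=128, sigma=2.5):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for p in points:
        img += np.exp(-((xx - p[0]) ** 2 + (yy - p[1]) ** 2) / (2 * sigma**2))
    return img


class TestFiducialTracking:
    def test_identical_frames_zero_displacement(self):
        pts = np.array([[40.0, 40.0], [80.0, 60.0], [60.0, 90.0]])
        img = _blob_frame(pts)
        tracks = ck.track_fiducials([img, img], pts)
        for t in tracks:
            np.testing.assert_allclose(t.positions[1], t.positions[0], atol=1e-6)

    def test_integer_translation_recovered_subpixel(self):
        pts = np.array([[40.0, 40.0], [80.0, 60.0], [60.0, 90.0]])
        img = _blob_frame(pts)
        shifted = np.roll(img, 7, axis=1)  # shift by (+7, 0) px
        tracks = ck.track_fiducials([img, shifted], pts)
        for t in tracks:
            d = t.positions[1] - t.positions[0]
            assert d[0] == pytest.approx(7.0, abs=0.25)
            assert d[1] == pytest.approx(0.0, abs=0.25)

    def test_marker_leaving_search_window_is_lost(self):
        pts = np.array([[40.0, 40.0]])
        img = _blob_frame(pts)
        far = _blob_frame(np.array([[100.0, 100.0]]))
        tracks = ck.track_fiducials([img, far], pts, search_radius=10)
        assert tracks[0].lost_frame == 1
        assert np.isnan(tracks[0].positions[1]).all()

    def test_seed_outside_raster_rejected(self):
        img = _blob_frame(np.array([[40.0, 40.0]]))
        with pytest.raises(InvalidSeedError):
            ck.track_fiducials([img, img], np.array([[500.0, 40.0]]))


class TestLocalStretch:
    @staticmethod
    def _static_track(mid, pos, n_frames=3):
        return ck.MarkerTrack(mid, np.tile(np.asarray(pos, dtype=float), (n_frames, 1)))

    def test_static_markers_give_unit_stretch(self):
        a = self._static_track(0, [10.0, 50.0])
        b = self._static_track(1, [90.0, 50.0])
        np.testing.assert_allclose(ck.local_stretch([(a, b)]), 1.0)

    def test_affine_stretch_recovered_from_tracked_markers(self):
        # virtual markers on a textured scene warped by a lambda = 1.4 affine
        # map; each marker's local texture is unique, as on real tissue
        from scipy.ndimage import affine_transform, gaussian_filter

        rng = np.random.default_rng(2)
        texture = gaussian_filter(rng.standard_normal((256, 256)), 2.0)
        lam = 1.4
        c = 128.0
        # output pixel (row, col) samples input at the inverse affine map
        matrix = np.diag([lam**0.5, 1.0 / lam])
        offset = c - matrix @ np.array([c, c])
        warped = affine_transform(texture, matrix, offset=offset, order=3)
        pts = np.array([[70.0, 80.0], [180.0, 80.0], [70.0, 180.0], [180.0, 180.0]])
        tracks = ck.track_fiducials([texture, warped], pts, search_radius=45)
        pairs = [(tracks[0], tracks[1]), (tracks[2], tracks[3])]
        local = ck.local_stretch(pairs)
        assert local[1] == pytest.approx(1.4, abs=0.02)

    def test_pure_transverse_motion_projects_out(self):
        a0 = np.array([[10.0, 50.0], [10.0, 80.0]])
        b0 = np.array([[90.0, 50.0], [90.0, 80.0]])
        a = ck.MarkerTrack(0, a0)
        b = ck.MarkerTrack(1, b0)
        np.testing.assert_allclose(ck.local_stretch([(a, b)]), 1.0)

    def test_unstable_pair_rejected(self):
        a = self._static_track(0, [10.0, 50.0])
        b = self._static_track(1, [11.0, 90.0])  # projected separation 1 px
        with pytest.raises(UnstablePairError):
            ck.local_stretch([(a, b)])


class TestExternalTracings:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        rows = []
        square = [(0, 0), (10, 0), (10, 10), (0, 10)]
        for frame in range(2):
            for vi, (x, y) in enumerate(square):
                rows.append({"cell_id": 3, "frame": frame, "vertex_index": vi, "x_px": x, "y_px": y})
        path = tmp_path / "tracings.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        frames = ck.read_tracings(path)
        assert sorted(frames) == [0, 1]
        assert ck.circularity(frames[0][0]) == pytest.approx(np.pi / 4)

    def test_trajectory_csv_written_with_fit_summary(self, tmp_path):
        lam = np.array([1.0, 1.2, 1.4])
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        chain = [ck.CellOutline(0, t, square) for t in range(3)]
        traj = ck.ci_trajectory([chain], lam)
        out = tmp_path / "traj.csv"
        ck.write_ci_trajectory(traj, out)
        assert out.read_text().splitlines()[0] == "frame,stretch,mean_ci,n_cells"
        assert (tmp_path / "traj.fit.csv").exists()
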