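"""Arch localization, morphology, skeleton pruning and 14-point sampling."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial import cKDTree

from panomatch.arch import (
    ArchCurve,
    clean_mask,
    extract_arch,
    reference_arch_mask,
    sample_arch_points,
    select_best_slice,
    skeleton_centerline,
)
from panomatch.phantom import _arch_polyline
from panomatch.volume_io import VoxelVolume


class TestReferenceMask:
    def test_shape_and_symmetry(self):
        mask = reference_arch_mask((200, 180), (0.7, 0.7))
        assert mask.any()
        np.testing.assert_array_equal(mask, mask[::-1, :])  # mirror in x

    def test_area_fraction_on_typical_frame(self):
        # band area ~ arc length x band width, a few percent of the frame
        mask = reference_arch_mask((200, 180), (0.7, 0.7))
        frac = mask.mean()
        assert 0.05 <= frac <= 0.25

    def test_deterministic(self):
        a = reference_arch_mask((128, 128), (0.5, 0.5))
        b = reference_arch_mask((128, 128), (0.5, 0.5))
        np.testing.assert_array_equal(a, b)

    def test_small_frame_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            reference_arch_mask((32, 32), (0.5, 0.5))


def _arch_band_volume(k: int, nz: int = 16, faint: float = 300.0):
    """Volume whose slice k carries a bright arch band; elsewhere sub-threshold."""
    band = reference_arch_mask((128, 128), (0.8, 0.8))
    vol = np.full((128, 128, nz), -1000.0, dtype=np.float32)
    vol[:, :, :] = faint  # soft tissue everywhere, below the 500 HU cut
    vol[:, :, k][band] = 1000.0
    blob = np.zeros_like(band)
    blob[40:60, 40:60] = True  # a non-arch bony blob on other slices
    for iz in range(nz):
        if iz != k:
            vol[:, :, iz][blob] = 1000.0
    return VoxelVolume(vol, (0.8, 0.8, 1.0))


class TestSelectBestSlice:
    def test_finds_the_arch_slice(self):
        score = select_best_slice(_arch_band_volume(11))
        assert abs(score.slice_index - 11) <= 2
        assert score.correlation > 0.5

    def test_soft_tissue_only_is_an_error(self):
        vol = VoxelVolume(np.full((64, 64, 12), 50.0, dtype=np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="no jaw found"):
            select_best_slice(vol)

    def test_slice_duplication_keeps_physical_position(self):
        vol = _arch_band_volume(6, nz=12)
        doubled = VoxelVolume(np.repeat(vol.intensities, 2, axis=2), (0.8, 0.8, 0.5))
        z1 = select_best_slice(vol).slice_index * 1.0
        z2 = select_best_slice(doubled).slice_index * 0.5
        assert abs(z1 - z2) <= 1.0  # same physical z within one original slice


class TestCleanMask:
    def test_removes_isolated_specks(self):
        band = reference_arch_mask((128, 128), (0.8, 0.8))
        noisy = band.copy()
        for i, j in [(5, 5), (10, 100), (120, 8), (64, 2), (2, 64)]:
            noisy[i, j] = True
        cleaned = clean_mask(noisy, (0.8, 0.8))
        for i, j in [(5, 5), (10, 100), (120, 8), (64, 2), (2, 64)]:
            assert not cleaned[i, j]

    def test_closes_small_gap(self):
        from skimage.measure import label

        band = reference_arch_mask((128, 128), (0.8, 0.8))
        broken = band.copy()
        broken[:, 63:64] = False  # 0.8 mm gap across the band
        assert label(broken, connectivity=2).max() >= 2
        cleaned = clean_mask(broken, (0.8, 0.8))
        assert label(cleaned, connectivity=2).max() == 1

    def test_idempotent(self):
        band = reference_arch_mask((128, 128), (0.8, 0.8))
        once = clean_mask(band, (0.8, 0.8))
        twice = clean_mask(once, (0.8, 0.8))
        np.testing.assert_array_equal(once, twice)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clean_mask(np.zeros((32, 32), dtype=bool), (1, 1))


def _brute_force_longest_path(skel: np.ndarray) -> float:
    """Oracle: longest geodesic over all endpoint pairs of the skeleton graph."""
    g = nx.Graph()
    pix = set(map(tuple, np.argwhere(skel)))
    for i, j in pix:
        for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):
            if (i + di, j + dj) in pix:
                g.add_edge((i, j), (i + di, j + dj), weight=np.hypot(di, dj))
    best = 0.0
    for u, v in itertools.combinations(g.nodes, 2):
        try:
            best = max(best, nx.dijkstra_path_length(g, u, v, weight="weight"))
        except nx.NetworkXNoPath:
            pass
    return best


class TestSkeletonCenterline:
    def test_one_pixel_line_is_its_own_skeleton(self):
        mask = np.zeros((32, 32), dtype=bool)
        for c in range(4, 28):
            mask[10, c] = True
        path = skeleton_centerline(mask)
        assert len(path) == 24
        assert set(map(tuple, path)) == set(map(tuple, np.argwhere(mask)))

    def test_spur_is_pruned(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[20, 5:55] = True  # main run
        mask[10:20, 30] = True  # 10-pixel spur
        path = skeleton_centerline(mask)
        assert not any(tuple(p) in {(r, 30) for r in range(10, 20)} for p in path)

    def test_matches_brute_force_geodesic_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            mask = np.zeros((24, 24), dtype=bool)
            # random tree-ish scribble
            r, c = 12, 3
            mask[r, c] = True
            for _ in range(60):
                dr, dc = rng.integers(-1, 2), rng.integers(0, 2)
                r = int(np.clip(r + dr, 1, 22))
                c = int(np.clip(c + dc, 1, 22))
                mask[r, c] = True
            path = skeleton_centerline(mask)
            seg = np.diff(path, axis=0)
            length = np.hypot(seg[:, 0], seg[:, 1]).sum()
            from skimage.morphology import skeletonize

            expected = _brute_force_longest_path(skeletonize(mask))
            assert length == pytest.approx(expected, abs=1e-9)

    def test_path_is_simple(self):
        mask = reference_arch_mask((128, 128), (0.8, 0.8))
        path = skeleton_centerline(mask)
        assert len({tuple(p) for p in path}) == len(path)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5:10] = True
        mask[20, 5:10] = True
        with pytest.raises(ValueError, match="single connected"):
            skeleton_centerline(mask)


class TestSampleArchPoints:
    def test_straight_line_arithmetic(self):
        # 110 mm straight path at 1 mm/pixel
        path = np.column_stack([np.arange(111), np.full(111, 7)])
        curve = sample_arch_points(path, (1.0, 1.0), z_mm=-5.0)
        pts = curve.points_mm
        assert len(pts) == 14
        xs = pts[:, 0]
        np.testing.assert_allclose(np.diff(xs), 10.0, atol=1e-9)
        assert xs[0] == pytest.approx(-10.0)
        assert xs[-1] == pytest.approx(120.0)
        np.testing.assert_allclose(pts[:, 2], 15.0)  # z - 5 + 20 mm cranial shift

    def test_always_fourteen_points(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(40, 120))
            path = np.column_stack([np.arange(n), (10 + 5 * np.sin(np.arange(n) / 9)).astype(int)])
            curve = sample_arch_points(path, (0.8, 0.8), z_mm=0.0)
            assert curve.points_mm.shape == (14, 3)

    def test_short_path_rejected(self):
        path = np.column_stack([np.arange(10), np.zeros(10)])
        with pytest.raises(ValueError, match="too short"):
            sample_arch_points(path, (1.0, 1.0), z_mm=0.0)

    def test_orientation_right_to_left(self):
        path = np.column_stack([np.arange(60, 0, -1), np.zeros(60)])
        curve = sample_arch_points(path, (1.0, 1.0), z_mm=0.0)
        assert curve.points_mm[0, 0] < curve.points_mm[-1, 0]


class TestCurveValidation:
    def test_requires_exactly_fourteen(self):
        with pytest.raises(ValueError, match="14"):
            ArchCurve(np.zeros((12, 3)) + np.arange(12)[:, None])

    def test_rejects_duplicate_neighbors(self):
        pts = np.column_stack([np.arange(14.0), np.zeros(14), np.zeros(14)])
        pts[7] = pts[6]
        with pytest.raises(ValueError, match="distinct"):
            ArchCurve(pts)

    def test_standard_curve_must_be_planar(self):
        pts = np.column_stack([np.arange(14.0), np.zeros(14), np.arange(14.0)])
        with pytest.raises(ValueError, match="planar"):
            ArchCurve(pts, provenance="standard")
        ArchCurve(pts, provenance="truth")  # non-standard may vary in z


class TestEndToEndOnPhantom:
    def test_curve_tracks_true_centerline(self, fixture_phantom, fixture_spec):
        curve, score = extract_arch(fixture_phantom.volume)
        assert curve.points_mm.shape == (14, 3)
        poly = _arch_polyline(fixture_spec.arch_width_mm, fixture_spec.arch_depth_mm, 4096)
        dist, _ = cKDTree(poly).query(curve.points_mm[:, :2])
        assert dist.max() <= 2.0

    def test_interior_points_equally_spaced(self, fixture_phantom):
        curve, _ = extract_arch(fixture_phantom.volume)
        inner = curve.points_mm[1:-1]
        gaps = np.linalg.norm(np.diff(inner, axis=0), axis=1)
        # chord gaps of equal-arc samples agree to within a voxel
        assert np.ptp(gaps) < 1.0

    def test_cranial_shift_applied(self, fixture_phantom):
        curve, score = extract_arch(fixture_phantom.volume)
        vol = fixture_phantom.volume
        slice_z = vol.origin_mm[2] + score.slice_index * vol.spacing_mm[2]
        assert curve.points_mm[0, 2] == pytest.approx(slice_z + 20.0)
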