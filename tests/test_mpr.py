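"""Curved MPR: spline fitting, slab sampling, projection, finalization."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from panomatch.arch import ArchCurve
from panomatch.mpr import (
    ParametricCurve,
    ReconSettings,
    bright_band_slope,
    finalize_pr_like,
    fit_curve_bspline,
    project_slab,
    realign_teeth,
    sample_curved_slab,
)
from panomatch.phantom import _arch_polyline, _equal_arc_stations
from panomatch.pipeline import reconstruct_pr_like
from panomatch.volume_io import Image2D, VoxelVolume


def straight_curve(length=13.0, z=5.0):
    t = np.linspace(0, 1, 14)
    pts = np.column_stack([length * t, np.full(14, 2.0), np.full(14, z)])
    return ArchCurve(pts, provenance="truth")


class TestBsplineFit:
    def test_interpolates_control_points(self):
        poly = _arch_polyline(60, 50)
        pts = _equal_arc_stations(poly, np.linspace(0, 1, 14))
        curve = ArchCurve(np.column_stack([pts, np.zeros(14)]), provenance="truth")
        pc = fit_curve_bspline(curve)
        # interpolation contract: the spline passes through every knot
        np.testing.assert_allclose(pc._spline(pc._u), curve.points_mm, atol=1e-6)

    def test_collinear_points_give_straight_segment(self):
        pc = fit_curve_bspline(straight_curve())
        s = np.linspace(0, pc.total_length, 200)
        pts = pc.points_at(s)
        np.testing.assert_allclose(pts[:, 1], 2.0, atol=1e-6)
        np.testing.assert_allclose(pts[:, 2], 5.0, atol=1e-6)

    def test_spline_stays_near_analytic_parabola(self):
        poly = _arch_polyline(60, 55, 8192)
        pts = _equal_arc_stations(poly, np.linspace(0, 1, 14))
        pc = fit_curve_bspline(ArchCurve(np.column_stack([pts, np.zeros(14)]), provenance="truth"))
        s = np.linspace(0, pc.total_length, 500)
        sampled = pc.points_at(s)[:, :2]
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(poly).query(sampled)
        # the cubic through 14 equal-arc knots deviates most at the tightly
        # curved apex (~8 mm radius); half a millimeter bounds it there
        assert dist.max() < 0.5

    def test_duplicate_points_rejected(self):
        pts = np.column_stack([np.arange(14.0), np.zeros(14), np.zeros(14)])
        pts[5] = pts[4]
        with pytest.raises(ValueError, match="duplicate|distinct"):
            fit_curve_bspline(ArchCurve(pts, provenance="truth"))

    def test_arc_length_parameterization(self):
        poly = _arch_polyline(60, 55)
        pts = _equal_arc_stations(poly, np.linspace(0, 1, 14))
        pc = fit_curve_bspline(ArchCurve(np.column_stack([pts, np.zeros(14)]), provenance="truth"))
        s = np.linspace(0, pc.total_length, 64)
        seg = np.linalg.norm(np.diff(pc.points_at(s), axis=0), axis=1)
        np.testing.assert_allclose(seg, seg.mean(), rtol=0.01)


class TestSlabGeometry:
    def test_native_axis_sample_counts(self):
        """100 mm height at 0.10 mm and 30 mm depth at 0.35 mm sampling."""
        vol = VoxelVolume(np.zeros((40, 20, 20), dtype=np.float32), (1, 1, 1), (-10, -5, -5))
        settings = ReconSettings()  # native 0.10 in plane / 0.35 in depth
        slab = sample_curved_slab(vol, fit_curve_bspline(straight_curve(length=4.0, z=0.0)), settings)
        assert slab.samples.shape[1] == 1001
        assert slab.samples.shape[2] == 86

    def test_constant_volume_gives_constant_slab(self):
        vol = VoxelVolume(np.full((30, 30, 30), 250.0, dtype=np.float32), (1, 1, 1))
        settings = ReconSettings(
            slab_height_above_mm=5, slab_height_below_mm=5, slab_halfwidth_mm=5,
            native_inplane_mm=1.0, native_depth_mm=1.0,
        )
        curve = straight_curve(length=10.0, z=15.0)
        curve = ArchCurve(curve.points_mm + np.array([10.0, 13.0, 0.0]), provenance="truth")
        slab = sample_curved_slab(vol, fit_curve_bspline(curve), settings)
        np.testing.assert_allclose(slab.samples, 250.0, atol=1e-4)

    def test_out_of_volume_fills_with_air(self):
        vol = VoxelVolume(np.full((10, 10, 10), 500.0, dtype=np.float32), (1, 1, 1))
        settings = ReconSettings(
            slab_height_above_mm=30, slab_height_below_mm=30, slab_halfwidth_mm=2,
            native_inplane_mm=1.0, native_depth_mm=1.0,
        )
        curve = straight_curve(length=8.0, z=4.5)
        slab = sample_curved_slab(vol, fit_curve_bspline(curve), settings)
        assert slab.samples.min() == pytest.approx(-1000.0)

    def test_curve_outside_volume_rejected(self):
        vol = VoxelVolume(np.zeros((10, 10, 10), dtype=np.float32), (1, 1, 1))
        far = ArchCurve(straight_curve().points_mm + np.array([500.0, 500.0, 0.0]), provenance="truth")
        with pytest.raises(ValueError, match="outside"):
            sample_curved_slab(vol, fit_curve_bspline(far), ReconSettings())


class TestProjection:
    def _slab(self, values):
        from panomatch.mpr import CurvedSlab

        arr = np.asarray(values, dtype=np.float32)
        return CurvedSlab(arr, 1.0, np.arange(arr.shape[1], dtype=float), 1.0)

    def test_clamp_then_mean(self):
        slab = self._slab(np.array([400.0, 600.0, 800.0]).reshape(1, 1, 3))
        img = project_slab(slab, 500.0)
        assert img.pixels[0, 0] == pytest.approx((500 + 600 + 800) / 3)

    def test_air_slab_projects_to_threshold(self):
        slab = self._slab(np.full((4, 5, 6), -1000.0))
        img = project_slab(slab, 500.0)
        np.testing.assert_allclose(img.pixels, 500.0)

    def test_zero_highpass_is_plain_mean(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1000, (3, 4, 5)).astype(np.float32)
        img = project_slab(self._slab(data), 0.0)
        np.testing.assert_allclose(img.pixels, data.mean(axis=2)[:, ::-1].T, rtol=1e-6)

    def test_cranial_is_up(self):
        data = np.zeros((2, 3, 1), dtype=np.float32)
        data[:, 2, 0] = 1000.0  # largest height offset = most cranial
        img = project_slab(self._slab(data), 0.0)
        assert img.pixels[0].max() == 1000.0  # appears in the top row


class TestFinalize:
    def test_matching_resolution_keeps_grid(self):
        img = Image2D(np.random.default_rng(1).uniform(0, 1, (50, 40)), (0.10, 0.10))
        out = finalize_pr_like(img, ReconSettings(resolution_mm_per_pixel=0.10))
        assert out.shape == (50, 40)
        assert out.pixels.dtype == np.uint8

    def test_resample_factor(self):
        img = Image2D(np.random.default_rng(1).uniform(0, 1, (200, 100)), (0.10, 0.10))
        out = finalize_pr_like(img, ReconSettings(resolution_mm_per_pixel=0.115))
        assert abs(out.shape[1] - round(100 * 0.10 / 0.115)) <= 1
        assert out.resolution_mm_per_pixel == (0.115, 0.115)

    def test_nonconstant_output_spans_8bit_range(self):
        img = Image2D(np.random.default_rng(2).uniform(0, 1, (64, 64)), (0.10, 0.10))
        out = finalize_pr_like(img, ReconSettings(resolution_mm_per_pixel=0.12))
        assert out.pixels.min() == 0 and out.pixels.max() == 255


class TestPipelineOnPhantom:
    def test_reconstruction_is_deterministic(self, fixture_phantom, recon_settings):
        a = reconstruct_pr_like(fixture_phantom.volume, recon_settings)
        b = reconstruct_pr_like(fixture_phantom.volume, recon_settings)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_bright_blobs_match_tooth_count(self, fixture_phantom, fixture_spec, recon_settings):
        """Each tooth appears as a distinct bright blob in the PR-like image.

        Depth is sampled at the method's native 0.35 mm step (coarser
        steps alias crowns into stripes); the 60%-of-maximum mask is
        regularized by a sub-crown-gap closing before counting.
        """
        from skimage.morphology import closing, disk

        settings = dataclasses.replace(recon_settings, native_depth_mm=0.35)
        img = reconstruct_pr_like(fixture_phantom.volume, settings)
        px = img.pixels.astype(float)
        mask = closing(px >= 0.6 * px.max(), disk(2))
        labeled, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
        n_blobs = int((sizes >= 8).sum())
        assert n_blobs == 2 * fixture_spec.n_teeth

    def test_realign_levels_the_tooth_band(self, tilted_phantom, recon_settings):
        settings = dataclasses.replace(recon_settings, rotation="base", realign=False)
        img, rep = reconstruct_pr_like(tilted_phantom.volume, settings, return_report=True)
        pc = fit_curve_bspline(rep.curve)
        before = bright_band_slope(Image2D(img.pixels.astype(float), img.resolution_mm_per_pixel), pc)
        settings_re = dataclasses.replace(settings, realign=True)
        img2, rep2 = reconstruct_pr_like(tilted_phantom.volume, settings_re, return_report=True)
        after = bright_band_slope(Image2D(img2.pixels.astype(float), img2.resolution_mm_per_pixel), pc)
        assert abs(after) <= abs(before) + 1e-9
        assert abs(after) < 0.02

    def test_realign_skips_degenerate_band(self):
        vol = VoxelVolume(np.full((30, 30, 30), 100.0, dtype=np.float32), (1, 1, 1))
        settings = ReconSettings(
            slab_height_above_mm=5, slab_height_below_mm=5, slab_halfwidth_mm=3,
            native_inplane_mm=1.0, native_depth_mm=1.0,
        )
        curve = ArchCurve(straight_curve(10.0, 15.0).points_mm + np.array([10, 0, 0]), provenance="truth")
        pc = fit_curve_bspline(curve)
        slab = sample_curved_slab(vol, pc, settings)
        img = project_slab(slab, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            out = realign_teeth(vol, pc, img, settings)
        np.testing.assert_array_equal(out.pixels, img.pixels)
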