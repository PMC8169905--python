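"""Curvature pipeline: ridge filter, cleaning, skeleton traces, circle
fits, length calibration, and the composed per-image/per-directory drivers."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.optimize import least_squares

from hairmorph import CalibratedImage, CurvatureOptions, analyze_curvature_dir, analyze_curvature_image
from hairmorph.curvature_analysis import (
    FragmentTrace,
    KULPA_FACTOR,
    binarize_and_clean,
    fit_circle_taubin,
    fragment_curvature,
    fragment_length,
    refine_circle_fit,
    ridge_enhance,
    skeletonize_and_split,
)

RES = 132.0


def _binary_pipeline(img):
    response = ridge_enhance(img)
    return binarize_and_clean(response, image=img)


class TestRidgeEnhance:
    def test_constant_image_near_zero_response(self, blank_image):
        resp = ridge_enhance(blank_image)
        assert resp.shape == blank_image.pixels.shape
        assert np.abs(resp).max() < 1e-9

    def test_response_peaks_near_centerline(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=1.0, n_fragments=1, seed=2, canvas=(400, 400))
        resp = ridge_enhance(img)
        # strongest responses must lie inside the drawn stroke (within 2 px)
        stroke = ndimage.binary_dilation(img.pixels == 0, iterations=2)
        top = np.argsort(resp.ravel())[-200:]
        assert stroke.ravel()[top].mean() > 0.99


class TestBinarizeAndClean:
    def test_component_count_preserved(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=0.8, seed=3)
        mask = _binary_pipeline(img)
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 25

    def test_specks_removed(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=0.8, n_fragments=5, seed=3, canvas=(800, 800))
        noisy = img.pixels.copy()
        rng = np.random.default_rng(0)
        for _ in range(10):  # 10 isolated ~3 px specks
            r, c = rng.integers(20, 760, 2)
            noisy[r : r + 3, c] = 0
        noisy_img = CalibratedImage(noisy, resolution=RES, image_id="noisy")
        _, n_clean = ndimage.label(_binary_pipeline(img), structure=np.ones((3, 3)))
        _, n_noisy = ndimage.label(_binary_pipeline(noisy_img), structure=np.ones((3, 3)))
        assert n_noisy == n_clean == 5

    def test_blank_response_gives_empty_mask(self):
        mask = binarize_and_clean(np.zeros((50, 50)))
        assert mask.shape == (50, 50)
        assert not mask.any()


class TestSkeletonizeAndSplit:
    def test_single_arc_single_trace_with_expected_pixel_count(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=1.0, n_fragments=1, seed=4, canvas=(400, 400))
        traces = skeletonize_and_split(_binary_pipeline(img))
        assert len(traces) == 1
        # pixel count bounded by path geometry: each step covers 1..sqrt(2) px
        # of the true length (pi/2 mm * 132 px/mm), minus slight end recession
        n_px = len(traces[0].pixel_path)
        true_px = math.pi / 2 * RES
        assert true_px / math.sqrt(2) * 0.93 <= n_px <= true_px * 1.02
        t = traces[0]
        assert t.n_axial_steps + t.n_diagonal_steps == len(t.pixel_path) - 1

    def test_two_disjoint_arcs_two_traces(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=1.0, n_fragments=2, seed=5, canvas=(700, 700))
        assert len(skeletonize_and_split(_binary_pipeline(img))) == 2

    def test_crossing_strokes_split_at_branch_point(self):
        # plus-sign: two crossing strokes must never yield one merged trace
        mask = np.zeros((201, 201), bool)
        mask[95:106, 20:180] = True
        mask[20:180, 95:106] = True
        traces = skeletonize_and_split(mask, min_length_px=16)
        assert len(traces) == 4
        for t in traces:
            # each branch is roughly straight: spans one arm, not two
            assert len(t.pixel_path) < 90

    def test_empty_mask_empty_list(self):
        assert skeletonize_and_split(np.zeros((30, 30), bool)) == []


class TestFragmentLength:
    def _trace(self, path):
        path = np.asarray(path)
        steps = np.abs(np.diff(path, axis=0))
        ax = int((steps.sum(axis=1) == 1).sum())
        return FragmentTrace(path, ax, len(path) - 1 - ax)

    def test_horizontal_run_chain_rule(self):
        t = self._trace([(5, c) for c in range(10)])
        assert fragment_length(t, RES, calibration="chain") == pytest.approx(9 / 132)

    def test_diagonal_run_chain_rule(self):
        t = self._trace([(i, i) for i in range(10)])
        assert fragment_length(t, 1.0, calibration="chain") == pytest.approx(9 * math.sqrt(2))

    def test_kulpa_is_calibrated_chain(self):
        t = self._trace([(i, i) for i in range(10)])
        assert fragment_length(t, 1.0) == pytest.approx(9 * math.sqrt(2) * KULPA_FACTOR)

    def test_single_pixel_trace_has_zero_length(self):
        assert fragment_length(FragmentTrace(np.array([[3, 3]]), 0, 0), RES) == 0.0

    def test_arc_length_recovered_within_one_percent(self, arc_image_factory):
        # mean over several fragments: digitized length within 1% of pi/2 mm
        img, _ = arc_image_factory(curvature=1.0, n_fragments=10, seed=6, canvas=(1200, 1200))
        traces = skeletonize_and_split(_binary_pipeline(img))
        lengths = [fragment_length(t, RES) for t in traces]
        assert np.mean(lengths) == pytest.approx(math.pi / 2, rel=0.01)


class TestTaubinFit:
    def test_three_point_circumcircle_exact(self):
        fit = fit_circle_taubin(np.array([[1, 0], [0, 1], [-1, 0]]))  # (row, col)
        assert fit.radius_px == pytest.approx(1.0, abs=1e-12)
        assert fit.center_px == pytest.approx((0.0, 0.0), abs=1e-12)
        assert not fit.degenerate

    def test_noiseless_arc_recovered_to_machine_precision(self):
        theta = np.linspace(0.2, 1.4, 25)
        pts = np.column_stack([40 + 250 * np.sin(theta), -10 + 250 * np.cos(theta)])
        fit = fit_circle_taubin(pts)
        assert fit.radius_px == pytest.approx(250.0, abs=1e-6)
        assert fit.residual < 1e-9

    def test_noisy_arc_matches_geometric_oracle(self):
        rng = np.random.default_rng(0)
        theta = np.linspace(0.0, 2.0, 25)
        pts = np.column_stack([250 * np.sin(theta), 250 * np.cos(theta)]) + rng.normal(0, 1, (25, 2))
        fit = fit_circle_taubin(pts)

        def resid(p):  # independent geometric (orthogonal-distance) oracle
            return np.hypot(pts[:, 1] - p[0], pts[:, 0] - p[1]) - p[2]

        oracle = least_squares(resid, [0.0, 0.0, 240.0]).x[2]
        assert fit.radius_px == pytest.approx(oracle, rel=0.02)

    def test_collinear_points_degenerate_not_exception(self):
        fit = fit_circle_taubin(np.array([[0, c] for c in range(20)]))
        assert fit.degenerate
        assert fragment_curvature(fit, RES) == 0.0

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle_taubin(np.array([[0, 0], [1, 1]]))

    def test_geometric_refinement_preserves_exact_fit(self):
        theta = np.linspace(0.0, 3.0, 40)
        pts = np.column_stack([100 * np.sin(theta), 100 * np.cos(theta)])
        fit = refine_circle_fit(pts, fit_circle_taubin(pts))
        assert fit.radius_px == pytest.approx(100.0, abs=1e-8)


class TestFragmentCurvature:
    @pytest.mark.parametrize("radius_px,expected", [(132.0, 1.0), (66.0, 2.0)])
    def test_inverse_radius_in_mm(self, radius_px, expected):
        from hairmorph.curvature_analysis import CircleFitResult

        fit = CircleFitResult((0.0, 0.0), radius_px, 0.0)
        assert fragment_curvature(fit, RES) == pytest.approx(expected)

    def test_scale_equivariance(self):
        # doubling both resolution and radius leaves curvature unchanged
        from hairmorph.curvature_analysis import CircleFitResult

        c1 = fragment_curvature(CircleFitResult((0, 0), 100.0, 0.0), 132.0)
        c2 = fragment_curvature(CircleFitResult((0, 0), 200.0, 0.0), 264.0)
        assert c1 == pytest.approx(c2)


class TestAnalyzeImage:
    def test_simulated_image_recovered(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=1.0, seed=7)
        summary, measures = analyze_curvature_image(img)
        assert summary.hair_count == 25
        assert len(measures) == 25
        assert summary.mean_curvature == pytest.approx(1.0, rel=0.01)
        assert summary.median_curvature == pytest.approx(1.0, rel=0.01)
        assert summary.mean_length == pytest.approx(math.pi / 2, rel=0.02)

    def test_single_fragment_mean_equals_median(self, arc_image_factory):
        img, _ = arc_image_factory(curvature=0.5, n_fragments=1, seed=8, canvas=(900, 900))
        summary, measures = analyze_curvature_image(img)
        assert summary.hair_count == 1
        assert summary.mean_curvature == summary.median_curvature == measures[0].curvature_per_mm

    def test_empty_image_no_crash(self, blank_image):
        summary, measures = analyze_curvature_image(blank_image)
        assert summary.hair_count == 0
        assert measures == []
        assert math.isnan(summary.mean_curvature)


class TestAnalyzeDir:
    def test_batch_summary_deterministic_and_sorted(self, tmp_path, arc_image_factory):
        import tifffile

        for i, curv in enumerate([1.5, 0.5, 1.0]):
            img, _ = arc_image_factory(curvature=curv, n_fragments=3, seed=10 + i,
                                       image_id=f"img{i}", canvas=(900, 900))
            tifffile.imwrite(tmp_path / f"img{i}.tiff", img.pixels)
        out = tmp_path / "out"
        df1 = analyze_curvature_dir(tmp_path, RES, output_dir=out, save_raw=True)
        df2 = analyze_curvature_dir(tmp_path, RES)
        pd.testing.assert_frame_equal(df1, df2)
        assert list(df1.image_id) == sorted(df1.image_id)
        assert (out / "summary_curvature.csv").exists()
        assert (out / "img0_fragments.csv").exists()
        assert (df1.hair_count == 3).all()

    def test_unreadable_file_skipped(self, tmp_path, arc_image_factory):
        import tifffile

        img, _ = arc_image_factory(curvature=1.0, n_fragments=2, seed=11, image_id="good", canvas=(700, 700))
        tifffile.imwrite(tmp_path / "good.tiff", img.pixels)
        (tmp_path / "bad.tiff").write_bytes(b"not a tiff at all")
        df = analyze_curvature_dir(tmp_path, RES)
        assert list(df.image_id) == ["good"]

    def test_empty_dir_header_only(self, tmp_path):
        out = tmp_path / "out"
        df = analyze_curvature_dir(tmp_path, RES, output_dir=out)
        assert len(df) == 0
        assert (out / "summary_curvature.csv").read_text().startswith("image_id,")
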