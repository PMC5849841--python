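"""Gray-map LUT extraction, target location, and contrast-response fitting."""

from __future__ import annotations

import numpy as np
import pytest

import sonoqa as sq
from sonoqa.image_io import Rect


def ramp_image(transfer, length: int = 256, width: int = 12) -> sq.BModeImage:
    """An image whose left strip renders a linear input sweep through a
    display transfer function."""
    v = np.linspace(0.0, 255.0, length)
    displayed = np.clip(np.round(transfer(v)), 0, 255).astype(np.int64)
    px = np.zeros((length, width + 32), dtype=np.int64)
    px[:, :width] = displayed[:, None]
    return sq.BModeImage(pixels=px)


class TestLutExtraction:
    def test_linear_ramp_gives_identity(self):
        img = ramp_image(lambda v: v)
        lut = sq.extract_graymap_lut(img, Rect(0, 256, 0, 12))
        assert lut.source == "ramp_extracted"
        assert np.abs(lut.table - np.arange(256)).max() < 1.0

    def test_gamma_half_map_inverted_within_one_level(self):
        gamma = lambda v: 255.0 * (v / 255.0) ** 0.5
        img = ramp_image(gamma)
        lut = sq.extract_graymap_lut(img, Rect(0, 256, 0, 12))
        v = np.arange(256, dtype=float)
        codes = np.clip(np.round(gamma(v)), 0, 255).astype(int)
        err = lut.table[codes] - v
        assert np.abs(err).max() <= 1.0 + 1e-9

    def test_linearizes_ramp_pixels_within_one_level_rms(self):
        gamma = lambda v: 255.0 * (v / 255.0) ** 0.5
        img = ramp_image(gamma)
        lut = sq.extract_graymap_lut(img, Rect(0, 256, 0, 12))
        linearized = lut(img.pixels[:, 0])
        positions = np.linspace(0.0, 255.0, 256)
        assert np.sqrt(np.mean((linearized - positions) ** 2)) <= 1.0

    def test_constant_ramp_is_degenerate(self, flat_image):
        with pytest.raises(ValueError, match="degenerate ramp"):
            sq.extract_graymap_lut(flat_image(128), Rect(0, 64, 0, 8))

    def test_non_monotone_ramp_rejected(self):
        img = ramp_image(lambda v: 127.5 + 127.5 * np.sin(v / 255.0 * 4 * np.pi))
        with pytest.raises(ValueError, match="not monotone|degenerate"):
            sq.extract_graymap_lut(img, Rect(0, 256, 0, 12))

    def test_descending_ramp_accepted(self):
        img = ramp_image(lambda v: 255.0 - v)
        lut = sq.extract_graymap_lut(img, Rect(0, 256, 0, 12))
        assert np.abs(lut.table - np.arange(256)).max() < 1.0

    def test_lut_table_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            sq.GrayMapLUT(np.array([0.0, 2.0, 1.0]))


class TestTargetLocation:
    def test_auto_detection_close_to_truth(self, contrast_scene, identity_lut):
        cfg, image, truth, phantom = contrast_scene
        rois = sq.locate_contrast_targets(image, phantom, lut=identity_lut)
        assert all(r.detection_status == "ok" for r in rois)
        for roi, (depth, lateral) in zip(rois, truth.target_centers):
            # refined centers land well inside the 8 mm cylinders
            assert abs(image.depth_mm(roi.center_row) - depth) <= 0.5
            assert abs(image.lateral_mm(roi.center_col) - lateral) <= 0.5

    def test_plain_speckle_has_nothing_to_find(self, contrast_scene, identity_lut):
        cfg, _, _, phantom = contrast_scene
        from dataclasses import replace

        blank_cfg = replace(cfg, contrast_cylinders=[], ramp_roi=None)
        blank, _ = sq.simulate_gel_image(blank_cfg, seed=99)
        with pytest.raises(ValueError, match="failed auto-detection"):
            sq.locate_contrast_targets(blank, phantom, lut=identity_lut)

    def test_manual_center_override(self, contrast_scene, identity_lut):
        cfg, image, truth, phantom = contrast_scene
        depth, lateral = truth.target_centers[1]
        rois = sq.locate_contrast_targets(
            image, phantom, lut=identity_lut, manual_centers={1: (depth, lateral)}
        )
        assert rois[1].detection_method == "manual"
        assert rois[1].center_row == pytest.approx(image.row_at_depth(depth))
        assert rois[0].detection_method == "auto"


def _painted_target_image(means, centers_col, radius=10, background=50):
    px = np.full((80, 300), background, dtype=np.int64)
    rr, cc = np.ogrid[:80, :300]
    rois = []
    for mean, col in zip(means, centers_col):
        mask = (rr - 40) ** 2 + (cc - col) ** 2 <= radius**2
        px[mask] = mean
        rois.append(sq.calibration.TargetROI(40.0, float(col), float(radius),
                                             radius * 1.5, radius * 2.0, 0.0))
    return sq.BModeImage(pixels=px), rois


class TestContrastResponse:
    def test_exact_line_through_three_points(self, identity_lut):
        image, rois = _painted_target_image([80, 100, 120], [60, 150, 240])
        result = sq.measure_contrast_response(
            image, rois, nominal_contrasts=[-3.0, 0.0, 3.0], lut=identity_lut
        )
        assert result.slope == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert result.r_squared == pytest.approx(1.0)

    def test_equal_means_give_zero_slope_flagged(self, identity_lut):
        image, rois = _painted_target_image([100, 100, 100], [60, 150, 240])
        result = sq.measure_contrast_response(
            image, rois, nominal_contrasts=[-3.0, 0.0, 3.0], lut=identity_lut
        )
        assert result.slope == 0.0
        assert "no contrast discrimination" in result.flags

    def test_too_few_targets_rejected(self, identity_lut):
        image, rois = _painted_target_image([80, 120], [60, 240])
        with pytest.raises(ValueError, match="at least 3"):
            sq.measure_contrast_response(image, rois, nominal_contrasts=[-3, 3],
                                         lut=identity_lut)

    def test_equal_contrasts_rejected(self, identity_lut):
        image, rois = _painted_target_image([80, 100, 120], [60, 150, 240])
        with pytest.raises(ValueError, match="contrasts are equal"):
            sq.measure_contrast_response(image, rois, nominal_contrasts=[3, 3, 3],
                                         lut=identity_lut)

    def test_saturated_target_flagged(self, identity_lut):
        image, rois = _painted_target_image([80, 100, 255], [60, 150, 240])
        result = sq.measure_contrast_response(
            image, rois, nominal_contrasts=[-3.0, 0.0, 3.0], lut=identity_lut
        )
        assert result.saturation_flag

    @pytest.mark.parametrize("seed", range(5))
    def test_regression_matches_normal_equations_oracle(self, identity_lut, seed):
        rng = np.random.default_rng(seed)
        means = rng.integers(30, 220, size=5)
        contrasts = rng.normal(0.0, 5.0, size=5)
        image, rois = _painted_target_image(means, [40, 100, 160, 220, 280], radius=8)
        result = sq.measure_contrast_response(
            image, rois, nominal_contrasts=list(contrasts), lut=identity_lut
        )
        # brute-force normal equations on the per-target means
        x = np.vstack([contrasts, np.ones(5)]).T
        y = np.array([m for _, m, _ in result.per_target])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert result.slope == pytest.approx(beta[0], rel=1e-9)
        assert result.intercept == pytest.approx(beta[1], rel=1e-9)

    def test_predicted_slope_is_256_over_dr(self, contrast_scene, identity_lut):
        _, image, _, phantom = contrast_scene
        rois = sq.locate_contrast_targets(image, phantom, lut=identity_lut)
        result = sq.measure_contrast_response(image, rois, lut=identity_lut)
        assert result.predicted_slope == pytest.approx(
            256.0 / image.settings.dynamic_range
        )


class TestPixelToDb:
    def test_division_by_slope(self):
        cal = sq.ContrastResponseResult(slope=5.0, intercept=0.0, r_squared=1.0,
                                        per_target=[])
        assert sq.pixel_to_db(30.0, cal) == pytest.approx(6.0)
        assert sq.pixel_to_db(0.0, cal) == 0.0

    def test_zero_slope_uncalibrated(self):
        cal = sq.ContrastResponseResult(slope=0.0, intercept=0.0, r_squared=0.0,
                                        per_target=[])
        with pytest.raises(ValueError, match="uncalibrated"):
            sq.pixel_to_db(30.0, cal)


class TestGrayMapInvariance:
    """Measuring through a nonlinear display map with the ramp-extracted LUT
    must agree with measuring the unmapped scene."""

    @pytest.mark.parametrize("gamma", [0.5, 2.0])
    def test_slope_within_five_percent_of_identity(self, gamma, contrast_scene):
        from dataclasses import replace

        cfg, image, _, phantom = contrast_scene
        lut0 = sq.extract_graymap_lut(image, cfg.ramp_roi)
        rois0 = sq.locate_contrast_targets(image, phantom, lut=lut0)
        slope0 = sq.measure_contrast_response(image, rois0, lut=lut0).slope

        mapped_cfg = replace(cfg, gray_map=sq.gamma_map(gamma),
                             gray_map_id=f"gamma_{gamma}")
        mapped, _ = sq.simulate_gel_image(mapped_cfg, seed=11)  # same speckle seed
        lut = sq.extract_graymap_lut(mapped, cfg.ramp_roi)
        rois = sq.locate_contrast_targets(mapped, phantom, lut=lut)
        slope = sq.measure_contrast_response(mapped, rois, lut=lut).slope
        assert slope == pytest.approx(slope0, rel=0.05)
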