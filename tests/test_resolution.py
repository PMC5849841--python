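"""Pin detection and −6 dB width measurement."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import sonoqa as sq

#: −6 dB full width of a Gaussian amplitude profile is 2.3508·σ
W6 = sq.WIDTH_FACTOR_6DB


def single_pin_config(sigma_lat=0.6, sigma_ax=0.25, sigma_elev=1.2, spacing=0.06,
                      slope=5.0):
    """Noise-free single Gaussian pin centered in a small image."""
    rows = cols = 160
    return sq.SimulationConfig(
        rows=rows, cols=cols,
        axial_spacing=spacing, lateral_spacing=spacing,
        background_echogenicity=0.0, noise_rms=0.0, attenuation=0.0,
        pins=[sq.PinSpec(rows / 2 * spacing, cols / 2 * spacing,
                         sigma_ax, sigma_lat, sigma_elev, 1.0)],
        compression_slope=slope,
        compression_reference=10.0 ** (1.0 / 20.0),  # peak 1 dB below top code
    )


def _cal(slope):
    return sq.ContrastResponseResult(slope=slope, intercept=0.0, r_squared=1.0,
                                     per_target=[])


class TestClosedFormWidths:
    def test_gaussian_pin_matches_analytic_width(self, identity_lut):
        cfg = single_pin_config()
        image, truth = sq.simulate_gel_image(cfg, seed=0)
        pin = sq.Pin(truth.pin_centers[0][0], truth.pin_centers[0][1], 0.0)
        lat = sq.measure_pin_width(image, pin, "lateral", _cal(5.0), lut=identity_lut)
        ax = sq.measure_pin_width(image, pin, "axial", _cal(5.0), lut=identity_lut)
        assert lat.width_mm == pytest.approx(W6 * 0.6, rel=0.02)
        assert ax.width_mm == pytest.approx(W6 * 0.25, rel=0.02)
        assert lat.threshold_level == pytest.approx(lat.peak_level - 30.0)

    def test_width_converges_as_spacing_shrinks(self, identity_lut):
        """At spacing σ/10 the discretization error is within 2%."""
        cfg = single_pin_config(sigma_lat=0.6, spacing=0.06)
        image, truth = sq.simulate_gel_image(cfg, seed=0)
        pin = sq.Pin(*truth.pin_centers[0], 0.0)
        m = sq.measure_pin_width(image, pin, "lateral", _cal(5.0), lut=identity_lut)
        assert m.width_mm == pytest.approx(W6 * 0.6, rel=0.02)

    @pytest.mark.parametrize("slope", [2.844, 5.0, 8.0])
    def test_compression_invariance(self, slope, identity_lut):
        """The −6 dB width is invariant to the compression slope when the
        matching calibration is used."""
        cfg = single_pin_config(slope=slope)
        image, _ = sq.simulate_gel_image(cfg, seed=0)
        pin = sq.Pin(4.8, 4.8, 0.0)
        m = sq.measure_pin_width(image, pin, "lateral", _cal(slope), lut=identity_lut)
        assert m.width_mm == pytest.approx(W6 * 0.6, rel=0.02)

    def test_flat_profile_is_truncated(self, flat_image, identity_lut):
        img = flat_image(100, shape=(64, 64))
        with pytest.raises(ValueError, match="truncated"):
            sq.measure_pin_width(img, (3.2, 3.2), "lateral", _cal(5.0), lut=identity_lut)

    def test_nonpositive_calibration_rejected(self, flat_image, identity_lut):
        with pytest.raises(ValueError, match="slope"):
            sq.measure_pin_width(flat_image(), (3.2, 3.2), "lateral", _cal(0.0),
                                 lut=identity_lut)


class TestPinDetection:
    def test_all_pins_found_near_truth(self, resolution_scene, identity_lut):
        cfg, image, truth, phantom = resolution_scene
        det = sq.detect_pins(image, phantom, lut=identity_lut)
        assert det.n_found == det.n_expected == len(truth.pin_centers)
        for pin, (depth, lateral) in zip(det.pins, truth.pin_centers):
            # speckle perturbs the residual peak; centers land well within
            # the beam width of the true filament position
            assert abs(pin.depth_mm - depth) <= 0.25
            assert abs(pin.lateral_mm - lateral) <= 0.25

    def test_plain_speckle_finds_nothing(self, resolution_scene, identity_lut):
        cfg, _, _, phantom = resolution_scene
        blank_cfg = replace(cfg, pins=[])
        blank, _ = sq.simulate_gel_image(blank_cfg, seed=77)
        det = sq.detect_pins(blank, phantom, lut=identity_lut)
        assert det.n_found == 0
        assert det.failed

    def test_manual_centers_taken_verbatim(self, resolution_scene, identity_lut):
        _, image, truth, phantom = resolution_scene
        det = sq.detect_pins(image, phantom, lut=identity_lut,
                             manual_centers=[truth.pin_centers[2]])
        assert det.method == "manual"
        assert det.n_found == 1
        assert det.pins[0].depth_mm == truth.pin_centers[2][0]


class TestReferencePinSelection:
    def _det(self, depths):
        return sq.PinDetection(pins=[sq.Pin(d, 25.0, 100.0) for d in depths],
                               method="auto", n_expected=len(depths),
                               n_found=len(depths))

    def test_nearest_to_focal_depth(self):
        pin = sq.select_reference_pin(self._det([20, 40, 60]), focal_depth_mm=38)
        assert pin.depth_mm == 40

    def test_half_dop_rule_when_no_focus(self):
        pin = sq.select_reference_pin(self._det([20, 40, 60]), dop_cm=8.0)
        assert pin.depth_mm == 40  # half of 8 cm = 40 mm

    def test_tie_breaks_toward_shallower_pin(self):
        pin = sq.select_reference_pin(self._det([30, 50]), focal_depth_mm=40)
        assert pin.depth_mm == 30

    def test_no_criterion_is_an_error(self):
        with pytest.raises(ValueError, match="no selection criterion"):
            sq.select_reference_pin(self._det([30]))


class TestElevational:
    def test_tilted_width_is_quadrature_broadened(self, identity_lut):
        cfg = single_pin_config(sigma_lat=0.3, sigma_elev=1.2, spacing=0.1)
        image, truth = sq.simulate_tilted_pin_image(cfg, seed=0)
        pin = sq.Pin(*truth.pin_centers[0], 0.0)
        m = sq.measure_elevational(image, pin, _cal(5.0), lut=identity_lut)
        apparent_sigma = np.hypot(1.2, 0.3)
        assert m.axis == "elevational"
        assert m.width_mm == pytest.approx(W6 * apparent_sigma, rel=0.02)
        assert truth.expected_widths[0]["elevational_apparent"] == pytest.approx(
            W6 * apparent_sigma
        )

    def test_wide_inplane_beam_warns(self, identity_lut):
        cfg = single_pin_config(sigma_lat=1.5, sigma_elev=1.2, spacing=0.1)
        image, truth = sq.simulate_tilted_pin_image(cfg, seed=0)
        pin = sq.Pin(*truth.pin_centers[0], 0.0)
        with pytest.warns(UserWarning, match="dominated"):
            m = sq.measure_elevational(image, pin, _cal(5.0), lut=identity_lut,
                                       lateral_width_mm=W6 * 1.5)
        assert "lateral_beam_dominates" in m.flags

    def test_only_45_degrees_supported(self):
        with pytest.raises(ValueError, match="45"):
            sq.simulate_tilted_pin_image(single_pin_config(), tilt_degrees=30.0)


class TestResolutionVsDepth:
    def test_axial_constant_lateral_focused(self, resolution_scene,
                                            resolution_calibration, identity_lut):
        cfg, image, truth, phantom = resolution_scene
        det = sq.detect_pins(image, phantom, lut=identity_lut)
        table = sq.resolution_vs_depth(image, det, resolution_calibration,
                                       lut=identity_lut)
        ax = table[table.axis == "axial"].sort_values("pin_depth_mm")
        lat = table[table.axis == "lateral"].sort_values("pin_depth_mm")
        # axial width constant with depth (σ_axial is depth-independent)
        assert np.ptp(ax.width_mm.to_numpy()) / ax.width_mm.mean() < 0.10
        # lateral width minimal at the simulated 40 mm focus
        focus_idx = int(np.argmin(np.abs(lat.pin_depth_mm.to_numpy() - 40.0)))
        assert int(np.argmin(lat.width_mm.to_numpy())) == focus_idx

    def test_no_pins_gives_empty_table(self, resolution_scene,
                                       resolution_calibration, identity_lut):
        _, image, _, _ = resolution_scene
        det = sq.PinDetection(pins=[], method="auto", n_expected=7, n_found=0)
        table = sq.resolution_vs_depth(image, det, resolution_calibration,
                                       lut=identity_lut)
        assert table.empty

    def test_frequency_scaling_improves_resolution(self, identity_lut):
        """Beam σ scales as 1/frequency in simulation, so measured widths
        must decrease when transmit frequency increases."""
        widths = {}
        for f, scale in ((3.0, 5.0 / 3.0), (5.0, 1.0), (9.0, 5.0 / 9.0)):
            cfg = single_pin_config(sigma_lat=0.6 * scale, sigma_ax=0.25 * scale)
            image, truth = sq.simulate_gel_image(cfg, seed=0)
            pin = sq.Pin(*truth.pin_centers[0], 0.0)
            widths[f] = sq.measure_pin_width(image, pin, "lateral", _cal(5.0),
                                             lut=identity_lut).width_mm
        assert widths[3.0] > widths[5.0] > widths[9.0]
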