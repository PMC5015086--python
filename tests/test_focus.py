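"""Depth-from-focus: crop preparation, l1 curve, refinement, selection."""

import numpy as np
import pytest

from holofly.focus import (
    FocusConfig,
    FocusCurve,
    estimate_depth,
    focus_metric_curve,
    multipass_select,
    prepare_crop,
    refine_peak,
    variance_metric_curve,
)
from holofly.preprocess import enhance
from holofly.synth import SyntheticFly, simulate_hologram

PITCH = 30e-6


@pytest.fixture(scope="module")
def fc():
    return FocusConfig()


class TestPrepareCrop:
    def test_constant_crop_gives_zero_spectrum(self, fc):
        frame = np.full((512, 512), 3.3)
        spec = prepare_crop(frame, (256.0, 256.0), fc)
        assert np.allclose(spec, 0.0, atol=1e-9)

    def test_output_is_padded_square(self, fc):
        frame = np.random.default_rng(0).normal(size=(512, 512))
        spec = prepare_crop(frame, (100.0, 400.0), fc)
        assert spec.shape == (256, 256)

    def test_border_crop_zero_filled_not_shifted(self, fc):
        frame = np.random.default_rng(1).normal(size=(512, 512))
        spec = prepare_crop(frame, (5.0, 5.0), fc)  # mostly off-frame
        assert np.all(np.isfinite(spec))
        assert np.abs(spec).sum() > 0

    def test_centered_impulse_spectrum_is_flat(self, fc):
        """An impulse transforms to (near-)constant magnitude."""
        frame = np.zeros((512, 512))
        frame[256, 256] = 1.0
        spec = np.abs(prepare_crop(frame, (256.0, 256.0), fc))
        # away from DC (which carries the mean-subtraction residue) the
        # magnitude is that of a pure delta
        flat = spec[5:-5, 5:-5]
        assert flat.std() / flat.mean() < 0.05


class TestFocusMetricCurve:
    def test_zero_spectrum_gives_zero_curve(self, fc, optics512):
        spec = np.zeros((256, 256), complex)
        curve = focus_metric_curve(spec, fc, optics512)
        assert np.allclose(curve.metric_values, 0.0)

    def test_empty_z_grid_rejected(self, fc, optics512):
        with pytest.raises(ValueError):
            focus_metric_curve(
                np.ones((256, 256), complex), fc, optics512,
                z_grid_m=np.array([]),
            )

    def test_recovers_depth_of_single_fly(self, fc, optics512,
                                          flat_background, single_fly_frame):
        frame, _ = single_fly_frame(z_m=0.152, seed=21)
        enhanced = enhance(frame, flat_background, smooth_window=1)
        curve = estimate_depth(enhanced, (255.5, 255.5), fc, optics512)
        assert curve.selected_z_m is not None
        assert curve.selected_z_m == pytest.approx(0.152, abs=2e-3)

    def test_two_flies_give_two_extrema(self, fc, optics512,
                                        flat_background):
        """Both depths appear as local extrema in one crop's curve.

        A fly's focus dip spans roughly a centimeter (millimeter-sized
        objects have a large depth of focus), so only well-separated
        depths resolve into two extrema, and overlapping dips pull each
        other inward — hence the asymmetric tolerances.
        """
        ctr = 256 * PITCH
        flies = [
            SyntheticFly(position_m=(ctr - 70 * PITCH, ctr, 0.140)),
            SyntheticFly(position_m=(ctr + 70 * PITCH, ctr, 0.190)),
        ]
        frame = simulate_hologram(flies, optics512, noise_sd=0.005, seed=8)
        enhanced = enhance(frame, flat_background, smooth_window=1)
        spec = prepare_crop(enhanced, (256.0, 256.0), fc)
        curve = multipass_select(focus_metric_curve(spec, fc, optics512), fc)
        zs = np.array([z for z, _ in curve.peaks])
        assert len(zs) >= 2
        assert np.min(np.abs(zs - 0.140)) < 3e-3
        assert np.min(np.abs(zs - 0.190)) < 10e-3

    def test_translation_within_crop_changes_metric_little(
        self, fc, optics512, flat_background, single_fly_frame
    ):
        frame, _ = single_fly_frame(z_m=0.16, seed=9)
        enhanced = enhance(frame, flat_background, smooth_window=1)
        a = focus_metric_curve(
            prepare_crop(enhanced, (255.5, 255.5), fc), fc, optics512
        )
        b = focus_metric_curve(
            prepare_crop(enhanced, (248.5, 262.5), fc), fc, optics512
        )
        rel = np.abs(a.metric_values - b.metric_values) / a.metric_values
        assert rel.max() < 0.05


class TestRefinePeak:
    def test_parabola_vertex_recovered(self):
        z = 0.135 + 0.001 * np.arange(30)
        vertex = 0.1401
        curve = FocusCurve(z, (z - vertex) ** 2, sense="minimize")
        refined, boundary = refine_peak(curve, int(np.argmin(curve.metric_values)))
        assert not boundary
        assert refined == pytest.approx(vertex, abs=1e-5)

    def test_symmetric_triangle_keeps_apex(self):
        z = 0.135 + 0.001 * np.arange(21)
        vals = np.abs(np.arange(21) - 10).astype(float)
        curve = FocusCurve(z, vals, sense="minimize")
        refined, boundary = refine_peak(curve, 10)
        assert not boundary
        assert refined == pytest.approx(z[10], abs=1e-4)

    def test_monotone_curve_flags_boundary(self):
        z = 0.135 + 0.001 * np.arange(10)
        curve = FocusCurve(z, np.arange(10.0), sense="minimize")
        refined, boundary = refine_peak(curve, 0)
        assert boundary
        assert refined == z[0]

    def test_refinement_stays_within_one_grid_step(self):
        rng = np.random.default_rng(6)
        z = 0.135 + 0.001 * np.arange(30)
        vals = (z - 0.148) ** 2 + rng.normal(0, 1e-8, 30)
        curve = FocusCurve(z, vals, sense="minimize")
        idx = int(np.argmin(vals))
        refined, _ = refine_peak(curve, idx)
        assert abs(refined - z[idx]) <= 0.001 + 1e-12


class TestMultipassSelect:
    def _curve_with_dips(self, dips):
        """Synthetic metric with Gaussian dips (depth, depth-width, size)."""
        z = 0.135 + 0.001 * np.arange(66)
        vals = np.full(66, 1000.0)
        for z0, w, amp in dips:
            vals -= amp * np.exp(-((z - z0) ** 2) / (2 * w**2))
        rng = np.random.default_rng(0)
        vals += rng.normal(0, 0.01, 66)
        return FocusCurve(z, vals, sense="minimize")

    def test_single_dominant_dip_selected(self, fc):
        curve = self._curve_with_dips([(0.158, 0.004, 50.0)])
        out = multipass_select(curve, fc)
        assert out.selected_z_m == pytest.approx(0.158, abs=1e-3)

    def test_subthreshold_peaks_leave_gap(self, fc):
        curve = self._curve_with_dips([(0.158, 0.004, 0.02)])
        out = multipass_select(curve, fc)
        assert out.selected_z_m is None

    def test_prior_breaks_tie_between_two_peaks(self, fc):
        curve = self._curve_with_dips(
            [(0.145, 0.004, 50.0), (0.180, 0.004, 50.0)]
        )
        out = multipass_select(curve, fc, prior_z_m=0.178)
        assert out.selected_z_m == pytest.approx(0.180, abs=1e-3)
        curve2 = self._curve_with_dips(
            [(0.145, 0.004, 50.0), (0.180, 0.004, 50.0)]
        )
        out2 = multipass_select(curve2, fc, prior_z_m=None)
        assert out2.selected_z_m is None  # ambiguous without a prior


class TestAgainstVarianceOracle:
    def test_l1_and_variance_metrics_agree(self, fc, optics512,
                                           flat_background, single_fly_frame):
        """Two independent focus criteria land on the same plane."""
        grid_step = optics512.z_step_m
        for i, z_true in enumerate((0.142, 0.163, 0.188)):
            frame, _ = single_fly_frame(z_m=z_true, seed=30 + i)
            enhanced = enhance(frame, flat_background, smooth_window=1)
            spec = prepare_crop(enhanced, (255.5, 255.5), fc)
            l1 = multipass_select(focus_metric_curve(spec, fc, optics512), fc)
            var = variance_metric_curve(spec, optics512)
            z_var = var.z_samples_m[np.argmax(var.metric_values)]
            assert l1.selected_z_m is not None
            assert abs(l1.selected_z_m - z_var) <= 2 * grid_step + 1e-9
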