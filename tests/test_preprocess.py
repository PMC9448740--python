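"""Behaviour of the spectral preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramandx.containers import SpectrumSet, trapezoid_area
from ramandx.errors import ParameterError, StateError, ValidationError
from ramandx.preprocess import (
    PreprocessConfig,
    calibrate_shift,
    estimate_baseline,
    flag_artifacts,
    normalize_area,
    preprocess_pipeline,
    smooth,
    subtract_baseline,
)
from tests.conftest import make_meta


@pytest.fixture
def cfg():
    return PreprocessConfig()


def spectrum_set(axis, rows):
    rows = np.atleast_2d(rows)
    return SpectrumSet(axis, rows, make_meta(rows.shape[0]))


class TestArtifactFlagging:
    def test_smooth_peak_kept(self, axis, cfg):
        y = 10.0 * np.exp(-0.5 * ((axis - 1100.0) / 4.0) ** 2) + 1.0
        kept, rejected = flag_artifacts(spectrum_set(axis, y), cfg)
        assert kept.n_spectra == 1 and rejected == []

    def test_cosmic_ray_rejected(self, axis, cfg):
        rng = np.random.default_rng(0)
        y = 10.0 * np.exp(-0.5 * ((axis - 1100.0) / 8.0) ** 2) + 1.0
        y += rng.normal(0, 0.05, axis.size)
        spike = y.copy()
        spike[200] += 50.0 * y.max()
        # independent hand oracle: the spike's second difference dominates
        # the MAD of second differences by far more than the threshold
        d2 = np.diff(spike, n=2)
        mad = np.median(np.abs(d2 - np.median(d2)))
        assert np.max(np.abs(d2)) > cfg.spike_mad_threshold * mad
        kept, rejected = flag_artifacts(spectrum_set(axis, np.vstack([y, spike])), cfg)
        assert kept.n_spectra == 1
        assert rejected == [(1, "cosmic_ray")]

    def test_saturated_spectrum_rejected(self, axis):
        cfg = PreprocessConfig(saturation_level=100.0)
        y = np.full(axis.size, 10.0)
        y[50:53] = 100.0
        kept, rejected = flag_artifacts(spectrum_set(axis, y), cfg)
        assert rejected == [(0, "saturation")]

    def test_clean_noise_rarely_rejected(self, axis, cfg):
        rng = np.random.default_rng(1)
        y = 5.0 + rng.normal(0, 0.1, size=(200, axis.size))
        kept, rejected = flag_artifacts(spectrum_set(axis, y), cfg)
        assert len(rejected) / 200 <= 0.01

    def test_short_spectrum_rejected(self, cfg):
        axis = np.linspace(450, 1800, 16)
        s = spectrum_set(axis, np.ones(16))
        # bypass construction-time validation to hit the operation's own check
        s.axis = s.axis[:4]
        s.intensities = s.intensities[:, :4]
        with pytest.raises(ValidationError):
            flag_artifacts(s, cfg)


class TestBaseline:
    def test_constant_reproduced(self, axis, cfg):
        y = np.full(axis.size, 7.0)
        b = estimate_baseline(y, cfg)
        np.testing.assert_allclose(b, y, atol=1e-9)

    def test_line_reproduced(self, axis, cfg):
        y = 2.0 + 0.01 * (axis - axis[0])
        b = estimate_baseline(y, cfg)
        np.testing.assert_allclose(b, y, atol=1e-8)

    def test_peak_on_quadratic_background_recovered(self, axis, cfg):
        # truth known by construction: narrow peak + smooth quadratic
        x = np.linspace(-1, 1, axis.size)
        background = 100.0 * (0.5 + 0.3 * x + 0.4 * x**2)
        peak = 40.0 * np.exp(-0.5 * ((axis - 1100.0) / (2.0 * 2.0)) ** 2)
        b = estimate_baseline(background + peak, cfg)
        off_peak = np.abs(axis - 1100.0) > 50.0
        err = np.abs(b - background)[off_peak]
        assert err.max() < 0.05 * (background.max() - background.min())

    def test_iterative_envelope_monotone(self, axis, cfg):
        rng = np.random.default_rng(3)
        y = 50.0 * np.exp(-0.5 * ((axis - 900) / 10.0) ** 2) + rng.uniform(0, 1, axis.size)
        b, trace = estimate_baseline(y, cfg, return_envelope_trace=True)
        for earlier, later in zip(trace, trace[1:]):
            # signal replacement can only lower the working envelope
            assert np.all(later <= earlier + 1e-12)
        assert b.max() <= y.max() + 1e-9

    def test_window_longer_than_spectrum_errors(self):
        axis = np.linspace(450, 1800, 20)
        cfg = PreprocessConfig(baseline_window=21)
        with pytest.raises(ParameterError):
            estimate_baseline(np.ones(20), cfg)

    def test_subtract_flat_gives_zero_and_tracks_state(self, axis, cfg):
        s = spectrum_set(axis, np.full((2, axis.size), 3.0))
        out = subtract_baseline(s, cfg)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)
        assert out.processing_state == ["baseline"]
        with pytest.raises(StateError):
            subtract_baseline(out, cfg)

    def test_peak_height_preserved(self, axis, cfg):
        x = np.linspace(-1, 1, axis.size)
        background = 100.0 * (0.6 + 0.2 * x + 0.3 * x**2)
        peak = 40.0 * np.exp(-0.5 * ((axis - 1100.0) / 4.0) ** 2)
        s = spectrum_set(axis, background + peak)
        out = subtract_baseline(s, cfg)
        i_peak = int(np.argmin(np.abs(axis - 1100.0)))
        assert out.intensities[0, i_peak] == pytest.approx(40.0, rel=0.05)


class TestCalibration:
    def _peaked(self, axis, center=1003.0):
        return 10.0 * np.exp(-0.5 * ((axis - center) / 3.0) ** 2) + 1.0

    def test_peak_at_reference_unshifted(self, axis, cfg):
        y = self._peaked(axis)
        out = calibrate_shift(spectrum_set(axis, y), cfg)
        np.testing.assert_array_equal(out.intensities[0], y)

    def test_translation_restored(self, axis, cfg):
        y = self._peaked(axis)
        shifted = np.roll(y, 3)
        shifted[:3] = y[0]
        out = calibrate_shift(spectrum_set(axis, shifted), cfg)
        interior = slice(4, -4)
        np.testing.assert_allclose(out.intensities[0][interior], y[interior], atol=1e-9)

    def test_flat_spectrum_left_alone(self, axis, cfg, caplog):
        y = np.full(axis.size, 2.0)
        with caplog.at_level("WARNING"):
            out = calibrate_shift(spectrum_set(axis, y), cfg)
        np.testing.assert_array_equal(out.intensities[0], y)
        assert any("unshifted" in r.message for r in caplog.records)

    def test_axis_not_covering_window_errors(self, cfg):
        axis = np.linspace(1200.0, 1800.0, 200)
        with pytest.raises(ParameterError):
            calibrate_shift(spectrum_set(axis, np.ones(200)), cfg)


class TestNormalization:
    def test_unit_area(self, small_set):
        out = normalize_area(small_set)
        areas = trapezoid_area(out.intensities, out.axis)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_idempotent(self, small_set):
        once = normalize_area(small_set)
        twice = normalize_area(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, axis, scale):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.5, 2.0, size=(1, axis.size))
        a = normalize_area(spectrum_set(axis, y))
        b = normalize_area(spectrum_set(axis, scale * y))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_zero_spectrum_rejected(self, axis):
        with pytest.raises(ValidationError):
            normalize_area(spectrum_set(axis, np.zeros(axis.size)))


class TestSmoothing:
    def test_line_unchanged(self, axis, cfg):
        y = 1.0 + 0.002 * (axis - axis[0])
        out = smooth(spectrum_set(axis, y), cfg)
        np.testing.assert_allclose(out.intensities[0], y, atol=1e-9)

    def test_three_point_mean_kernel(self, cfg):
        # SG(window 3, order 1) has coefficients (1/3, 1/3, 1/3)
        axis = np.linspace(450.0, 1800.0, 16)
        y = np.zeros(16)
        y[8] = 3.0
        out = smooth(spectrum_set(axis, y), cfg)
        np.testing.assert_allclose(out.intensities[0][7:10], [1.0, 1.0, 1.0], atol=1e-12)

    def test_noise_variance_decreases(self, axis, cfg):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(1, axis.size))
        out = smooth(spectrum_set(axis, y), cfg)
        assert out.intensities.var() < y.var()


class TestPipeline:
    def test_clean_cohort_no_rejections_unit_area(self, axis, library):
        from ramandx.synthetic import CohortDesign, simulate_cohort

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=4, seed=2
        )
        raw, truth, _ = simulate_cohort(design, library)
        processed, report = preprocess_pipeline(raw, PreprocessConfig())
        assert report.rejection_counts == {}
        # smoothing follows normalization in the chain, so areas are unit
        # only up to the smoother's edge effects
        areas = trapezoid_area(processed.intensities, processed.axis)
        np.testing.assert_allclose(areas, 1.0, atol=1e-3)

    def test_injected_cosmic_rays_all_rejected(self, axis, library):
        from ramandx.synthetic import CohortDesign, simulate_cohort

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=10,
            cosmic_ray_rate=0.05, seed=3,
        )
        raw, truth, _ = simulate_cohort(design, library)
        assert truth.cosmic_ray_spectra, "generator should have injected spikes"
        processed, report = preprocess_pipeline(raw, PreprocessConfig())
        rejected = {i for i, reason in report.rejected if reason == "cosmic_ray"}
        assert rejected == set(truth.cosmic_ray_spectra)

    def test_counts_conserved(self, library):
        from ramandx.synthetic import CohortDesign, simulate_cohort

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=5, seed=4
        )
        raw, _, _ = simulate_cohort(design, library)
        processed, report = preprocess_pipeline(raw, PreprocessConfig())
        assert sum(report.per_biopsy_counts.values()) == report.n_kept
        assert report.n_kept + len(report.rejected) == report.n_input

    def test_deterministic(self, library):
        from ramandx.synthetic import CohortDesign, simulate_cohort

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=3, seed=6
        )
        raw, _, _ = simulate_cohort(design, library)
        a, _ = preprocess_pipeline(raw, PreprocessConfig())
        b, _ = preprocess_pipeline(raw.copy(), PreprocessConfig())
        np.testing.assert_array_equal(a.intensities, b.intensities)
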